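"""Bulked-segregant scan over pooled SNP calls.

Two pools of F2 segregants — self-compatible (SC) and self-incompatible (SI)
— are sequenced and their per-site allele counts compared against two
reference genotypes: MN47 (the mapping reference) and AL4 (a reference built
from the SC parent's inbreeding population).  A region causal for the pooled
phenotype shows a depression of heterozygosity in the SC pool: its reads
match the AL4 allele at almost every site, while the SI pool stays
polymorphic.

The scan has four layers:

* call-level filters (minimum within-pool allele frequency, minimum score);
* per-site divergence from a chosen reference, averaged in sliding windows
  (window 200 kb, step 10 kb by default);
* candidate-region detection on the window profiles;
* a seven-category per-SNP classification of allele sharing between pools
  and references, with per-gene summaries.

Pools have no diploid genotype, so "homozygous/fixed" is defined on read
fractions: a pool is fixed when its minor-allele read fraction is at or below
``fixation_threshold`` (default 0.1%).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SC_POOL = "SC"
SI_POOL = "SI"
NUCLEOTIDES = ("A", "C", "G", "T")

DEFAULT_MIN_FREQ = 0.10
DEFAULT_MIN_SCORE = 25.0
DEFAULT_FIXATION_THRESHOLD = 0.001
DEFAULT_WINDOW_SIZE = 200_000
DEFAULT_STEP_SIZE = 10_000
DEFAULT_SC_MAX = 0.05
DEFAULT_SI_MIN = 0.35


@dataclass(frozen=True)
class PoolCounts:
    """Read evidence for one pool at one site."""

    depth: int
    allele_counts: dict[str, int]
    score: float = 40.0

    def __post_init__(self) -> None:
        if self.depth < 0 or any(c < 0 for c in self.allele_counts.values()):
            raise ValueError("negative read counts")
        if sum(self.allele_counts.values()) != self.depth:
            raise ValueError(
                f"allele counts sum to {sum(self.allele_counts.values())}, "
                f"depth is {self.depth}"
            )

    @property
    def major_allele(self) -> str | None:
        if self.depth == 0:
            return None
        # deterministic tie-break: highest count, then alphabetical
        return min(self.allele_counts, key=lambda a: (-self.allele_counts[a], a))

    @property
    def minor_fraction(self) -> float | None:
        if self.depth == 0:
            return None
        return 1.0 - max(self.allele_counts.values()) / self.depth

    def fraction(self, allele: str) -> float | None:
        if self.depth == 0:
            return None
        return self.allele_counts.get(allele, 0) / self.depth

    def is_fixed(self, threshold: float = DEFAULT_FIXATION_THRESHOLD) -> bool:
        mf = self.minor_fraction
        return mf is not None and mf <= threshold


@dataclass(frozen=True)
class SnpCall:
    """One site's per-pool read counts plus the two reference alleles.

    ``ref_base`` is the MN47 reference allele; ``al4_allele`` the AL4
    genotype's allele at the site (``None`` when unknown or ambiguous).
    """

    chrom: str
    pos: int
    ref_base: str
    pools: dict[str, PoolCounts]
    al4_allele: str | None = None
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")


@dataclass(frozen=True)
class SnpCategoryFlags:
    """The seven allele-sharing categories of the per-gene SNP summary.

    Implications: flag4 => flag2 => flag1, and flag6 (no SC coverage)
    suppresses flags 1-5.
    """

    homo_sc: bool
    al4_sc_homo_si_het: bool
    sc_ne_si_both_homo: bool
    sc_eq_al4_si_het: bool
    sc_eq_mn47_when_homo: bool
    missing_in_sc: bool
    indel: bool

    def as_tuple(self) -> tuple[bool, ...]:
        return (
            self.homo_sc,
            self.al4_sc_homo_si_het,
            self.sc_ne_si_both_homo,
            self.sc_eq_al4_si_het,
            self.sc_eq_mn47_when_homo,
            self.missing_in_sc,
            self.indel,
        )


FLAG_NAMES = (
    "homo_sc",
    "al4_sc_homo_si_het",
    "sc_ne_si_both_homo",
    "sc_eq_al4_si_het",
    "sc_eq_mn47_when_homo",
    "missing_in_sc",
    "indel",
)


@dataclass(frozen=True)
class WindowProfile:
    """Mean divergence from the reference per pool in one window.

    Windows are 1-based, half-open ``[start, start + window_size)``; ``end``
    is the inclusive last base.  Empty windows carry NaN means.
    """

    chrom: str
    start: int
    end: int
    mean_divergence: dict[str, float]
    n_snps: int


@dataclass(frozen=True)
class RegionCall:
    """A run of consecutive windows matching the SC-fixed / SI-polymorphic rule."""

    chrom: str
    start: int
    end: int
    n_windows: int
    sc_mean: float
    si_mean: float

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def call_variants(
    sites: list[SnpCall],
    min_freq: float = DEFAULT_MIN_FREQ,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[SnpCall]:
    """Keep sites with a qualifying alternative allele in at least one pool.

    An alternative allele qualifies in a pool when its read fraction is at
    least ``min_freq`` and the pool's site score at least ``min_score``
    (both thresholds inclusive).
    """
    kept = []
    for snp in sites:
        ok = False
        for pool in snp.pools.values():
            if pool.depth == 0 or pool.score < min_score:
                continue
            for allele, count in pool.allele_counts.items():
                if allele != snp.ref_base and count / pool.depth >= min_freq:
                    ok = True
                    break
            if ok:
                break
        if ok:
            kept.append(snp)
    return kept


def divergence_frequency(
    snp: SnpCall, pool: str, reference: str = "AL4"
) -> float:
    """Fraction of a pool's reads differing from the chosen reference allele.

    0 means fixation for the reference allele, 1 fixation for anything else.
    NaN when the pool has no coverage or the reference allele is unknown.
    """
    ref_allele = snp.al4_allele if reference == "AL4" else snp.ref_base
    if ref_allele is None:
        return float("nan")
    counts = snp.pools.get(pool)
    if counts is None or counts.depth == 0:
        return float("nan")
    return 1.0 - counts.allele_counts.get(ref_allele, 0) / counts.depth


def sliding_window_profile(
    snps: list[SnpCall],
    window_size: int = DEFAULT_WINDOW_SIZE,
    step_size: int = DEFAULT_STEP_SIZE,
    reference: str = "AL4",
    pools: tuple[str, ...] = (SC_POOL, SI_POOL),
) -> list[WindowProfile]:
    """Average per-site divergence in sliding windows along each chromosome.

    Windows are anchored at position 1 and advance by ``step_size`` while the
    start does not exceed the chromosome's highest SNP position; a window
    averages the non-missing divergences of the SNPs it contains.  The
    result is invariant to the input order of SNPs.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    by_chrom: dict[str, list[SnpCall]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)

    profiles: list[WindowProfile] = []
    for chrom in sorted(by_chrom):
        chrom_snps = sorted(by_chrom[chrom], key=lambda s: s.pos)
        pos = np.array([s.pos for s in chrom_snps])
        div = {
            pool: np.array(
                [divergence_frequency(s, pool, reference) for s in chrom_snps]
            )
            for pool in pools
        }
        # prefix sums over non-NaN divergences for O(1) window means
        valid = {p: ~np.isnan(div[p]) for p in pools}
        cum = {p: np.concatenate(([0.0], np.cumsum(np.where(valid[p], div[p], 0.0)))) for p in pools}
        cum_n = {p: np.concatenate(([0], np.cumsum(valid[p]))) for p in pools}
        max_pos = int(pos[-1])
        starts = range(1, max_pos + 1, step_size)
        for start in starts:
            stop = start + window_size  # half-open
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, stop, side="left"))
            means = {}
            for p in pools:
                n_valid = int(cum_n[p][hi] - cum_n[p][lo])
                means[p] = (
                    (cum[p][hi] - cum[p][lo]) / n_valid if n_valid else float("nan")
                )
            profiles.append(
                WindowProfile(
                    chrom=chrom,
                    start=start,
                    end=start + window_size - 1,
                    mean_divergence=means,
                    n_snps=hi - lo,
                )
            )
    return profiles


def classify_snp(
    snp: SnpCall,
    fixation_threshold: float = DEFAULT_FIXATION_THRESHOLD,
) -> SnpCategoryFlags:
    """Assign the seven allele-sharing category flags to one SNP.

    A pool counts as homozygous (fixed) when its minor-allele read fraction
    is at or below ``fixation_threshold``.  Missing SC coverage sets the
    missing flag and suppresses categories 1-5.
    """
    sc = snp.pools.get(SC_POOL)
    si = snp.pools.get(SI_POOL)
    missing_sc = sc is None or sc.depth == 0
    indel = snp.is_indel
    if missing_sc:
        return SnpCategoryFlags(False, False, False, False, False, True, indel)

    sc_fixed = sc.is_fixed(fixation_threshold)
    sc_allele = sc.major_allele
    al4_known = snp.al4_allele in NUCLEOTIDES
    si_covered = si is not None and si.depth > 0
    si_fixed = si_covered and si.is_fixed(fixation_threshold)

    flag1 = sc_fixed
    flag2 = flag1 and al4_known and si_covered and not si_fixed
    flag3 = flag1 and si_fixed and si.major_allele != sc_allele
    flag4 = flag2 and sc_allele == snp.al4_allele
    flag5 = flag1 and sc_allele == snp.ref_base
    return SnpCategoryFlags(flag1, flag2, flag3, flag4, flag5, False, indel)


def candidate_snp_filter(
    snps: list[SnpCall],
    fixation_threshold: float = DEFAULT_FIXATION_THRESHOLD,
) -> list[SnpCall]:
    """SNPs diagnostic for the SC phenotype.

    Retains non-indel sites where the SC pool is fixed on the AL4 allele,
    that allele differs from the MN47 reference, and the SI pool is
    polymorphic or fixed on a different allele.  Idempotent and monotone.
    """
    kept = []
    for snp in snps:
        if snp.is_indel:
            continue
        sc = snp.pools.get(SC_POOL)
        si = snp.pools.get(SI_POOL)
        if sc is None or sc.depth == 0 or si is None or si.depth == 0:
            continue
        if not sc.is_fixed(fixation_threshold):
            continue
        sc_allele = sc.major_allele
        if snp.al4_allele not in NUCLEOTIDES or sc_allele != snp.al4_allele:
            continue
        if sc_allele == snp.ref_base:
            continue
        if si.is_fixed(fixation_threshold) and si.major_allele == sc_allele:
            continue
        kept.append(snp)
    return kept


def detect_regions(
    profiles: list[WindowProfile],
    sc_max: float = DEFAULT_SC_MAX,
    si_min: float = DEFAULT_SI_MIN,
    min_windows: int = 10,
) -> list[RegionCall]:
    """Maximal runs of windows where SC is near-fixed and SI polymorphic.

    A window qualifies when it is non-empty, its SC mean divergence is at
    most ``sc_max`` and its SI mean at least ``si_min``.  Runs of at least
    ``min_windows`` consecutive windows are merged across their step overlap
    into one region, ranked by run length (descending), then SC mean
    (ascending), then (chrom, start).
    """
    regions: list[RegionCall] = []
    by_chrom: dict[str, list[WindowProfile]] = {}
    for w in profiles:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        wins = sorted(by_chrom[chrom], key=lambda w: w.start)
        run: list[WindowProfile] = []
        for w in wins + [None]:  # sentinel flushes the last run
            ok = (
                w is not None
                and w.n_snps > 0
                and not np.isnan(w.mean_divergence.get(SC_POOL, np.nan))
                and not np.isnan(w.mean_divergence.get(SI_POOL, np.nan))
                and w.mean_divergence[SC_POOL] <= sc_max
                and w.mean_divergence[SI_POOL] >= si_min
            )
            if ok:
                run.append(w)
                continue
            if len(run) >= min_windows:
                regions.append(
                    RegionCall(
                        chrom=chrom,
                        start=run[0].start,
                        end=run[-1].end,
                        n_windows=len(run),
                        sc_mean=float(
                            np.mean([x.mean_divergence[SC_POOL] for x in run])
                        ),
                        si_mean=float(
                            np.mean([x.mean_divergence[SI_POOL] for x in run])
                        ),
                    )
                )
            run = []
    regions.sort(key=lambda r: (-r.n_windows, r.sc_mean, r.chrom, r.start))
    return regions


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (1-based inclusive) with optional CDS sub-intervals."""

    name: str
    chrom: str
    start: int
    end: int
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def gene_summary(
    snps: list[SnpCall],
    genes: list[GeneAnnotation],
    fixation_threshold: float = DEFAULT_FIXATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene SNP counts and proportions of the seven category flags.

    A SNP falling in several genes is assigned to the shortest containing
    interval (deterministic nested-feature resolution).  Genes without SNPs
    get count 0 and NA proportions.
    """
    rows = []
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    assigned: dict[str, list[SnpCall]] = {g.name: [] for g in genes}
    for snp in snps:
        hits = [
            g
            for g in by_chrom.get(snp.chrom, [])
            if g.start <= snp.pos <= g.end
        ]
        if not hits:
            continue
        target = min(hits, key=lambda g: (g.length, g.name))
        assigned[target.name].append(snp)

    for g in genes:
        gene_snps = assigned[g.name]
        n = len(gene_snps)
        n_coding = sum(
            1
            for s in gene_snps
            if any(lo <= s.pos <= hi for lo, hi in g.cds)
        )
        row: dict[str, object] = {
            "gene": g.name,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "n_snps": n,
            "n_snps_coding": n_coding if g.cds else pd.NA,
        }
        if n == 0:
            for name in FLAG_NAMES:
                row[f"prop_{name}"] = float("nan")
        else:
            flags = [classify_snp(s, fixation_threshold).as_tuple() for s in gene_snps]
            arr = np.array(flags, dtype=float)
            for i, name in enumerate(FLAG_NAMES):
                row[f"prop_{name}"] = float(arr[:, i].mean())
        rows.append(row)
    return pd.DataFrame(rows)
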