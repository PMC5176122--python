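"""Estimation of S-allele diversity in population samples.

In a sporophytic self-incompatibility (SI) system the number of S-haplotypes
segregating in a population is a key quantity: it bounds mate availability and
shrinks sharply when a population shifts to inbreeding.  Screening assays
(allele-specific PCR panels) identify only a known set of SRK alleles, so a
sample of diploid individuals yields, per individual, zero, one or two
identified allele copies.  Heterozygosity at B80 — a gene flanking the S-locus
in strong linkage disequilibrium with SRK — is used to decide whether an
individual with a single amplified allele is a true homozygote or carries a
second, unidentified allele.

The total allele number N is estimated from the pattern of repeats in the
sample with the repeatability index

    N = n / (1 - (n - 2) / (m - 2))

where ``n`` is the number of distinct alleles identified and ``m`` the number
of gene copies sampled (2 x individuals).  When n = m (no repeats) the
estimate is unbounded and reported as an explicit flag.  Unidentified copies
enter as a bracket: the minimum assumes all of them are one shared novel
allele, the maximum assumes each is unique.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .util import mean_half_up, round_half_up

UNKNOWN = "?"

#: modes for individuals whose two B80 haplotypes both point to the single
#: identified SRK allele but come from distinct genetic backgrounds
SHARED_BACKGROUND_MODES = ("homozygous", "two_alleles")


@dataclass(frozen=True)
class SampleGenotype:
    """One individual's (possibly incomplete) S-locus genotype.

    ``srk_alleles`` holds the raw allele tokens: identified labels such as
    ``"S1"`` and the marker ``"?"`` for a copy known to exist but not
    identified.  A single token means only one allele amplified and the
    homozygote/missing-allele question is still open (resolved by
    :func:`infer_missing_alleles` from the B80 genotype).  More than two
    tokens can occur when an unlinked paralogue co-amplifies (e.g. S45); such
    labels are dropped through an exclusion list before tallying.
    """

    individual_id: str
    population: str
    srk_alleles: tuple[str, ...]
    b80_alleles: tuple[str, ...] = ()
    phenotype: str = "unknown"
    inferred_homozygous: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.srk_alleles) <= 3:
            raise ValueError(
                f"{self.individual_id}: expected 1-3 SRK allele tokens, "
                f"got {self.srk_alleles!r}"
            )
        if len(self.b80_alleles) > 2:
            raise ValueError(f"{self.individual_id}: >2 B80 haplotypes")

    @property
    def identified(self) -> tuple[str, ...]:
        return tuple(a for a in self.srk_alleles if a != UNKNOWN)

    @property
    def n_unknown(self) -> int:
        return sum(1 for a in self.srk_alleles if a == UNKNOWN)

    @property
    def is_resolved(self) -> bool:
        """True once the genotype holds exactly two copies (labels or ``?``)."""
        return len(self.srk_alleles) == 2

    def without_alleles(self, exclude: frozenset[str]) -> "SampleGenotype":
        if not exclude or not any(a in exclude for a in self.srk_alleles):
            return self
        kept = tuple(a for a in self.srk_alleles if a not in exclude)
        if not kept:
            kept = (UNKNOWN,)
        return replace(self, srk_alleles=kept)


@dataclass(frozen=True)
class B80LinkMap:
    """Known associations between B80 haplotypes and SRK alleles."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for hap, alleles in self.mapping.items():
            if not alleles:
                raise ValueError(f"B80 haplotype {hap!r} maps to an empty set")

    def __contains__(self, hap: str) -> bool:
        return hap in self.mapping

    def __getitem__(self, hap: str) -> frozenset[str]:
        return self.mapping[hap]


@dataclass(frozen=True)
class AlleleTally:
    """Per-population allele-copy counts over a sample of individuals.

    ``carriers_per_allele`` (individuals containing the allele, the incidence
    printed in survey tables) is filled by :func:`tally_population`; it is
    optional because a tally can also be reconstructed from published counts.
    """

    population: str
    n_individuals: int
    copies_per_allele: dict[str, int]
    missing_copies: int
    het_fraction: float
    homozygous_alleles: frozenset[str]
    carriers_per_allele: dict[str, int] | None = None

    @property
    def m(self) -> int:
        """Gene copies sampled: 2 per diploid individual."""
        return 2 * self.n_individuals

    @property
    def n_identified(self) -> int:
        return len(self.copies_per_allele)

    def __post_init__(self) -> None:
        if sum(self.copies_per_allele.values()) + self.missing_copies != self.m:
            raise ValueError(
                f"{self.population}: copies ({sum(self.copies_per_allele.values())}) "
                f"+ missing ({self.missing_copies}) != m ({self.m})"
            )
        if not 0 <= self.missing_copies <= self.m:
            raise ValueError("missing_copies out of range")


@dataclass(frozen=True)
class DiversityEstimate:
    """Bracketed repeatability-index estimate of the S-allele number."""

    population: str
    n_min: int
    n_max: int
    raw_min: float | None
    raw_max: float | None
    min_unbounded: bool = False
    max_unbounded: bool = False

    @property
    def rounded_min(self) -> int | None:
        return None if self.min_unbounded else int(round_half_up(self.raw_min))

    @property
    def rounded_max(self) -> int | None:
        return None if self.max_unbounded else int(round_half_up(self.raw_max))


@dataclass(frozen=True)
class PopulationMeta:
    """Mating-system metadata for one population."""

    population: str
    outcrossing_rate_tm: float
    cluster: str = ""
    mating_class: str = ""  # inbreeding | outcrossing | mixed
    exclude_from_tm_mean: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.outcrossing_rate_tm <= 1.0:
            raise ValueError(f"{self.population}: Tm outside [0, 1]")


@dataclass
class InferenceWarning:
    individual_id: str
    message: str


def infer_missing_alleles(
    genotypes: list[SampleGenotype],
    linkmap: B80LinkMap,
    shared_background: str = "homozygous",
    warnings_out: list[InferenceWarning] | None = None,
) -> list[SampleGenotype]:
    """Resolve single-allele genotypes using linked B80 heterozygosity.

    For an individual where only one SRK allele ``a`` amplified:

    * B80 homozygous -> called homozygous ``a/a``;
    * B80 heterozygous with both haplotypes known to associate with ``a``
      (same allele, two genetic backgrounds) -> homozygous ``a/a`` by default,
      or ``a/?`` under ``shared_background="two_alleles"``;
    * B80 heterozygous otherwise -> a second, unidentified copy ``a/?``;
    * B80 haplotype absent from the link map, or no B80 genotype -> the record
      is carried through unchanged and a warning is recorded.
    """
    if shared_background not in SHARED_BACKGROUND_MODES:
        raise ValueError(f"unknown shared_background mode {shared_background!r}")
    if warnings_out is None:
        warnings_out = []
    out: list[SampleGenotype] = []
    for g in genotypes:
        if len(g.srk_alleles) != 1 or g.srk_alleles[0] == UNKNOWN:
            out.append(g)
            continue
        allele = g.srk_alleles[0]
        if len(g.b80_alleles) != 2:
            warnings_out.append(
                InferenceWarning(g.individual_id, "no complete B80 genotype; left unresolved")
            )
            out.append(g)
            continue
        h1, h2 = g.b80_alleles
        if h1 not in linkmap or h2 not in linkmap:
            missing = [h for h in (h1, h2) if h not in linkmap]
            warnings_out.append(
                InferenceWarning(
                    g.individual_id,
                    f"B80 haplotype(s) {','.join(missing)} absent from link map",
                )
            )
            out.append(g)
            continue
        if h1 == h2:
            out.append(
                replace(g, srk_alleles=(allele, allele), inferred_homozygous=True)
            )
            continue
        s1, s2 = linkmap[h1], linkmap[h2]
        if allele in s1 and allele in s2:
            # both haplotypes compatible with homozygosity for `allele`
            if shared_background == "homozygous":
                out.append(
                    replace(g, srk_alleles=(allele, allele), inferred_homozygous=True)
                )
            else:
                out.append(replace(g, srk_alleles=(allele, UNKNOWN)))
        else:
            out.append(replace(g, srk_alleles=(allele, UNKNOWN)))
    return out


def tally_population(
    genotypes: list[SampleGenotype],
    exclude_alleles: frozenset[str] | set[str] = frozenset(),
) -> AlleleTally:
    """Count allele copies, missing copies and heterozygosity for one population.

    All genotypes must be resolved to two copies (run
    :func:`infer_missing_alleles` first for single-amplification records).
    A homozygote contributes 2 copies of its allele; an individual is counted
    heterozygous when its two copies are known to be distinct (two different
    labels, or one label plus an inferred-missing copy).
    """
    if not genotypes:
        raise ValueError("no individuals")
    pops = {g.population for g in genotypes}
    if len(pops) != 1:
        raise ValueError(f"genotypes span several populations: {sorted(pops)}")
    exclude = frozenset(exclude_alleles)

    copies: dict[str, int] = {}
    carriers: dict[str, int] = {}
    missing = 0
    het = 0
    homozygous: set[str] = set()
    for g in genotypes:
        g = g.without_alleles(exclude)
        if len(g.srk_alleles) > 2:
            raise ValueError(f"{g.individual_id}: ploidy violation")
        if len(g.srk_alleles) == 1:
            raise ValueError(
                f"{g.individual_id}: unresolved single-allele genotype; "
                "run infer_missing_alleles first"
            )
        a, b = g.srk_alleles
        for allele in (a, b):
            if allele == UNKNOWN:
                missing += 1
            else:
                copies[allele] = copies.get(allele, 0) + 1
        for allele in {a, b} - {UNKNOWN}:
            carriers[allele] = carriers.get(allele, 0) + 1
        if a != b:
            het += 1  # distinct labels, or label + inferred-missing copy
        elif a != UNKNOWN:
            homozygous.add(a)
    return AlleleTally(
        population=pops.pop(),
        n_individuals=len(genotypes),
        copies_per_allele=copies,
        missing_copies=missing,
        het_fraction=het / len(genotypes),
        homozygous_alleles=frozenset(homozygous),
        carriers_per_allele=carriers,
    )


def repeatability_estimate(n: int, m: int, literal: bool = False) -> float | None:
    """Repeatability-index estimate of the total allele number.

    Returns ``n / (1 - (n - 2)/(m - 2))``, or ``None`` when ``n == m``
    (every sampled copy distinct: the estimate is unbounded).  With
    ``literal=True`` the historically printed form ``1 - (n - 2)/(m - 2)``
    is returned unmodified for audit; it is not a usable allele-number
    estimator (it never exceeds ~1) and is kept only so the two forms can be
    compared.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m < 4:
        raise ValueError("m must be >= 4")
    if n > m:
        raise ValueError(f"n ({n}) cannot exceed gene copies m ({m})")
    repeat_fraction = 1.0 - (n - 2) / (m - 2)
    if literal:
        return repeat_fraction
    if repeat_fraction == 0.0:  # n == m: no repeated alleles observed
        return None
    return n / repeat_fraction


def bound_allele_number(tally: AlleleTally) -> DiversityEstimate:
    """Bracket the allele-number estimate over the unidentified copies.

    Minimum bound: all missing copies are one shared novel allele
    (n_min = n_identified + 1 if any are missing).  Maximum bound: every
    missing copy is a distinct novel allele (n_max = n_identified + missing).
    """
    n_min = tally.n_identified + (1 if tally.missing_copies > 0 else 0)
    n_max = tally.n_identified + tally.missing_copies
    raw_min = repeatability_estimate(n_min, tally.m)
    raw_max = repeatability_estimate(n_max, tally.m)
    return DiversityEstimate(
        population=tally.population,
        n_min=n_min,
        n_max=n_max,
        raw_min=raw_min,
        raw_max=raw_max,
        min_unbounded=raw_min is None,
        max_unbounded=raw_max is None,
    )


def summarize_populations(
    tallies: list[AlleleTally],
    estimates: list[DiversityEstimate],
    meta: list[PopulationMeta],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population report plus inbreeding/outcrossing group means.

    Group means of the allele-number bounds are arithmetic means of the
    rounded per-population integers, reported to 2 decimals (half-up).  Tm
    means skip populations flagged ``exclude_from_tm_mean``; mixed-mating
    populations belong to neither group.  Allele incidence proportions are
    fractions of individuals carrying each allele.
    """
    meta_by_pop = {m.population: m for m in meta}
    est_by_pop = {e.population: e for e in estimates}
    rows = []
    for tally in tallies:
        if tally.population not in meta_by_pop:
            raise ValueError(f"population {tally.population!r} missing from metadata")
        if tally.population not in est_by_pop:
            raise ValueError(f"population {tally.population!r} missing an estimate")
        pm = meta_by_pop[tally.population]
        est = est_by_pop[tally.population]
        rows.append(
            {
                "population": tally.population,
                "tm": pm.outcrossing_rate_tm,
                "cluster": pm.cluster,
                "mating_class": pm.mating_class,
                "n_individuals": tally.n_individuals,
                "m": tally.m,
                "n_identified": tally.n_identified,
                "missing_copies": tally.missing_copies,
                "het_fraction": tally.het_fraction,
                "homozygous": ",".join(sorted(tally.homozygous_alleles)) or "None",
                "min_alleles": est.rounded_min,
                "max_alleles": est.rounded_max,
                "min_unbounded": est.min_unbounded,
                "max_unbounded": est.max_unbounded,
            }
        )
    per_pop = pd.DataFrame(rows).sort_values("population").reset_index(drop=True)

    tally_by_pop = {t.population: t for t in tallies}
    all_alleles = sorted({a for t in tallies for a in t.copies_per_allele})
    group_rows = []
    for cls in ("inbreeding", "outcrossing"):
        pops = [r for r in rows if r["mating_class"] == cls]
        if not pops:
            continue
        mins = [r["min_alleles"] for r in pops if not r["min_unbounded"]]
        maxs = [r["max_alleles"] for r in pops if not r["max_unbounded"]]
        if len(mins) < len(pops) or len(maxs) < len(pops):
            warnings.warn(
                f"{cls}: unbounded estimates excluded from group means", stacklevel=2
            )
        tm_vals = [
            r["tm"]
            for r in pops
            if not meta_by_pop[r["population"]].exclude_from_tm_mean
        ]
        n_ind = sum(r["n_individuals"] for r in pops)
        row: dict[str, object] = {
            "mating_class": cls,
            "n_populations": len(pops),
            "mean_tm": mean_half_up(tm_vals, 2) if tm_vals else None,
            "mean_het": mean_half_up([r["het_fraction"] for r in pops], 2),
            "mean_min_alleles": mean_half_up(mins, 2) if mins else None,
            "mean_max_alleles": mean_half_up(maxs, 2) if maxs else None,
        }
        for allele in all_alleles:
            carriers = 0
            known = True
            for r in pops:
                t = tally_by_pop[r["population"]]
                if t.carriers_per_allele is None:
                    known = False
                    break
                carriers += t.carriers_per_allele.get(allele, 0)
            row[f"prop_{allele}"] = (
                round_half_up(carriers / n_ind, 2) if known else None
            )
        group_rows.append(row)
    return per_pop, pd.DataFrame(group_rows)
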