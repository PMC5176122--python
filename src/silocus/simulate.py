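"""Synthetic data generators for every pipeline stage.

Three generators, each emitting ground truth alongside the data:

* :func:`simulate_si_population` — diploid S-locus genotypes produced by
  compatibility-constrained random mating under a dominance hierarchy, for
  validating the allele-number estimator.
* :func:`simulate_partial_genotyping` — masks alleles outside a detection
  panel and emits linked B80 genotypes, emulating an allele-specific PCR
  screen with incomplete primer coverage.
* :func:`simulate_f2_bsa` — a biparental F2 mapping family segregating the
  S-locus and an unlinked recessive modifier of self-compatibility, pooled
  by phenotype and sequenced with binomial read sampling, for validating the
  bulked-segregant scan end to end.

Every generator is deterministic under its seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bsa import PoolCounts, SnpCall, SC_POOL, SI_POOL
from .diversity import B80LinkMap, SampleGenotype, UNKNOWN
from .genetics import (
    SC,
    SI,
    DominanceModel,
    PlantGenotype,
    is_compatible,
    phenotype_from_genotype,
)

_MAX_MATING_TRIES = 1000


def linear_hierarchy(alleles: tuple[str, ...]) -> DominanceModel:
    """Linear dominance hierarchy: each allele dominant over all earlier ones.

    The first allele is the bottom recessive (the S1 role); frequency skew in
    :func:`default_population_spec` puts the recessive alleles at the highest
    frequencies, the configuration negative frequency-dependent selection
    maintains in sporophytic SI populations.
    """
    pairs = {
        (alleles[j], alleles[i])
        for i in range(len(alleles))
        for j in range(i + 1, len(alleles))
    }
    return DominanceModel(pairs=frozenset(pairs), recessive_to_all=frozenset())


@dataclass(frozen=True)
class PopulationSimSpec:
    """Conditions for one simulated SI population sample."""

    alleles: tuple[str, ...]
    frequencies: tuple[float, ...]
    dominance: DominanceModel
    n_individuals: int = 8
    selfing_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.frequencies):
            raise ValueError("one frequency per allele required")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if len(self.alleles) < 3:
            raise ValueError("an SI population needs at least 3 S-alleles")


def default_population_spec(
    k: int,
    n_individuals: int = 8,
    seed: int = 0,
    frequency_ratio: float = 0.7,
) -> PopulationSimSpec:
    """Realistic default: K alleles in a linear dominance hierarchy.

    Frequencies follow a geometric series (ratio 0.7) with the most
    recessive allele most frequent — dominance shelters recessive alleles
    from expression, letting them segregate at higher frequency.
    """
    alleles = tuple(f"S{i + 1:02d}" for i in range(k))
    w = np.array([frequency_ratio**i for i in range(k)])
    freqs = tuple(float(x) for x in w / w.sum())
    return PopulationSimSpec(
        alleles=alleles,
        frequencies=freqs,
        dominance=linear_hierarchy(alleles),
        n_individuals=n_individuals,
        seed=seed,
    )


@dataclass
class PopulationTruth:
    """Ground truth emitted with a simulated population sample."""

    k: int
    allele_frequencies: dict[str, float]
    genotypes: list[tuple[str, str]]


def simulate_si_population(
    spec: PopulationSimSpec,
) -> tuple[list[SampleGenotype], PopulationTruth]:
    """Sample individuals produced by compatibility-constrained random mating.

    Each individual is the offspring of a random mating pair drawn from the
    allele frequencies and accepted only if the pollination is compatible
    under the dominance model (rejection sampling).  With probability
    ``selfing_probability`` a maternal self-fertilisation is forced instead
    (only meaningful for partially self-compatible scenarios).
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.array(spec.frequencies)
    k = len(spec.alleles)

    def draw_plant() -> PlantGenotype:
        i, j = rng.choice(k, size=2, p=freqs)
        return PlantGenotype(s_locus=(spec.alleles[i], spec.alleles[j]))

    genotypes: list[SampleGenotype] = []
    truth_genos: list[tuple[str, str]] = []
    for idx in range(spec.n_individuals):
        for _ in range(_MAX_MATING_TRIES):
            mother = draw_plant()
            if rng.random() < spec.selfing_probability:
                father = mother
            else:
                father = draw_plant()
                if not is_compatible(mother, father, spec.dominance):
                    continue
            child = (
                mother.s_locus[rng.integers(2)],
                father.s_locus[rng.integers(2)],
            )
            break
        else:
            raise RuntimeError("population not viable: rejection sampling cap hit")
        child = tuple(sorted(child))
        truth_genos.append(child)  # type: ignore[arg-type]
        genotypes.append(
            SampleGenotype(
                individual_id=f"sim{idx + 1:03d}",
                population="SIM",
                srk_alleles=child,
                phenotype="SI",
            )
        )
    truth = PopulationTruth(
        k=k,
        allele_frequencies=dict(zip(spec.alleles, spec.frequencies)),
        genotypes=truth_genos,
    )
    return genotypes, truth


def panel_linkmap(alleles: tuple[str, ...]) -> B80LinkMap:
    """One diagnostic B80 haplotype per S-allele (tight linkage, no sharing)."""
    return B80LinkMap({f"hap_{a}": frozenset({a}) for a in alleles})


def simulate_partial_genotyping(
    genotypes: list[SampleGenotype],
    panel: frozenset[str] | set[str],
    linkmap: B80LinkMap,
    seed: int = 0,
) -> list[SampleGenotype]:
    """Mask alleles undetectable by the screening panel.

    Identified copies keep their labels; off-panel copies disappear from the
    SRK genotype (single amplification) or become explicit unknowns when
    neither copy is detectable.  B80 genotypes are emitted from the link map
    so that downstream missing-allele inference can be validated against the
    truth.
    """
    if not panel:
        raise ValueError("detection panel is empty")
    hap_of = {next(iter(v)): h for h, v in linkmap.mapping.items() if len(v) == 1}
    observed: list[SampleGenotype] = []
    for g in genotypes:
        a, b = g.srk_alleles
        b80 = tuple(sorted(hap_of.get(x, f"hap_{x}") for x in (a, b)))
        seen = tuple(x for x in (a, b) if x in panel)
        if len(seen) == 2:
            srk = seen
        elif len(seen) == 1:
            srk = seen  # single amplification; resolved later via B80
        else:
            srk = (UNKNOWN, UNKNOWN)
        observed.append(
            SampleGenotype(
                individual_id=g.individual_id,
                population=g.population,
                srk_alleles=srk,
                b80_alleles=b80,
                phenotype=g.phenotype,
            )
        )
    return observed


# ---------------------------------------------------------------------------
# F2 bulked-segregant simulation


@dataclass(frozen=True)
class BsaSimSpec:
    """Conditions for the F2 bulked-segregant simulation.

    The design mirrors the mapping cross: two fully homozygous, fully
    divergent grandparental backgrounds (AL4-like, carrying S1 and the
    recessive modifier allele m; MN47-like, carrying other S-alleles and M),
    F1 sib-mating, phenotypes under scenario A, and phenotype-selected pools
    sequenced to a target depth.  The causal S-locus sits at 9.5 Mb on
    chromosome 7, the unlinked modifier on chromosome 5.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"5": 20_000_000, "7": 20_000_000}
    )
    snp_density: float = 5e-5
    causal_chrom: str = "7"
    causal_pos: int = 9_500_000
    modifier_chrom: str = "5"
    modifier_pos: int = 10_000_000
    n_f2: int = 400
    pool_size: int = 10
    depth_mean: float = 50.0
    error_rate: float = 0.001
    score_mean: float = 40.0
    score_sd: float = 3.0
    crossovers_per_meiosis: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.causal_pos > self.chrom_lengths[self.causal_chrom]:
            raise ValueError("causal position outside its chromosome")
        if self.modifier_pos > self.chrom_lengths[self.modifier_chrom]:
            raise ValueError("modifier position outside its chromosome")
        if self.pool_size > self.n_f2:
            raise ValueError("pool size exceeds family size")


@dataclass
class BsaTruth:
    """Ground truth emitted with a simulated pooled-SNP dataset."""

    causal_chrom: str
    causal_pos: int
    modifier_chrom: str
    modifier_pos: int
    phenotypes: list[str]
    sc_pool_indices: list[int]
    si_pool_indices: list[int]
    true_divergence: dict[str, dict[str, np.ndarray]]  # pool -> chrom -> frac
    snp_positions: dict[str, np.ndarray]


class _Gamete:
    """An F1 gamete: mosaic of grandparental ancestry along one genome.

    The F1 parents are heterozygous AL4/MN47 at every site, so a gamete is
    fully described per chromosome by a random starting phase and Poisson
    crossover breakpoints (expected ``crossovers_per_meiosis`` per
    chromosome, positions uniform).
    """

    __slots__ = ("phase", "breaks")

    def __init__(self, rng: np.random.Generator, chrom_lengths: dict[str, int], rate: float):
        self.phase: dict[str, int] = {}
        self.breaks: dict[str, np.ndarray] = {}
        for chrom, length in chrom_lengths.items():
            n_co = rng.poisson(rate)
            self.phase[chrom] = int(rng.integers(2))
            self.breaks[chrom] = np.sort(rng.integers(1, length + 1, size=n_co))

    def ancestry(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """0 = AL4-derived, 1 = MN47-derived at each position."""
        crossed = np.searchsorted(self.breaks[chrom], positions, side="left")
        return (self.phase[chrom] + crossed) % 2


def simulate_f2_bsa(spec: BsaSimSpec) -> tuple[list[SnpCall], BsaTruth]:
    """Simulate pooled SNP calls for an F2 family segregating for SC.

    Returns the SNP calls (MN47 as mapping reference, AL4 allele known at
    every site) and the ground truth, including each pool's analytic
    divergence-from-AL4 fraction per site.

    Raises ``RuntimeError`` when fewer SC plants arise than the SC pool
    needs — the real constraint of phenotype-selected pools.
    """
    rng = np.random.default_rng(spec.seed)

    # SNP positions per chromosome
    positions: dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        n = rng.poisson(length * spec.snp_density)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        positions[chrom] = pos

    # reference and AL4 alleles per site (always different bases)
    bases = np.array(["A", "C", "G", "T"])
    ref_alleles: dict[str, np.ndarray] = {}
    al4_alleles: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        ref_idx = rng.integers(4, size=pos.size)
        shift = rng.integers(1, 4, size=pos.size)
        ref_alleles[chrom] = bases[ref_idx]
        al4_alleles[chrom] = bases[(ref_idx + shift) % 4]

    # F2 individuals: two F1 gametes per individual
    gametes = [
        (
            _Gamete(rng, spec.chrom_lengths, spec.crossovers_per_meiosis),
            _Gamete(rng, spec.chrom_lengths, spec.crossovers_per_meiosis),
        )
        for _ in range(spec.n_f2)
    ]

    causal = np.array([spec.causal_pos])
    modif = np.array([spec.modifier_pos])
    phenotypes: list[str] = []
    for g1, g2 in gametes:
        s_anc = (
            int(g1.ancestry(spec.causal_chrom, causal)[0]),
            int(g2.ancestry(spec.causal_chrom, causal)[0]),
        )
        m_anc = (
            int(g1.ancestry(spec.modifier_chrom, modif)[0]),
            int(g2.ancestry(spec.modifier_chrom, modif)[0]),
        )
        # ancestry 0 carries S1 and m; ancestry 1 carries a dominant S-allele and M
        geno = PlantGenotype(
            s_locus=tuple("S1" if a == 0 else "S23" for a in s_anc),  # type: ignore[arg-type]
            modifier=tuple("m" if a == 0 else "M" for a in m_anc),  # type: ignore[arg-type]
        )
        phenotypes.append(phenotype_from_genotype(geno))

    sc_idx = [i for i, p in enumerate(phenotypes) if p == SC]
    si_idx = [i for i, p in enumerate(phenotypes) if p == SI]
    if len(sc_idx) < spec.pool_size:
        raise RuntimeError(
            f"insufficient SC plants: {len(sc_idx)} < pool size {spec.pool_size}"
        )
    sc_pool = list(rng.choice(sc_idx, size=spec.pool_size, replace=False))
    si_pool = list(rng.choice(si_idx, size=spec.pool_size, replace=False))

    # analytic pool divergence-from-AL4 = MN47-ancestry fraction per site
    true_div: dict[str, dict[str, np.ndarray]] = {SC_POOL: {}, SI_POOL: {}}
    for pool_name, members in ((SC_POOL, sc_pool), (SI_POOL, si_pool)):
        for chrom, pos in positions.items():
            total = np.zeros(pos.size)
            for i in members:
                g1, g2 = gametes[i]
                total += g1.ancestry(chrom, pos) + g2.ancestry(chrom, pos)
            true_div[pool_name][chrom] = total / (2 * len(members))

    # read sampling
    snps: list[SnpCall] = []
    for chrom, pos in positions.items():
        ref = ref_alleles[chrom]
        al4 = al4_alleles[chrom]
        pool_counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for pool_name in (SC_POOL, SI_POOL):
            f = true_div[pool_name][chrom]
            p_obs = f * (1 - spec.error_rate) + (1 - f) * spec.error_rate
            depth = rng.poisson(spec.depth_mean, size=pos.size)
            mn47_reads = rng.binomial(depth, p_obs)
            pool_counts[pool_name] = (depth, mn47_reads)
        scores = {
            p: rng.normal(spec.score_mean, spec.score_sd, size=pos.size)
            for p in (SC_POOL, SI_POOL)
        }
        for j in range(pos.size):
            pools = {}
            for pool_name in (SC_POOL, SI_POOL):
                depth, mn47_reads = pool_counts[pool_name]
                d, c = int(depth[j]), int(mn47_reads[j])
                counts = {}
                if c:
                    counts[str(ref[j])] = c
                if d - c:
                    counts[str(al4[j])] = d - c
                pools[pool_name] = PoolCounts(
                    depth=d, allele_counts=counts, score=float(scores[pool_name][j])
                )
            snps.append(
                SnpCall(
                    chrom=chrom,
                    pos=int(pos[j]),
                    ref_base=str(ref[j]),
                    al4_allele=str(al4[j]),
                    pools=pools,
                )
            )

    truth = BsaTruth(
        causal_chrom=spec.causal_chrom,
        causal_pos=spec.causal_pos,
        modifier_chrom=spec.modifier_chrom,
        modifier_pos=spec.modifier_pos,
        phenotypes=phenotypes,
        sc_pool_indices=[int(i) for i in sc_pool],
        si_pool_indices=[int(i) for i in si_pool],
        true_divergence=true_div,
        snp_positions=positions,
    )
    return snps, truth
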