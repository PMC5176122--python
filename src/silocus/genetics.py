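"""Sporophytic self-incompatibility genetics.

In a sporophytic SI system the specificity a plant presents — on both the
stigma and the pollen coat — is determined by its diploid genotype at the
S-locus, subject to dominance between S-alleles.  A pollination fails when
the pollen parent's expressed specificities intersect the pistil parent's.

Self-compatibility (SC) is modelled under "scenario A": a recessive modifier
locus, unlinked to the S-locus, abolishes the SI response only in plants that
are homozygous for the recessive allele S1 *and* homozygous for the recessive
modifier allele ``m``.  This reproduces the two observations the model rests
on: every SC segregant is an S1 homozygote, but not every S1 homozygote is SC.

The module also provides cross simulation over the two loci (with optional
viability distortion against S1), silique-count phenotype classification, and
Pearson chi-square segregation tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import product

import numpy as np
from scipy import stats

S1 = "S1"
MODIFIER_ALLELES = ("M", "m")

# phenotype labels
SC, SI, LEAKY, MALE_STERILE, AMBIGUOUS, UNKNOWN = (
    "SC",
    "SI",
    "leaky",
    "male_sterile",
    "ambiguous",
    "unknown",
)


@dataclass(frozen=True)
class DominanceModel:
    """Partial order over S-alleles: ``(dominant, recessive)`` pairs.

    ``recessive_to_all`` lists alleles masked by every other allele; by
    default only S1, the one relation with direct experimental support.
    Pairs not ordered by either mechanism act codominantly.
    """

    pairs: frozenset[tuple[str, str]] = frozenset()
    recessive_to_all: frozenset[str] = frozenset({S1})

    def __post_init__(self) -> None:
        for dom, rec in self.pairs:
            if dom == rec:
                raise ValueError(f"irreflexivity violated: {dom} > {dom}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph: dict[str, set[str]] = {}
        for dom, rec in self.pairs:
            graph.setdefault(dom, set()).add(rec)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in graph.get(node, ()):
                if state.get(nxt) == 1:
                    raise ValueError("dominance relation contains a cycle")
                if state.get(nxt, 0) == 0:
                    visit(nxt)
            state[node] = 2

        for node in list(graph):
            if state.get(node, 0) == 0:
                visit(node)

    def dominates(self, a: str, b: str) -> bool:
        if a == b:
            return False
        if (a, b) in self.pairs:
            return True
        if (b, a) in self.pairs:
            return False
        return b in self.recessive_to_all and a not in self.recessive_to_all


DEFAULT_DOMINANCE = DominanceModel()


def _sorted_pair(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PlantGenotype:
    """S-locus diplotype plus unlinked modifier diplotype."""

    s_locus: tuple[str, str]
    modifier: tuple[str, str] = ("M", "M")
    viability_weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.s_locus) != 2 or len(self.modifier) != 2:
            raise ValueError("each locus carries exactly two alleles")
        if any(a not in MODIFIER_ALLELES for a in self.modifier):
            raise ValueError(f"modifier alleles must be in {MODIFIER_ALLELES}")
        if self.viability_weight <= 0:
            raise ValueError("viability_weight must be positive")
        object.__setattr__(self, "s_locus", _sorted_pair(self.s_locus))
        object.__setattr__(self, "modifier", _sorted_pair(self.modifier))

    @property
    def si_functional(self) -> bool:
        """Scenario A: SI lost only in S1/S1; m/m plants."""
        return not (self.s_locus == (S1, S1) and self.modifier == ("m", "m"))

    @classmethod
    def parse(cls, text: str) -> "PlantGenotype":
        """Parse ``"S1/Sx:Mm"`` (modifier part optional, defaults M/M)."""
        if ":" in text:
            s_part, m_part = text.split(":", 1)
            if "/" in m_part:
                m_alleles = tuple(m_part.split("/"))
            else:
                m_alleles = tuple(m_part)
        else:
            s_part, m_alleles = text, ("M", "M")
        s_alleles = tuple(s_part.split("/"))
        if len(s_alleles) != 2 or len(m_alleles) != 2:
            raise ValueError(f"cannot parse genotype {text!r}")
        return cls(s_locus=s_alleles, modifier=m_alleles)  # type: ignore[arg-type]


@dataclass(frozen=True)
class SiliqueRecord:
    """Fruit-set outcomes of replicated self-pollinations of one plant."""

    full: int
    partial: int
    empty: int

    def __post_init__(self) -> None:
        if min(self.full, self.partial, self.empty) < 0:
            raise ValueError("silique counts must be non-negative")

    @property
    def total(self) -> int:
        return self.full + self.partial + self.empty


@dataclass(frozen=True)
class SegregationResult:
    observed: dict[str, int]
    expected_proportions: dict[str, float]
    chi_square: float
    df: int
    p_value: float


def expressed_specificities(
    genotype: PlantGenotype,
    dominance: DominanceModel = DEFAULT_DOMINANCE,
    side: str = "pistil",
) -> frozenset[str]:
    """Specificities a plant presents on the given side.

    Sporophytic on both sides, so ``side`` does not change the rule; it is
    kept for symmetry with systems where male and female dominance differ.
    """
    if side not in ("pistil", "pollen"):
        raise ValueError(f"side must be 'pistil' or 'pollen', got {side!r}")
    a, b = genotype.s_locus
    if a == b:
        return frozenset({a})
    if dominance.dominates(a, b):
        return frozenset({a})
    if dominance.dominates(b, a):
        return frozenset({b})
    return frozenset({a, b})


def is_compatible(
    mother: PlantGenotype,
    father: PlantGenotype,
    dominance: DominanceModel = DEFAULT_DOMINANCE,
) -> bool:
    """Whether pollen from ``father`` can fertilise ``mother``.

    An SI-functional mother rejects pollen whose expressed specificities
    overlap her own; a mother without functional SI accepts everything.
    """
    if not mother.si_functional:
        return True
    pistil = expressed_specificities(mother, dominance, "pistil")
    pollen = expressed_specificities(father, dominance, "pollen")
    return not (pistil & pollen)


def simulate_cross(
    mother: PlantGenotype,
    father: PlantGenotype,
    n_offspring: int,
    seed: int | np.random.Generator,
    dominance: DominanceModel = DEFAULT_DOMINANCE,
    override_incompatibility: bool = False,
    s1_selection: float = 0.0,
    selection_mode: str = "zygote",
) -> list[PlantGenotype]:
    """Draw offspring of a cross, one allele per parent per locus, unlinked.

    ``s1_selection`` applies a viability distortion of strength ``s`` against
    S1: in ``"gamete"`` mode an S1-carrying gamete is transmitted with
    relative weight ``1 - s``; in ``"zygote"`` mode a zygote survives with
    probability ``(1 - s) ** (number of S1 copies)``.  Both are exposed
    because segregation data cannot distinguish them.
    """
    if not is_compatible(mother, father, dominance) and not override_incompatibility:
        raise ValueError("cross rejected by SI")
    if not 0.0 <= s1_selection < 1.0:
        raise ValueError("s1_selection must be in [0, 1)")
    if selection_mode not in ("gamete", "zygote"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def gamete_probs(pair: tuple[str, str]) -> np.ndarray:
        if selection_mode == "gamete" and s1_selection > 0:
            w = np.array([1.0 - s1_selection if a == S1 else 1.0 for a in pair])
            return w / w.sum()
        return np.array([0.5, 0.5])

    offspring: list[PlantGenotype] = []
    mom_s_p, dad_s_p = gamete_probs(mother.s_locus), gamete_probs(father.s_locus)
    zygote_sel = selection_mode == "zygote" and s1_selection > 0
    while len(offspring) < n_offspring:
        k = n_offspring - len(offspring)
        ms = rng.choice(2, size=k, p=mom_s_p)
        fs = rng.choice(2, size=k, p=dad_s_p)
        mm = rng.integers(2, size=k)
        fm = rng.integers(2, size=k)
        u = rng.random(k) if zygote_sel else None
        for j in range(k):
            s_pair = (mother.s_locus[ms[j]], father.s_locus[fs[j]])
            if zygote_sel:
                n_s1 = sum(1 for a in s_pair if a == S1)
                if n_s1 and u[j] > (1.0 - s1_selection) ** n_s1:
                    continue
            offspring.append(
                PlantGenotype(
                    s_locus=s_pair,
                    modifier=(mother.modifier[mm[j]], father.modifier[fm[j]]),
                )
            )
    return offspring


def phenotype_from_genotype(
    genotype: PlantGenotype,
    model: str = "scenarioA",
    male_sterility_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Selfing phenotype under scenario A, with optional sterility masking.

    Male sterility has no genetic model in this framework; it is an
    independent masking event at the given rate (default 0), reflecting that
    a sterile plant's selfing phenotype cannot be scored.
    """
    if model != "scenarioA":
        raise ValueError(f"unknown model {model!r}")
    if male_sterility_rate > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        if rng.random() < male_sterility_rate:
            return MALE_STERILE
    return SC if not genotype.si_functional else SI


def classify_selfing_phenotype(record: SiliqueRecord) -> str:
    """Classify a plant from self-pollination fruit set.

    Generalises the 5-of-6 rule proportionally: SC when at least 5/6 of
    pollinations give full siliques, SI when at least 5/6 give empty ones,
    leaky when two or more show partial development and neither rule fires,
    else ambiguous.
    """
    total = record.total
    if total < 6:
        raise ValueError("insufficient pollinations (need at least 6)")
    threshold = math.ceil(5 * total / 6)
    if record.full >= threshold:
        return SC
    if record.empty >= threshold:
        return SI
    if record.partial >= 2:
        return LEAKY
    return AMBIGUOUS


def expected_f2_segregation(
    mother: PlantGenotype,
    father: PlantGenotype,
    model: str = "scenarioA",
    dominance: DominanceModel = DEFAULT_DOMINANCE,
) -> dict[tuple[tuple[str, str], tuple[str, str], str], Fraction]:
    """Exact offspring distribution over (S genotype, modifier genotype, phenotype).

    Exhaustive enumeration of the 4 x 4 equi-probable gamete combinations of
    the two unlinked loci; probabilities are exact fractions summing to 1.
    """
    if not is_compatible(mother, father, dominance):
        raise ValueError("cross rejected by SI")
    dist: dict[tuple[tuple[str, str], tuple[str, str], str], Fraction] = {}
    cell = Fraction(1, 16)
    for ms, mm, fs, fm in product(range(2), repeat=4):
        s_pair = _sorted_pair((mother.s_locus[ms], father.s_locus[fs]))
        mod_pair = _sorted_pair((mother.modifier[mm], father.modifier[fm]))
        geno = PlantGenotype(s_locus=s_pair, modifier=mod_pair)
        phen = phenotype_from_genotype(geno, model=model)
        key = (s_pair, mod_pair, phen)
        dist[key] = dist.get(key, Fraction(0)) + cell
    assert sum(dist.values()) == 1
    return dist


def segregation_chi_square(
    observed: dict[str, int],
    expected_proportions: dict[str, float],
) -> SegregationResult:
    """Pearson goodness-of-fit test of observed class counts."""
    if set(observed) != set(expected_proportions):
        raise ValueError("observed and expected classes differ")
    if any(c < 0 for c in observed.values()):
        raise ValueError("negative observed count")
    total = sum(observed.values())
    if total == 0:
        raise ValueError("no observations")
    if abs(sum(expected_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    classes = sorted(observed)
    for c in classes:
        if expected_proportions[c] == 0 and observed[c] > 0:
            raise ValueError(f"class {c!r} has expected proportion 0 but was observed")
    obs = np.array([observed[c] for c in classes], dtype=float)
    exp = np.array([expected_proportions[c] * total for c in classes])
    keep = exp > 0
    chi2, p = stats.chisquare(obs[keep], exp[keep], ddof=0)
    df = int(keep.sum()) - 1
    return SegregationResult(
        observed=dict(observed),
        expected_proportions=dict(expected_proportions),
        chi_square=float(chi2),
        df=df,
        p_value=float(p),
    )
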