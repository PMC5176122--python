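"""High-level pipeline entry points shared by the CLI and scripts."""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .diversity import (
    InferenceWarning,
    bound_allele_number,
    infer_missing_alleles,
    summarize_populations,
    tally_population,
)
from .io import read_genotype_table, read_linkmap, read_population_meta

#: alleles amplified by the screening assay but unlinked to the SI phenotype
DEFAULT_EXCLUDE_ALLELES = frozenset({"S45"})


def packaged_fixture(name: str) -> Path:
    """Path to a packaged survey fixture (genotypes, link map, metadata)."""
    return Path(str(resources.files("silocus.data").joinpath(name)))


def diversity_report(
    genotypes_path: str | Path,
    linkmap_path: str | Path,
    meta_path: str | Path,
    exclude_alleles: frozenset[str] = DEFAULT_EXCLUDE_ALLELES,
    shared_background: str = "homozygous",
) -> tuple[pd.DataFrame, pd.DataFrame, list[InferenceWarning]]:
    """Full S-allele diversity pipeline: read, infer, tally, bound, summarise.

    Returns the per-population report, the mating-class group means, and any
    inference warnings (B80 haplotypes absent from the link map, individuals
    left unresolved).
    """
    genotypes = read_genotype_table(genotypes_path, exclude_alleles=exclude_alleles)
    linkmap = read_linkmap(linkmap_path)
    meta = read_population_meta(meta_path)

    warnings_out: list[InferenceWarning] = []
    by_pop: dict[str, list] = {}
    for g in genotypes:
        by_pop.setdefault(g.population, []).append(g)

    tallies = []
    estimates = []
    for pop in sorted(by_pop):
        resolved = infer_missing_alleles(
            by_pop[pop],
            linkmap,
            shared_background=shared_background,
            warnings_out=warnings_out,
        )
        tally = tally_population(resolved, exclude_alleles=exclude_alleles)
        tallies.append(tally)
        estimates.append(bound_allele_number(tally))
    per_pop, groups = summarize_populations(tallies, estimates, meta)
    return per_pop, groups, warnings_out
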