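import pytest
from hypothesis import HealthCheck, settings

from silocus.pipeline import packaged_fixture

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_paths():
    """Packaged population-survey fixtures (genotypes, B80 link map, metadata)."""
    return {
        "genotypes": packaged_fixture("table1_genotypes.tsv"),
        "linkmap": packaged_fixture("table1_linkmap.tsv"),
        "meta": packaged_fixture("table1_meta.tsv"),
    }


@pytest.fixture(scope="session")
def survey_report(survey_paths):
    from silocus.pipeline import diversity_report

    per_pop, groups, warns = diversity_report(
        survey_paths["genotypes"], survey_paths["linkmap"], survey_paths["meta"]
    )
    return per_pop, groups, warns
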