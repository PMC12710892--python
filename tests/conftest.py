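import pytest

from strainmatch import (
    CohortConfig,
    generate_cohort,
    normalise_by_species_median,
    pairwise_species_distances,
)


@pytest.fixture(scope="session")
def clean_cohort():
    """Recovery-regime cohort: no shared lineages, full detection."""
    config = CohortConfig(
        seed=11,
        donor_efficiency=0.3,
        p_shared_lineage=0.0,
        detection_rate=1.0,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def clean_distances(clean_cohort):
    return normalise_by_species_median(
        pairwise_species_distances(clean_cohort.alignments)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-like defaults: background lineage sharing, depth dropout."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_distances(default_cohort):
    return normalise_by_species_median(
        pairwise_species_distances(default_cohort.alignments)
    )
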