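import pytest
from hypothesis import settings

from dyadshift.io_tables import MetadataTable, SampleMetadata

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from dyadshift.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_families=4,
        n_species=6,
        n_genes_per_species=60,
        transmission_probability=0.4,
        alignment_length=800,
        n_pathways=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A small synthetic cohort shared across tests (read-only)."""
    return generate_cohort(small_config)


@pytest.fixture
def dyad_metadata():
    """Two families, one mother and one infant each."""
    return MetadataTable(
        [
            SampleMetadata("F01M", "F01", "mother", "exclusive", "SiteA"),
            SampleMetadata("F01I", "F01", "infant", "exclusive", "SiteA"),
            SampleMetadata("F02M", "F02", "mother", "partial", "SiteB"),
            SampleMetadata("F02I", "F02", "infant", "partial", "SiteB"),
        ]
    )
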