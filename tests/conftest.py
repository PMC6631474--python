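import pytest

from pccomp import (
    assemble_constituent_catalog,
    default_humet_config,
    load_reference,
    simulate_paired_cohort,
)


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def catalogs(reference):
    """Catalogs for the 38 reference sums with the 69 constituents mapped."""
    return assemble_constituent_catalog(
        reference.sum_labels, list(reference.frame.constituent_label)
    )


@pytest.fixture(scope="session")
def humet_cohort(reference):
    """One seeded deep multi-timepoint cohort shared by read-only tests."""
    config = default_humet_config(reference, seed=2024)
    species, fa, truth = simulate_paired_cohort(config)
    return config, species, fa, truth
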