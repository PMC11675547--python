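import pytest

from varpoints.model import (
    Consequence,
    VariantRecord,
)
from varpoints.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-variant seeded cohort shared by the cheaper stage tests."""
    return generate_cohort(CohortSpec(n_variants=40, seed=7))


@pytest.fixture
def missense_variant():
    return VariantRecord(
        variant_id="v1",
        gene="BRCA1",
        hgvs_c="c.5408G>C",
        hgvs_p="p.Gly1803Ala",
        protein_position=1803,
        consequence=Consequence.MISSENSE,
    )
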