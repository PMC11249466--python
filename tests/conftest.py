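import pytest

from gripcalc import (
    CoefficientTable,
    cohort_frame,
    default_spec,
    example_coefficients,
    generate,
)


@pytest.fixture(scope="session")
def identity_coeffs():
    return CoefficientTable.identity()


@pytest.fixture(scope="session")
def example_coeffs():
    return example_coefficients()


@pytest.fixture(scope="session")
def study_cohort():
    """A study-sized synthetic cohort (190 records, seeded)."""
    return generate(default_spec(), seed=20170701)


@pytest.fixture(scope="session")
def study_frame(study_cohort):
    return cohort_frame(study_cohort)
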