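import pytest

from fiq16 import load_codebook, load_composition
from fiq16.scoring import example_fat_response
from fiq16.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def codebook():
    return load_codebook()


@pytest.fixture(scope="session")
def composition():
    return load_composition()


@pytest.fixture(scope="session")
def example_response(codebook):
    return example_fat_response(codebook)


@pytest.fixture(scope="session")
def small_cohort(codebook, composition):
    """A 30-participant synthetic paired cohort, fixed seed."""
    return generate_cohort(CohortSpec(n=30, seed=42), codebook, composition)
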