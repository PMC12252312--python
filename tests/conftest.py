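import pytest

from lipidprs import default_simspec, simulate_cohort


@pytest.fixture(scope="session")
def spec5584():
    """Study-scale default generator specification (n = 5584)."""
    return default_simspec(n_subjects=5584, seed=20)


@pytest.fixture(scope="session")
def cohort5584(spec5584):
    """One study-scale synthetic cohort: (genotypes, phenotypes)."""
    return simulate_cohort(spec5584)
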