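import pytest
from hypothesis import settings

import snpmeta as sm

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def table1() -> sm.StudyTable:
    """The packaged 48-study KCNJ11 E23K / T2D table."""
    return sm.load_table1()


@pytest.fixture(scope="session")
def allele_ests(table1):
    """Allele-contrast estimates reconstructed from the fixture's MAFs."""
    return sm.allele_estimates(table1)


@pytest.fixture(scope="session")
def genotype_table():
    """A synthetic collection carrying HWE genotype counts and trio data."""
    cfg = sm.SimulationConfig(seed=42, k_studies=30, genotype_mode=True, k_trios=4)
    return sm.simulate_studies(cfg)
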