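import pytest

from florin.simulate import SimulationDesign
from florin.types import Thresholds


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture
def small_design() -> SimulationDesign:
    """A fast design for layout/sequence tests."""
    return SimulationDesign(seed=42, n_mrna=10, n_lncrna=10, n_mirna=5,
                            chrom_len=1_500_000, cis_fraction=0.5, n_snps=60)
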