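import numpy as np
import pytest

from condlab import ConditioningTable, SimConfig, simulate_conditioning


@pytest.fixture
def small_table():
    return ConditioningTable(cs1=[3.0, 5.0, 4.0], cs2=[1.0, 2.0, 3.0])


@pytest.fixture
def acq_like_table():
    """A 40-subject table whose paired t is moderate, like an acquisition phase."""
    return simulate_conditioning(SimConfig(n=40, mu1=0.5, mu2=0.0, sigma=1.0, rho=0.5, seed=7))


@pytest.fixture
def grouped_table():
    return simulate_conditioning(
        SimConfig(n=20, mu1=1.0, mu2=0.0, groups=2, mu1_g2=0.2, mu2_g2=0.0, seed=11)
    )


@pytest.fixture
def write_csv(tmp_path):
    def _write(df, name="data.csv", **kwargs):
        path = tmp_path / name
        df.to_csv(path, index=False, **kwargs)
        return str(path)

    return _write
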