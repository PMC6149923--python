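import numpy as np
import pytest

from synabm.agents import PhenotypeParams
from synabm.engine import SimulationConfig
from synabm.microenvironment import DrugField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noop_config():
    """No death channels, no proliferation: population must stay frozen."""
    return SimulationConfig(
        phenotype=PhenotypeParams(lam=0.0, c1=0.0, c2=0.0,
                                  theta=(0.0, 0.0, 0.0), p_pro=0.0),
        n_per_axis=30, n_cells=50, horizon_steps=30, seed=7)


@pytest.fixture
def decline_rise_config():
    """Short-half-life drug pair with death parameters in the calibrated
    range: mortality dominates while the drugs are present, regrowth
    takes over once they have decayed."""
    return SimulationConfig(
        drugs=(DrugField("drugA", 10.0, 3.5), DrugField("drugB", 10.0, 18.0)),
        phenotype=PhenotypeParams(lam=1.0, c1=0.01, c2=0.3,
                                  theta=(0.0006, 0.0085, 0.0101), p_pro=0.8),
        horizon_steps=100, seed=5)
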