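import numpy as np
import pytest

from paintkinetics import BindingRates, SimulationConfig, simulate_ensemble
from paintkinetics.units import nM

#: Table-1-style conventional-imager rate constants used as ground truth
CONVENTIONAL = BindingRates(ka=1.49e6, kd=0.303)
REFERENCE = BindingRates(ka=1.5e6, kd=0.3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_ensemble():
    """A stationary (no depletion) ensemble shared by read-only tests."""
    cfg = SimulationConfig(
        rates=REFERENCE,
        concentration=nM(10),
        n_origami=20,
        sites_per_origami=12,
        exposure=0.2,
        n_frames=5100,
        seed=101,
    )
    return simulate_ensemble(cfg)


@pytest.fixture(scope="session")
def depleting_ensemble():
    """An ensemble with a fast depletion clock so decay is visible quickly."""
    cfg = SimulationConfig(
        rates=REFERENCE,
        concentration=nM(100),
        delta=1e-3,
        n_origami=400,
        sites_per_origami=1,
        exposure=2.0,
        n_frames=4000,
        seed=202,
    )
    return simulate_ensemble(cfg)
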