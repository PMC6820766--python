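import numpy as np
import pytest

from cmsa import NetworkParams, SimConfig, run_simulation


@pytest.fixture(scope="session")
def small_spont_record():
    """One small spontaneous run shared by raster-level tests (N=64)."""
    cfg = SimConfig(params=NetworkParams(N=64), duration_ms=2500.0,
                    transient_ms=1500.0, seed=7)
    return run_simulation(cfg)


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same fresh stream regardless
    # of execution order
    return np.random.default_rng(1234)
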