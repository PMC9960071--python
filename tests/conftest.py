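import pytest

from kflux.simulate import HopModelConfig, gen_ion_trajectory


@pytest.fixture(scope="session")
def hop_trajectory():
    """One default hopping trajectory with truth log (reused: ~0.3 s)."""
    cfg = HopModelConfig(duration_ns=250.0, seed=7)
    tracks, truth = gen_ion_trajectory(cfg)
    return cfg, tracks, truth
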