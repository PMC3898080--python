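import numpy as np
import pytest

from fiberdyn.distributions import DistributionSpec
from fiberdyn.repsim import PulseScheme, Scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_scenario():
    """Factory for small, fully-controlled scenarios."""

    def _make(**overrides):
        kwargs = dict(
            name="test",
            region_length=1000.0,
            origin_spacing=DistributionSpec("fixed", mean=175.0),
            firing_time=DistributionSpec("fixed", mean=0.0),
            fork_velocity=DistributionSpec("fixed", mean=2.0),
            sister_noise_sd=0.0,
            stall_rate=0.0,
            pulses=PulseScheme(),
            fiber_length=DistributionSpec("fixed", mean=1000.0),
            detection_limit=1.0,
            kb_per_um=2.0,
            n_molecules=1,
            seed=0,
        )
        kwargs.update(overrides)
        return Scenario(**kwargs)

    return _make
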