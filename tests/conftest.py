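import numpy as np
import pytest

from usvsong import PixelTrace, SynthesisConfig, builtin_profiles


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def gerf(profiles):
    return profiles["GER/f"]


@pytest.fixture
def quiet_cfg():
    """Synthesis without frequency jitter: contours are exactly the templates."""
    return SynthesisConfig(noise_sd_khz=0.0)


def make_trace(freqs, dt=0.5, t0=0.0, amps=None, element_id="e", channel="ch0"):
    """Uniformly sampled trace from a frequency list (helper, not a fixture)."""
    freqs = np.asarray(freqs, dtype=float)
    n = freqs.size
    if amps is None:
        amps = np.ones(n)
    return PixelTrace(times_ms=t0 + dt * np.arange(n), freqs_khz=freqs,
                      amps=np.asarray(amps, dtype=float),
                      element_id=element_id, channel=channel)
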