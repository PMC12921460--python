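import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import isopupil as ip

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def timeline():
    return ip.build_timeline()


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, blink-free, jitter-free session parameters."""
    return ip.SimulationParams(
        noise_sd_mm=0.0,
        blink_rate_hz=0.0,
        hippus_amplitude_mm=0.0,
        timestamp_jitter_s=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_session(clean_params, timeline):
    return ip.simulate_session(clean_params, timeline)


@pytest.fixture(scope="session")
def default_session(timeline):
    """One session at the default (noisy, blinking) parameters."""
    return ip.simulate_session(ip.SimulationParams(seed=11), timeline)


def random_trace_frame(rng, n):
    """A random but valid canonical-format data frame with missing values."""
    t = np.cumsum(rng.uniform(0.005, 0.02, n))
    t -= t[0]
    df = pd.DataFrame(
        {
            "t_s": t,
            "left_mm": rng.uniform(2.0, 8.0, n),
            "right_mm": rng.uniform(2.0, 8.0, n),
            "left_open": rng.uniform(0.0, 1.0, n),
            "right_open": rng.uniform(0.0, 1.0, n),
            "gaze_x": rng.normal(0.5, 0.1, n),
            "gaze_y": rng.normal(0.5, 0.1, n),
        }
    )
    for col in ("left_mm", "right_mm", "left_open", "right_open", "gaze_x", "gaze_y"):
        df.loc[rng.random(n) < 0.1, col] = np.nan
    return df
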