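import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsasync import (GeneratorConfig, NoiseConfig, ParticipantProfile,
                     generate_beats, render_ppg)
from rsasync.protocol import DEFAULT_PROTOCOL
from rsasync.synth_ppg import ground_truth_for

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def quiet_cfg():
    """Generator configuration with every noise source disabled."""
    return GeneratorConfig(noise=NoiseConfig.zero())


@pytest.fixture(scope="session")
def paced_profile():
    return ParticipantProfile(id="T01", age_years=9, baseline_hr=90.0,
                              rsa_amp=12.0, resp_mode="paced", seed=11)


@pytest.fixture(scope="session")
def clean_paced_recording(paced_profile, protocol):
    """120-s noise-free paced recording with its exact beats and truth."""
    beats = generate_beats(paced_profile, protocol, 120.0)
    rec = render_ppg(beats, 100.0, NoiseConfig.zero(), 120.0,
                     meta={"id": paced_profile.id, "mode": "paced",
                           "age_years": paced_profile.age_years})
    truth = ground_truth_for(paced_profile, protocol, beats, 120.0)
    return rec, beats, truth


def constant_rate_beats(bpm: float, duration: float) -> np.ndarray:
    """Exactly periodic beats at a constant rate (test helper)."""
    ibi = 60.0 / bpm
    return np.arange(ibi, duration + ibi / 2, ibi)
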