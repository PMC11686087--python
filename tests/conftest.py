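import numpy as np
import pytest
from hypothesis import settings

from pwavekit.synth import SynthEcgSpec, default_p_specs, generate_ecg

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def clean_spec(heart_rate_bpm=60.0, duration_ms=120.0, n_beats=22, seed=0, **kw):
    """Noise-free, wander-free ECG spec with uniform per-lead P durations."""
    rr = 60.0 / heart_rate_bpm
    return SynthEcgSpec(
        heart_rate_bpm=heart_rate_bpm,
        duration_s=0.5 + (n_beats + 1) * rr + 0.5,
        noise_sd_mv=0.0,
        baseline_wander_amplitude_mv=0.0,
        p_waves=default_p_specs(duration_ms=duration_ms, duration_spread=0.0),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def clean_record_and_truth():
    """One clean 60 bpm record with 120 ms P waves, plus ground truth."""
    return generate_ecg(clean_spec())


@pytest.fixture(scope="session")
def noisy_record_and_truth():
    """A record with the default noise and baseline wander levels."""
    spec = SynthEcgSpec(duration_s=23.0, seed=11)
    return generate_ecg(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
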