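import numpy as np
import pytest

from clutchvibe.signal_io import RecordingMeta
from clutchvibe.synthetic_signals import SyntheticSpec, generate_recording
from clutchvibe.windowing import Window


@pytest.fixture
def slow_mode_spec() -> SyntheticSpec:
    """Soft-clutch-like mode: 25.65 Hz, tau 0.10 s, noise-free by default."""
    return SyntheticSpec(
        frequency_hz=25.65,
        tau_s=0.10,
        sample_rate_hz=4000.0,
        pre_s=0.05,
        impact_s=0.03,
        free_s=0.30,
        post_s=0.10,
        noise_sd=0.0,
        impact_gain=5.0,
    )


@pytest.fixture
def fast_mode_spec() -> SyntheticSpec:
    """Stiff-clutch-like mode: 105.15 Hz, tau 0.02 s."""
    return SyntheticSpec(
        frequency_hz=105.15,
        tau_s=0.02,
        sample_rate_hz=4000.0,
        pre_s=0.05,
        impact_s=0.03,
        free_s=0.06,
        post_s=0.05,
        noise_sd=0.0,
        impact_gain=5.0,
    )


def truth_window(spec: SyntheticSpec, seed: int = 0) -> Window:
    """Window spanning exactly the generated free segment (ground truth)."""
    rec = generate_recording(spec, seed, meta=RecordingMeta(recording_id="truth"))
    fs = spec.sample_rate_hz
    b2 = int(round(rec.meta.extra["free_start_s"] * fs))
    b3 = int(round(rec.meta.extra["free_end_s"] * fs))
    return Window(
        recording_id="truth",
        start_idx=b2,
        end_idx=b3,
        sample_rate_hz=fs,
        samples=rec.samples[b2:b3],
    )


@pytest.fixture
def make_truth_window():
    return truth_window


@pytest.fixture
def noise_recording():
    """Pure-noise recording factory (no vibration event)."""

    def _make(seed: int = 0, n: int = 2000, sd: float = 0.01, fs: float = 4000.0):
        rng = np.random.default_rng(seed)
        from clutchvibe.signal_io import Recording

        return Recording(
            samples=sd * rng.standard_normal(n),
            sample_rate_hz=fs,
            meta=RecordingMeta(recording_id="noise"),
        )

    return _make
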