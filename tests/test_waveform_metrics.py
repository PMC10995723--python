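"""Peak amplitude, above-noise duration, and spatial attenuation."""

from dataclasses import replace

import numpy as np
import pytest

from clutchvibe.signal_io import Recording, RecordingMeta
from clutchvibe.synthetic_signals import generate_recording, noise_sd_for_snr
from clutchvibe.waveform_metrics import (
    peak_amplitude,
    spatial_attenuation,
    total_duration,
)
from clutchvibe.windowing import NoiseStats, estimate_noise_floor


def _rec(samples, fs=1000.0):
    return Recording(np.asarray(samples, dtype=float), fs, RecordingMeta())


class TestPeakAmplitude:
    def test_max_absolute_value(self):
        assert peak_amplitude(_rec([0, 1, -3, 2])) == 3.0

    def test_sign_flip_invariance(self):
        x = np.sin(np.linspace(0, 10, 100)) * np.linspace(2, 0, 100)
        assert peak_amplitude(_rec(x)) == peak_amplitude(_rec(-x))

    def test_all_zero_recording(self):
        assert peak_amplitude(_rec(np.zeros(10))) == 0.0

    def test_dc_offset_removed_via_pre_event_mean(self):
        event = np.array([0, 1, -3, 2] * 12 + [0, 0], dtype=float)
        x = np.concatenate([np.full(50, 2.0), 2.0 + event])
        rec = _rec(x)
        assert peak_amplitude(rec, pre_event_span=(0, 50)) == pytest.approx(3.0)

    def test_peak_lies_in_impact_for_strong_transient(self, slow_mode_spec):
        spec = replace(slow_mode_spec, impact_gain=5.0, noise_sd=0.0)
        rec = generate_recording(spec, seed=0)
        peak = peak_amplitude(rec)
        imp0 = int(spec.pre_s * spec.sample_rate_hz)
        imp1 = int((spec.pre_s + spec.impact_s) * spec.sample_rate_hz)
        assert peak == pytest.approx(np.max(np.abs(rec.samples[imp0:imp1])))
        assert peak > np.hypot(spec.amp_cos, spec.amp_sin)


class TestTotalDuration:
    def test_closed_form_envelope_crossing(self, slow_mode_spec):
        """Noise-free decay with envelope A0 e^{-t/tau} stays above a
        threshold for tau * ln(A0/threshold) seconds."""
        spec = replace(
            slow_mode_spec, amp_cos=1.0, amp_sin=0.0, impact_gain=0.0,
            free_s=0.45, post_s=0.05,
        )
        rec = generate_recording(spec, seed=0)
        threshold = 0.05
        noise = NoiseStats(rms=threshold / 3.0, segment=(0, 1))
        measured = total_duration(rec, noise, f_nominal_hz=spec.frequency_hz)
        expected = spec.tau_s * np.log(1.0 / threshold)
        assert abs(measured - expected) <= 1.0 / spec.frequency_hz

    def test_pure_noise_duration_zero_at_high_threshold(self, noise_recording):
        rec = noise_recording(seed=3, n=4000, sd=0.01)
        noise = estimate_noise_floor(rec, (0, 4000))
        assert total_duration(rec, noise, threshold_factor=8.0) == 0.0

    def test_monotone_in_threshold(self, slow_mode_spec):
        spec = replace(
            slow_mode_spec, noise_sd=noise_sd_for_snr(slow_mode_spec, 10.0)
        )
        rec = generate_recording(spec, seed=5)
        noise = estimate_noise_floor(rec, (0, int(0.05 * spec.sample_rate_hz)))
        durations = [
            total_duration(rec, noise, threshold_factor=f)
            for f in (2.0, 3.0, 5.0, 8.0)
        ]
        assert all(a >= b for a, b in zip(durations, durations[1:]))

    def test_species_duration_contrast(self, slow_mode_spec, fast_mode_spec):
        """Fast-damping clutches ring about a third as long as slow ones."""
        slow = replace(
            slow_mode_spec, free_s=0.40, impact_s=0.04,
        )
        slow = replace(slow, noise_sd=noise_sd_for_snr(slow, 10.0))
        fast = replace(
            fast_mode_spec, free_s=0.12, impact_s=0.03,
        )
        fast = replace(fast, noise_sd=noise_sd_for_snr(fast, 10.0))
        ratios = []
        for seed in range(20):
            durs = []
            for spec in (slow, fast):
                rec = generate_recording(spec, seed=seed)
                noise = estimate_noise_floor(
                    rec, (0, int(0.05 * spec.sample_rate_hz))
                )
                durs.append(total_duration(rec, noise))
            ratios.append(durs[0] / durs[1])
        assert 2.0 <= np.mean(ratios) <= 5.0


class TestSpatialAttenuation:
    def test_attenuating_clutch(self):
        r = spatial_attenuation([2.0] * 5, [1.0] * 5, "c1")
        assert r.absolute_change == pytest.approx(-1.0)
        assert r.proportional == pytest.approx(0.5)
        assert not r.enhanced

    def test_enhanced_clutch(self):
        r = spatial_attenuation([1.0] * 5, [1.2] * 5, "c2")
        assert r.proportional == pytest.approx(1.2)
        assert r.enhanced

    def test_proportional_from_replicates(self):
        r = spatial_attenuation([1, 1, 1, 1, 1], [2, 2, 2, 2, 2])
        assert r.proportional == pytest.approx(2.0)

    def test_sign_consistency_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p1 = rng.uniform(0.1, 3.0, 5)
            p2 = rng.uniform(0.1, 3.0, 5)
            r = spatial_attenuation(p1.tolist(), p2.tolist())
            assert np.sign(r.absolute_change) == np.sign(r.proportional - 1.0) or (
                r.absolute_change == 0 and r.proportional == 1.0
            )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            spatial_attenuation([0.0] * 5, [1.0] * 5, "c3")
        with pytest.raises(ValueError, match="replicate"):
            spatial_attenuation([], [1.0])
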