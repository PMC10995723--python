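"""Synthetic recording and cohort generation with known ground truth."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clutchvibe.modal_fit import eval_model
from clutchvibe.synthetic_signals import (
    CohortSpec,
    GroupSpec,
    SyntheticSpec,
    generate_cohort,
    generate_recording,
    noise_sd_for_snr,
    species_cohort_spec,
)


class TestGenerateRecording:
    def test_noise_free_free_segment_matches_model_bitwise(self, slow_mode_spec):
        spec = replace(
            slow_mode_spec, noise_sd=0.0, impact_gain=0.0, trend=(0.0, 0.0, 0.0)
        )
        rec = generate_recording(spec, seed=0)
        fs = spec.sample_rate_hz
        b2 = int(round(rec.meta.extra["free_start_s"] * fs))
        b3 = int(round(rec.meta.extra["free_end_s"] * fs))
        t = np.arange(b3 - b2) / fs
        expected = eval_model(spec.modal_params(), t)
        assert np.array_equal(rec.samples[b2:b3], expected)

    def test_seed_determinism(self, slow_mode_spec):
        spec = replace(slow_mode_spec, noise_sd=0.01)
        a = generate_recording(spec, seed=42).samples
        b = generate_recording(spec, seed=42).samples
        assert np.array_equal(a, b)
        c = generate_recording(spec, seed=43).samples
        assert not np.array_equal(a, c)

    def test_snr_convention(self):
        """Empirical RMS(noise)/RMS(clean free segment) ~ 1/SNR over 100 seeds."""
        spec = SyntheticSpec(
            frequency_hz=25.65, tau_s=0.10, sample_rate_hz=4000.0,
            pre_s=0.02, impact_s=0.02, free_s=0.3, post_s=0.02,
        )
        spec = replace(spec, noise_sd=noise_sd_for_snr(spec, 10.0))
        clean = generate_recording(replace(spec, noise_sd=0.0), seed=0)
        fs = spec.sample_rate_hz
        b2 = int(round(clean.meta.extra["free_start_s"] * fs))
        b3 = int(round(clean.meta.extra["free_end_s"] * fs))
        rms_clean = np.sqrt(np.mean(clean.samples[b2:b3] ** 2))
        ratios = []
        for seed in range(100):
            noisy = generate_recording(spec, seed=seed)
            ref = generate_recording(replace(spec, noise_sd=0.0), seed=seed)
            noise = noisy.samples[b2:b3] - ref.samples[b2:b3]
            ratios.append(np.sqrt(np.mean(noise**2)) / rms_clean)
        assert np.mean(ratios) == pytest.approx(0.1, rel=0.1)

    def test_nyquist_violation_rejected(self):
        spec = SyntheticSpec(frequency_hz=3000.0, sample_rate_hz=4000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            generate_recording(spec, seed=0)

    def test_negative_duration_rejected(self):
        spec = SyntheticSpec(pre_s=-0.01)
        with pytest.raises(ValueError, match="pre_s"):
            generate_recording(spec, seed=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        pre=st.floats(0, 0.05),
        impact=st.floats(0, 0.05),
        free=st.floats(0.01, 0.3),
        post=st.floats(0, 0.1),
        fs=st.sampled_from([2000.0, 4000.0, 44100.0]),
    )
    def test_sample_count_matches_rounded_duration(self, pre, impact, free, post, fs):
        spec = SyntheticSpec(
            frequency_hz=50.0, tau_s=0.05, sample_rate_hz=fs,
            pre_s=pre, impact_s=impact, free_s=free, post_s=post,
        )
        rec = generate_recording(spec, seed=0)
        assert rec.n_samples == round(spec.total_s * fs)


def _mini_groups(freq_sd=0.0, tau_sd=0.0):
    return [
        GroupSpec(
            label="fast", n_clutches=2, freq_mean_hz=105.0, freq_sd_hz=freq_sd,
            tau_mean_s=0.02, tau_sd_s=tau_sd,
            free_s_by_excitation={"pendulum_1cm": 0.05},
            replicates_per_type=2,
        ),
        GroupSpec(
            label="slow", n_clutches=2, freq_mean_hz=26.0, freq_sd_hz=freq_sd,
            tau_mean_s=0.10, tau_sd_s=tau_sd,
            free_s_by_excitation={"pendulum_1cm": 0.15},
            replicates_per_type=2,
        ),
    ]


class TestGenerateCohort:
    def test_zero_sd_cohort_reproduces_group_means(self):
        cohort = CohortSpec(groups=_mini_groups(), seed=0, sample_rate_hz=2000.0)
        _, truth = generate_cohort(cohort)
        fast = truth[truth.group == "fast"]
        assert (fast.true_frequency_hz == 105.0).all()
        assert (fast.true_tau_s == 0.02).all()

    def test_study_design_counts(self):
        """16 + 17 clutches x 4 excitation types x 5 replicates = 660."""
        cohort = species_cohort_spec(seed=0, sample_rate_hz=2000.0)
        recordings, truth = generate_cohort(cohort)
        assert len(recordings) == 16 * 20 + 17 * 20 == 660
        assert len(truth) == 660
        assert truth.recording_id.is_unique

    def test_truth_table_determinism(self):
        cohort = CohortSpec(
            groups=_mini_groups(freq_sd=10.0, tau_sd=0.01),
            seed=7, sample_rate_hz=2000.0,
        )
        _, t1 = generate_cohort(cohort)
        _, t2 = generate_cohort(cohort)
        assert t1.equals(t2)

    def test_clutch_draws_are_positive(self):
        cohort = CohortSpec(
            groups=_mini_groups(freq_sd=50.0, tau_sd=0.08),
            seed=3, sample_rate_hz=2000.0,
        )
        _, truth = generate_cohort(cohort)
        assert (truth.true_frequency_hz > 0).all()
        assert (truth.true_tau_s > 0).all()

    def test_one_cycle_floor_on_free_duration(self):
        """The free segment always holds at least one full vibration cycle."""
        cohort = CohortSpec(
            groups=[
                GroupSpec(
                    label="verylow", n_clutches=5, freq_mean_hz=8.0,
                    freq_sd_hz=4.0, tau_mean_s=0.1, tau_sd_s=0.0,
                    free_s_by_excitation={"drop_small": 0.05},
                )
            ],
            seed=1, sample_rate_hz=2000.0,
        )
        _, truth = generate_cohort(cohort)
        free = truth.free_end_s - truth.free_start_s
        # boundary rounding can shave up to one sample off the segment
        margin = 1.5 / 2000.0
        assert ((free + margin) * truth.true_frequency_hz >= 1.0).all()
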