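"""Model evaluation, separable least squares, NRMSE, and acceptance filters."""

import numpy as np
import pandas as pd
import pytest

from clutchvibe.modal_fit import (
    FitFilterCriteria,
    FitOptions,
    ModalParams,
    apply_fit_filters,
    compute_nrmse,
    eval_model,
    fit_window,
    initial_estimates,
    solve_linear_coeffs,
)
from clutchvibe.synthetic_signals import SyntheticSpec, noise_sd_for_snr
from clutchvibe.windowing import Window

from conftest import truth_window


class TestEvalModel:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            # at t=0 the damped terms reduce to a1
            (ModalParams(omega=6, tau=2, a1=1, a2=1), 0.0, 1.0),
            # e^-1 (cos 12 + sin 12)
            (ModalParams(omega=6, tau=2, a1=1, a2=1), 2.0, 0.1130423775470884),
            # pure quadratic trend: 1 + 2*2 + 3*4
            (ModalParams(omega=6, tau=2, a3=1, a4=2, a5=3), 2.0, 17.0),
        ],
    )
    def test_pointwise_values(self, params, t, expected):
        assert eval_model(params, np.array([t]))[0] == pytest.approx(
            expected, rel=1e-12
        )

    def test_envelope_reaches_e_minus_one_at_tau(self):
        """The damped component's envelope at t=tau is 36.8% of its start."""
        p = ModalParams(omega=2 * np.pi * 40.0, tau=0.05, a1=0.6, a2=-1.1)
        t = np.linspace(0, 0.2, 20001)
        env = np.hypot(
            eval_model(ModalParams(p.omega, p.tau, a1=p.a1, a2=p.a2), t),
            eval_model(ModalParams(p.omega, p.tau, a1=-p.a2, a2=p.a1), t),
        )
        i_tau = np.argmin(np.abs(t - p.tau))
        assert env[i_tau] / env[0] == pytest.approx(np.exp(-1), rel=1e-6)


class TestSolveLinearCoeffs:
    def test_exact_recovery_of_linear_coefficients(self):
        rng = np.random.default_rng(7)
        t = np.arange(400) / 4000.0
        truth = ModalParams(
            omega=2 * np.pi * 60, tau=0.05, a1=1.2, a2=-0.7, a3=0.3, a4=2.0, a5=-30.0
        )
        y = eval_model(truth, t)
        coeffs, resid = solve_linear_coeffs(truth.omega, truth.tau, t, y)
        np.testing.assert_allclose(
            coeffs, [truth.a1, truth.a2, truth.a3, truth.a4, truth.a5], rtol=1e-9
        )
        assert resid < 1e-18

    def test_constant_window_maps_to_offset(self):
        t = np.arange(100) / 1000.0
        coeffs, resid = solve_linear_coeffs(50.0, 0.1, t, np.full(100, 3.5))
        assert coeffs[2] == pytest.approx(3.5, abs=1e-9)
        np.testing.assert_allclose(coeffs[[0, 1, 3, 4]], 0.0, atol=1e-7)
        assert resid == pytest.approx(0.0, abs=1e-16)

    def test_least_squares_is_unbiased_under_noise(self):
        rng = np.random.default_rng(11)
        t = np.arange(300) / 4000.0
        truth = ModalParams(omega=2 * np.pi * 80, tau=0.04, a1=1.0, a2=0.5)
        clean = eval_model(truth, t)
        sigma = 0.3
        a1_hats = []
        for _ in range(300):
            y = clean + sigma * rng.standard_normal(t.size)
            coeffs, _ = solve_linear_coeffs(truth.omega, truth.tau, t, y)
            a1_hats.append(coeffs[0])
        se = np.std(a1_hats, ddof=1) / np.sqrt(len(a1_hats))
        assert abs(np.mean(a1_hats) - truth.a1) < 3 * se

    def test_duplicated_times_raise(self):
        t = np.zeros(10)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            solve_linear_coeffs(10.0, 0.1, t, np.ones(10))

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError, match="6 samples"):
            solve_linear_coeffs(10.0, 0.1, np.arange(4.0), np.ones(4))


class TestComputeNrmse:
    def test_zero_iff_identical(self):
        x = np.array([1.0, -2.0, 0.5])
        assert compute_nrmse(x, x) == 0.0
        assert compute_nrmse(x, x + 1e-3) > 0

    def test_hand_computed_value(self):
        obs = np.array([1.0, 0.0, -1.0, 0.0])
        assert compute_nrmse(obs, np.zeros(4)) == pytest.approx(
            np.sqrt(0.5), rel=1e-12
        )

    def test_invariant_under_repetition(self):
        obs = np.array([1.0, 0.0, -1.0, 0.0])
        pred = np.array([0.5, 0.0, -0.5, 0.1])
        once = compute_nrmse(obs, pred)
        twice = compute_nrmse(np.tile(obs, 2), np.tile(pred, 2))
        assert once == pytest.approx(twice, rel=1e-14)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_nrmse(np.ones(3), np.ones(4))


class TestInitialEstimates:
    def test_noise_free_estimates_near_truth(self, slow_mode_spec):
        win = truth_window(slow_mode_spec)
        omega0, tau0 = initial_estimates(win)
        assert omega0 == pytest.approx(2 * np.pi * 25.65, rel=0.2)
        assert tau0 == pytest.approx(0.10, rel=0.5)

    def test_undamped_sinusoid_gives_long_tau(self):
        fs = 4000.0
        t = np.arange(int(0.2 * fs)) / fs
        x = np.sin(2 * np.pi * 50 * t)
        win = Window("undamped", 0, t.size, fs, x)
        _, tau0 = initial_estimates(win)
        assert tau0 >= win.duration_s

    def test_too_few_crossings_raise(self):
        win = Window("flatish", 0, 64, 4000.0, np.linspace(0, 1, 64))
        with pytest.raises(ValueError, match="zero crossings"):
            initial_estimates(win)


class TestFitWindow:
    def test_noise_free_recovery_with_trend(self, slow_mode_spec):
        from dataclasses import replace

        spec = replace(slow_mode_spec, trend=(0.2, 1.5, -20.0))
        win = truth_window(spec)
        fit = fit_window(win)
        assert fit.converged
        assert fit.frequency_hz == pytest.approx(25.65, rel=1e-4)
        assert fit.tau_s == pytest.approx(0.10, rel=1e-4)
        assert fit.epsilon < 1e-8
        assert fit.frequency_hz * fit.period_s == pytest.approx(1.0, rel=1e-12)

    def test_epsilon_not_worse_than_true_parameters(self, fast_mode_spec):
        """Optimized misfit never exceeds the misfit at the true parameters."""
        from dataclasses import replace

        spec = replace(
            fast_mode_spec, noise_sd=noise_sd_for_snr(fast_mode_spec, 10.0)
        )
        win = truth_window(spec, seed=3)
        fit = fit_window(win)
        y = win.samples / np.std(win.samples)
        coeffs, _ = solve_linear_coeffs(
            2 * np.pi * spec.frequency_hz, spec.tau_s, win.times, y
        )
        true_p = ModalParams(
            2 * np.pi * spec.frequency_hz, spec.tau_s, *coeffs.tolist()
        )
        eps_true = compute_nrmse(y, eval_model(true_p, win.times))
        assert fit.epsilon <= eps_true + 1e-10

    def test_determinism(self, slow_mode_spec):
        win = truth_window(slow_mode_spec, seed=5)
        f1 = fit_window(win)
        f2 = fit_window(win)
        assert f1.frequency_hz == f2.frequency_hz
        assert f1.tau_s == f2.tau_s
        assert f1.epsilon == f2.epsilon

    def test_median_recovery_under_noise(self, fast_mode_spec):
        """Stiff-clutch preset at SNR 10: median frequency error below 5%."""
        from dataclasses import replace

        freqs = []
        for seed in range(30):
            spec = replace(
                fast_mode_spec,
                free_s=0.03,
                noise_sd=noise_sd_for_snr(
                    replace(fast_mode_spec, free_s=0.03), 10.0
                ),
            )
            win = truth_window(spec, seed=seed)
            freqs.append(fit_window(win).frequency_hz)
        med = np.median(freqs)
        assert abs(med - 105.15) / 105.15 < 0.05


class TestFitFilters:
    @staticmethod
    def _row(**kw):
        base = dict(
            recording_id="r",
            group="g",
            excitation_type="pendulum_1cm",
            frequency_hz=100.0,
            tau_s=0.02,
            epsilon=0.1,
            window_duration_s=0.04,
        )
        base.update(kw)
        return base

    def test_epsilon_threshold(self):
        df = pd.DataFrame([self._row(epsilon=0.6), self._row(epsilon=0.4)])
        accepted, rejected = apply_fit_filters(df, FitFilterCriteria(group_keys=()))
        assert len(accepted) == 1
        assert rejected.iloc[0]["rejection_reasons"] == "epsilon"

    def test_tau_vs_window(self):
        df = pd.DataFrame(
            [self._row(tau_s=0.05, window_duration_s=0.03, frequency_hz=100.0)]
        )
        _, rejected = apply_fit_filters(df, FitFilterCriteria(group_keys=()))
        assert "tau_vs_window" in rejected.iloc[0]["rejection_reasons"]

    def test_three_sd_outlier_rejected(self):
        rng = np.random.default_rng(0)
        rows = [
            self._row(frequency_hz=100 + rng.normal(0, 1), tau_s=0.02)
            for _ in range(20)
        ]
        rows.append(self._row(frequency_hz=200.0, tau_s=0.02))
        df = pd.DataFrame(rows)
        accepted, rejected = apply_fit_filters(df, FitFilterCriteria())
        assert 200.0 not in accepted["frequency_hz"].to_numpy()
        bad = rejected[rejected.frequency_hz == 200.0].iloc[0]
        assert "z_outlier" in bad["rejection_reasons"]

    def test_sub_cycle_fit_rejected(self):
        # a fitted curve with < 1 cycle in the window is unidentifiable
        df = pd.DataFrame([self._row(frequency_hz=5.0, window_duration_s=0.05)])
        _, rejected = apply_fit_filters(df, FitFilterCriteria(group_keys=()))
        assert "min_cycles" in rejected.iloc[0]["rejection_reasons"]

    def test_spike_fit_rejected(self):
        # f*tau < 1: decays before completing a cycle -> transient, not a mode
        df = pd.DataFrame(
            [self._row(frequency_hz=1300.0, tau_s=0.0005, window_duration_s=0.02)]
        )
        _, rejected = apply_fit_filters(df, FitFilterCriteria(group_keys=()))
        assert "min_cycles" in rejected.iloc[0]["rejection_reasons"]

    def test_singleton_cell_skips_z_filter(self):
        df = pd.DataFrame([self._row(group="a"), self._row(group="b")])
        accepted, _ = apply_fit_filters(df, FitFilterCriteria(group_keys=("group",)))
        assert accepted["z_skipped"].all()
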