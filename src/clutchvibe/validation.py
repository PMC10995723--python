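"""Self-contained validation studies of the fitting pipeline.

Each function here builds its own synthetic inputs, runs the package's own
estimators, and returns the measured quantities.  They back both the test
suite and the reproduction script, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort_stats import recovery_metrics, welch_t
from .field_data import CLUTCH_DIMENSIONS
from .modal_fit import (
    FitFilterCriteria,
    FitOptions,
    ModalParams,
    apply_fit_filters,
    eval_model,
    fit_window,
)
from .pipeline import PipelineConfig, run_pipeline
from .synthetic_signals import (
    SyntheticSpec,
    generate_recording,
    species_cohort_spec,
)
from .signal_io import Recording, RecordingMeta
from .waveform_metrics import total_duration
from .windowing import NoiseStats, Window

__all__ = [
    "envelope_decay_ratio",
    "clutch_dimension_welch",
    "oracle_equivalence_study",
    "species_recovery_study",
    "tau_filter_study",
    "noise_rejection_study",
    "duration_closed_form_study",
]


def envelope_decay_ratio(
    omega: float = 6.0, tau: float = 2.0, a1: float = 1.0, a2: float = 1.0
) -> float:
    """Envelope value at t = tau as a fraction of its initial value.

    The model's free-vibration envelope is sqrt(a1^2 + a2^2) exp(-t/tau);
    evaluated numerically through the model itself (cos/sin components at
    quadrature phases) rather than asserted, so this checks the implemented
    signal, not the algebra.  Expected: e^-1 ~ 0.368.
    """
    amp = np.hypot(a1, a2)

    def envelope_at(t: float) -> float:
        # amplitude of the damped component at time t, via two phase reads
        pc = ModalParams(omega=omega, tau=tau, a1=amp, a2=0.0)
        ps = ModalParams(omega=omega, tau=tau, a1=0.0, a2=amp)
        c = eval_model(pc, np.array([t]))[0]
        s = eval_model(ps, np.array([t]))[0]
        return float(np.hypot(c, s))

    return envelope_at(tau) / envelope_at(0.0)


def clutch_dimension_welch() -> dict[str, dict[str, float]]:
    """Welch t/df/p for each published clutch-dimension comparison."""
    out = {}
    for var, groups in CLUTCH_DIMENSIONS.items():
        w = welch_t(groups["A_callidryas"], groups["A_spurrelli"])
        out[var] = {"t": w.t, "df": w.df, "p": w.p}
    return out


def _window_from_spec(spec: SyntheticSpec, seed: int) -> Window:
    """Exact free-vibration window of a synthetic recording (truth bounds)."""
    rec = generate_recording(spec, seed)
    fs = spec.sample_rate_hz
    b2 = int(round(rec.meta.extra["free_start_s"] * fs))
    b3 = int(round(rec.meta.extra["free_end_s"] * fs))
    return Window(
        recording_id=rec.meta.recording_id or "synthetic",
        start_idx=b2,
        end_idx=b3,
        sample_rate_hz=fs,
        samples=rec.samples[b2:b3],
    )


def oracle_equivalence_study(
    n_cases: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Noise-free recovery over randomized admissible parameters.

    Draws n_cases parameter sets (frequency 5-400 Hz, tau spanning strong to
    weak damping, random amplitudes and trend), renders noise-free windows of
    at least one cycle, fits them, and reports relative errors of omega, tau
    and the linear coefficients plus the achieved epsilon.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cases):
        f = float(rng.uniform(5.0, 400.0))
        n_cycles = float(rng.uniform(1.5, 8.0))
        duration = n_cycles / f
        tau = float(duration * rng.uniform(0.3, 3.0))
        a1, a2 = rng.uniform(-2, 2, size=2)
        if np.hypot(a1, a2) < 0.1:
            a1 = 1.0
        a3, a4, a5 = rng.uniform(-1, 1, size=3) * [0.5, 5.0, 50.0]
        spec = SyntheticSpec(
            frequency_hz=f,
            tau_s=tau,
            amp_cos=float(a1),
            amp_sin=float(a2),
            trend=(float(a3), float(a4), float(a5)),
            sample_rate_hz=max(4000.0, 40.0 * f),
            pre_s=0.0,
            impact_s=0.0,
            free_s=duration,
            post_s=0.0,
            noise_sd=0.0,
            impact_gain=0.0,
        )
        win = _window_from_spec(spec, seed=i)
        fit = fit_window(win)
        truth = spec.modal_params()
        rel = lambda est, true: abs(est - true) / abs(true)
        rows.append(
            {
                "case": i,
                "true_frequency_hz": f,
                "true_tau_s": tau,
                "rel_err_omega": rel(fit.params.omega, truth.omega),
                "rel_err_tau": rel(fit.params.tau, truth.tau),
                "rel_err_a1": rel(fit.params.a1, truth.a1),
                "rel_err_a2": rel(fit.params.a2, truth.a2),
                "epsilon": fit.epsilon,
            }
        )
    return pd.DataFrame(rows)


def species_recovery_study(
    seed: int = 0,
    sample_rate_hz: float = 4000.0,
    snr: float = 10.0,
    out_dir: str = "scratch/recovery_study",
) -> dict:
    """Full-pipeline parameter recovery on the two-species synthetic cohort.

    Simulates the field design (16 + 17 clutches x 4 excitation types x 5
    replicates, between-clutch spread at the reported SDs, free-segment
    durations at the species' mean window lengths), runs windowing, fitting
    and the acceptance filters, and scores accepted fits against truth.
    Returns median relative errors and the accepted-fit group mean ratios
    for frequency (expected ~4x) and tau (expected ~5x).
    """
    cohort = species_cohort_spec(
        seed=seed, sample_rate_hz=sample_rate_hz, snr=snr
    )
    config = PipelineConfig(out_dir=out_dir, cohort=cohort, seed=seed)
    result = run_pipeline(config)
    accepted = result["accepted"]
    truth = result["truth"]
    report = recovery_metrics(truth, accepted)
    per = report.per_parameter.set_index("parameter")

    means = accepted.groupby("group")[["frequency_hz", "tau_s"]].mean()
    freq_ratio = (
        means.loc["A_spurrelli", "frequency_hz"]
        / means.loc["A_callidryas", "frequency_hz"]
    )
    tau_ratio = (
        means.loc["A_callidryas", "tau_s"] / means.loc["A_spurrelli", "tau_s"]
    )
    return {
        "n_recordings": result["counts"]["recordings"],
        "n_accepted": result["counts"]["accepted"],
        "median_rel_err_frequency": float(
            per.loc["frequency_hz", "median_rel_error"]
        ),
        "median_rel_err_tau": float(per.loc["tau_s", "median_rel_error"]),
        "freq_ratio_spurrelli_over_callidryas": float(freq_ratio),
        "tau_ratio_callidryas_over_spurrelli": float(tau_ratio),
        "result": result,
    }


def tau_filter_study(seed: int = 0) -> dict:
    """Grid of fits whose true tau exceeds the window duration.

    Windows are rendered noise-free at several (frequency, cycles) settings
    with tau = 2-8x the window length; the tau-vs-window acceptance rule
    should reject nearly all of them.
    """
    rows = []
    case = 0
    for f in (25.0, 50.0, 105.0):
        for n_cycles in (2.0, 4.0):
            for tau_mult in (2.0, 4.0, 8.0):
                duration = n_cycles / f
                spec = SyntheticSpec(
                    frequency_hz=f,
                    tau_s=tau_mult * duration,
                    sample_rate_hz=4000.0,
                    pre_s=0.0,
                    impact_s=0.0,
                    free_s=duration,
                    post_s=0.0,
                    noise_sd=0.0,
                    impact_gain=0.0,
                )
                win = _window_from_spec(spec, seed=seed + case)
                fit = fit_window(win)
                rows.append(
                    {
                        "recording_id": f"grid-{case}",
                        "frequency_hz": fit.frequency_hz,
                        "tau_s": fit.tau_s,
                        "epsilon": fit.epsilon,
                        "window_duration_s": win.duration_s,
                    }
                )
                case += 1
    fits = pd.DataFrame(rows)
    criteria = FitFilterCriteria(group_keys=())
    accepted, rejected = apply_fit_filters(fits, criteria)
    tau_rejected = rejected["rejection_reasons"].str.contains("tau_vs_window")
    return {
        "n_cases": len(fits),
        "tau_rejection_rate": float(tau_rejected.sum() / len(fits)),
        "fits": fits,
    }


def noise_rejection_study(
    n_seeds: int = 200, seed: int = 0, n_samples: int = 400,
    sample_rate_hz: float = 4000.0,
) -> dict:
    """Fits to pure-noise windows: epsilon should flag nearly all of them.

    Gaussian-noise windows carry no damped sinusoid, so the best achievable
    fit explains almost none of the variance and epsilon stays near 1,
    far above the 0.5 acceptance threshold.
    """
    root = np.random.SeedSequence(seed)
    n_flagged = 0
    epsilons = []
    for i, child in enumerate(root.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        x = rng.standard_normal(n_samples)
        win = Window(
            recording_id=f"noise-{i}",
            start_idx=0,
            end_idx=n_samples,
            sample_rate_hz=sample_rate_hz,
            samples=x,
        )
        fit = fit_window(win, FitOptions(maxiter=400))
        epsilons.append(fit.epsilon)
        if fit.epsilon >= 0.5:
            n_flagged += 1
    return {
        "n_seeds": n_seeds,
        "flagged_rate": n_flagged / n_seeds,
        "median_epsilon": float(np.median(epsilons)),
    }


def duration_closed_form_study(threshold: float = 0.05) -> pd.DataFrame:
    """Measured total duration vs. the analytic envelope crossing time.

    For a noise-free decaying sinusoid with initial envelope A0 the smoothed
    envelope falls below a threshold at t = tau * ln(A0 / threshold); the
    measured duration should match within about one envelope-smoothing
    period.  20-case grid over frequency x tau.
    """
    rows = []
    for f in (20.0, 40.0, 80.0, 160.0):
        for tau in (0.02, 0.05, 0.1, 0.2, 0.4):
            expected = tau * np.log(1.0 / threshold)
            free_s = expected * 1.5          # keep the crossing inside the segment
            spec = SyntheticSpec(
                frequency_hz=f,
                tau_s=tau,
                amp_cos=1.0,
                amp_sin=0.0,
                sample_rate_hz=8000.0,
                pre_s=0.02,
                impact_s=0.0,
                free_s=free_s,
                post_s=0.02,
                noise_sd=0.0,
                impact_gain=0.0,
            )
            rec = generate_recording(spec, seed=0)
            noise = NoiseStats(rms=threshold / 3.0, segment=(0, 1))
            measured = total_duration(rec, noise, threshold_factor=3.0,
                                      f_nominal_hz=f)
            rows.append(
                {
                    "frequency_hz": f,
                    "tau_s": tau,
                    "expected_s": expected,
                    "measured_s": measured,
                    "abs_error_s": abs(measured - expected),
                    "smoothing_period_s": 1.0 / f,
                }
            )
    return pd.DataFrame(rows)
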