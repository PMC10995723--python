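"""Damped-sinusoid modal fitting by separable (variable-projection) least squares.

The free vibration of an egg clutch is modelled as a single viscously damped
mode riding on a quadratic trend:

    a(t) = A1 exp(-t/tau) cos(omega t) + A2 exp(-t/tau) sin(omega t)
           + A3 + A4 t + A5 t^2

where omega (rad/s) is the angular frequency of the mode, tau (s) is the
amplitude-decay time constant (the time for the envelope to fall to
e^-1 ~ 36.8% of its starting value), A1/A2 (m/s^2) set amplitude and phase,
and A3-A5 absorb the slow quadratic drift seen in accelerometer traces.  The
period is T = 2 pi / omega and the cyclic frequency f = omega / 2 pi.

For fixed (omega, tau) the model is linear in A1-A5, so those are solved
exactly by least squares at every objective evaluation while a Nelder-Mead
simplex searches (log omega, log tau).  The objective is the root-mean-square
error between the observed and fitted series,

    epsilon = sqrt( (1/N) sum |a_n - a~_n|^2 ),

computed on a window pre-scaled by its standard deviation so that epsilon is
scale-free: a perfect fit gives 0, a fit no better than the window mean gives
~1, and the conventional acceptance threshold epsilon < 0.5 is meaningful for
any recording gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import find_peaks

from .windowing import Window, count_zero_crossings

__all__ = [
    "ModalParams",
    "ModalFit",
    "FitOptions",
    "FitFilterCriteria",
    "eval_model",
    "solve_linear_coeffs",
    "compute_nrmse",
    "initial_estimates",
    "fit_window",
    "apply_fit_filters",
]


@dataclass
class ModalParams:
    """Parameters of the single-mode damped-sinusoid-plus-trend model."""

    omega: float        # angular frequency, rad/s
    tau: float          # decay time constant, s
    a1: float = 0.0     # cos amplitude, m/s^2
    a2: float = 0.0     # sin amplitude, m/s^2
    a3: float = 0.0     # trend offset, m/s^2
    a4: float = 0.0     # trend slope, m/s^3
    a5: float = 0.0     # trend curvature, m/s^4

    @property
    def frequency_hz(self) -> float:
        return self.omega / (2.0 * np.pi)

    @property
    def period_s(self) -> float:
        return 2.0 * np.pi / self.omega


@dataclass
class ModalFit:
    """Result of fitting the modal model to one window."""

    params: ModalParams
    epsilon: float               # RMS misfit on the sd-normalized window
    n_evals: int                 # objective evaluations across all starts
    converged: bool
    window_duration_s: float
    predicted: np.ndarray        # fitted series a~_n, physical units
    recording_id: str = ""
    scale: float = 1.0           # sd used to normalize the window

    @property
    def frequency_hz(self) -> float:
        return self.params.frequency_hz

    @property
    def period_s(self) -> float:
        return self.params.period_s

    @property
    def tau_s(self) -> float:
        return self.params.tau


def eval_model(params: ModalParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the damped-sinusoid-plus-trend model at the given times."""
    t = np.asarray(times, dtype=float)
    decay = np.exp(-t / params.tau)
    return (
        params.a1 * decay * np.cos(params.omega * t)
        + params.a2 * decay * np.sin(params.omega * t)
        + params.a3
        + params.a4 * t
        + params.a5 * t * t
    )


def _design_matrix(omega: float, tau: float, t: np.ndarray) -> np.ndarray:
    decay = np.exp(-t / tau)
    return np.column_stack(
        [decay * np.cos(omega * t), decay * np.sin(omega * t),
         np.ones_like(t), t, t * t]
    )


def solve_linear_coeffs(
    omega: float, tau: float, times: np.ndarray, samples: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact least-squares solution for A1-A5 at fixed (omega, tau).

    Returns ``(coeffs, residual)`` where ``coeffs`` is (a1..a5) and
    ``residual`` the sum of squared errors.  Raises on a rank-deficient
    design (e.g. duplicated times or fewer than 6 samples).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(samples, dtype=float)
    if t.size != y.size:
        raise ValueError("times and samples must have equal length")
    if t.size < 6:
        raise ValueError(f"need at least 6 samples, got {t.size}")
    if not (omega > 0 and tau > 0):
        raise ValueError("omega and tau must be positive")
    X = _design_matrix(omega, tau, t)
    coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 5:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < 5); "
            "times may be duplicated or the window degenerate"
        )
    resid = y - X @ coeffs
    return coeffs, float(resid @ resid)


def compute_nrmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square misfit epsilon = sqrt(mean |a_n - a~_n|^2).

    Inputs are assumed to be on the module's normalized scale (the window is
    divided by its standard deviation before fitting); the formula itself is
    the plain RMS deviation and is zero iff the vectors are identical.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 1:
        raise ValueError("need at least one sample")
    d = obs - pred
    return float(np.sqrt(np.mean(d * d)))


def initial_estimates(window: Window) -> tuple[float, float]:
    """Automated starting values (omega0, tau0) for the simplex search.

    A stand-in for eyeballing the trace: omega0 comes from the dominant
    spectral peak of the quadratically detrended window (falling back to
    pi times the zero-crossing rate), tau0 from the slope of a line fitted
    to the log of the envelope peaks (falling back to the window duration
    when the envelope does not decay).
    """
    x = np.asarray(window.samples, dtype=float)
    t = window.times
    # remove the quadratic trend the model accounts for; a strong trend can
    # hide the oscillation from a raw zero-crossing count
    coef = np.polynomial.polynomial.polyfit(t, x, 2)
    xd = x - np.polynomial.polynomial.polyval(t, coef)
    if count_zero_crossings(xd) < 2:
        raise ValueError(
            "window has fewer than 2 zero crossings; cannot estimate a frequency"
        )

    fs = 1.0 / (t[1] - t[0])
    spec = np.abs(np.fft.rfft(xd))
    freqs = np.fft.rfftfreq(xd.size, d=1.0 / fs)
    k = int(np.argmax(spec[1:])) + 1
    f0 = freqs[k]
    if not f0 > 0:
        zcr = count_zero_crossings(xd) / window.duration_s
        omega0 = np.pi * zcr
    else:
        omega0 = 2.0 * np.pi * f0

    duration = window.duration_s
    tau0 = duration
    peaks, _ = find_peaks(np.abs(xd))
    if peaks.size >= 2:
        vals = np.abs(xd[peaks])
        ok = vals > 0
        if ok.sum() >= 2:
            slope = np.polynomial.polynomial.polyfit(
                t[peaks[ok]], np.log(vals[ok]), 1
            )[1]
            if slope < 0:
                tau0 = min(-1.0 / slope, 100.0 * duration)
    return float(omega0), float(tau0)


@dataclass
class FitOptions:
    """Controls for the simplex search.

    start_scales spreads a multiplicative grid of starting points around the
    automated initial estimates; the simplex runs in (log omega, log tau) so
    both parameters stay positive by construction.
    """

    start_scales: tuple[float, ...] = (0.5, 1.0, 2.0)
    fatol: float = 1e-10          # absolute tolerance on epsilon
    xatol: float = 1e-8           # tolerance on (log omega, log tau)
    maxiter: int = 2000
    initial: tuple[float, float] | None = None   # override (omega0, tau0)


def fit_window(window: Window, opts: FitOptions | None = None) -> ModalFit:
    """Fit the modal model to a window by Nelder-Mead over (log omega, log tau).

    At every candidate (omega, tau) the linear coefficients A1-A5 are solved
    exactly (variable projection), so the simplex only has to navigate a
    2-D landscape.  Nine starts on a {0.5, 1, 2}x grid around the automated
    initial estimates guard against local minima; the best epsilon wins, with
    ties broken toward smaller tau then smaller omega.  The result is a pure
    function of (window, opts).
    """
    opts = opts or FitOptions()
    y_raw = np.asarray(window.samples, dtype=float)
    t = window.times
    scale = float(np.std(y_raw))
    if not scale > 0:
        scale = 1.0
    y = y_raw / scale

    n_evals = 0

    def objective(logs: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        w = float(np.exp(logs[0]))
        tau = float(np.exp(logs[1]))
        X = _design_matrix(w, tau, t)
        coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 5:
            return np.inf
        r = y - X @ coeffs
        return float(np.sqrt(np.mean(r * r)))

    if opts.initial is not None:
        omega0, tau0 = opts.initial
    else:
        omega0, tau0 = initial_estimates(window)

    nm_options = dict(
        fatol=opts.fatol, xatol=opts.xatol,
        maxiter=opts.maxiter, maxfev=2 * opts.maxiter,
    )
    best = None  # (epsilon, tau, omega, success)
    for sw in opts.start_scales:
        for st in opts.start_scales:
            x0 = np.array([np.log(omega0 * sw), np.log(tau0 * st)])
            res = minimize(objective, x0, method="Nelder-Mead", options=nm_options)
            w = float(np.exp(res.x[0]))
            tau = float(np.exp(res.x[1]))
            eps = float(res.fun)
            cand = (eps, tau, w, bool(res.success))
            if best is None:
                best = cand
            elif eps < best[0] - 1e-12:
                best = cand
            elif abs(eps - best[0]) <= 1e-12 and (tau, w) < (best[1], best[2]):
                best = cand

    eps, tau, omega, success = best
    coeffs, _ = solve_linear_coeffs(omega, tau, t, y)
    a1, a2, a3, a4, a5 = (coeffs * scale).tolist()
    params = ModalParams(omega=omega, tau=tau, a1=a1, a2=a2, a3=a3, a4=a4, a5=a5)
    predicted = eval_model(params, t)
    return ModalFit(
        params=params,
        epsilon=eps,
        n_evals=n_evals,
        converged=success,
        window_duration_s=window.duration_s,
        predicted=predicted,
        recording_id=window.recording_id,
        scale=scale,
    )


@dataclass
class FitFilterCriteria:
    """Acceptance rules applied to a table of fits.

    A fit is kept iff (i) epsilon < epsilon_max, (ii) tau is smaller than the
    duration of the fitted window, (iii) omega and tau are positive, (iv) the
    window holds at least min_cycles full cycles of the fitted curve and the
    curve completes at least min_decay_cycles cycles within its own decay
    time (f x tau >= min_decay_cycles — a quantitative reading of "a clear
    decaying sinusoid": a fit that dies before finishing one cycle is a
    transient spike, not a vibration mode), and (v) its frequency and tau
    lie within z_max sample standard deviations of the mean of its grouping
    cell, where the cell means/SDs are computed in a single pass over the
    fits that survive (i)-(iv).
    """

    epsilon_max: float = 0.5
    require_tau_lt_window: bool = True
    require_positive: bool = True
    min_cycles: float = 1.0
    min_decay_cycles: float = 1.0
    z_max: float = 3.0
    group_keys: tuple[str, ...] = ("group", "excitation_type")

    def __post_init__(self) -> None:
        if self.epsilon_max < 0:
            raise ValueError("epsilon_max must be >= 0")
        if not self.z_max > 0:
            raise ValueError("z_max must be > 0")


def _zscores(values: np.ndarray, core: np.ndarray) -> np.ndarray:
    """|z| of values against mean/SD of the core subset (ddof=1)."""
    if core.size < 2:
        return np.zeros_like(values)
    m = core.mean()
    sd = core.std(ddof=1)
    if sd == 0:
        return np.where(values == m, 0.0, np.inf)
    return np.abs(values - m) / sd


def apply_fit_filters(
    fits: pd.DataFrame, criteria: FitFilterCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a fit table into accepted and rejected fits with reasons.

    ``fits`` needs columns frequency_hz, tau_s, epsilon, window_duration_s and
    (when the z filter is grouped) the grouping-key columns.  Returns
    ``(accepted, rejected)``; ``rejected`` carries a ``rejection_reasons``
    column listing every violated criterion.  Grouping cells with a single
    surviving fit skip the z filter and are flagged in ``z_skipped``.
    """
    criteria = criteria or FitFilterCriteria()
    df = fits.copy()
    n = len(df)
    reasons: list[list[str]] = [[] for _ in range(n)]

    eps_bad = df["epsilon"].to_numpy() >= criteria.epsilon_max
    pos_bad = np.zeros(n, dtype=bool)
    if criteria.require_positive:
        pos_bad = (df["tau_s"].to_numpy() <= 0) | (df["frequency_hz"].to_numpy() <= 0)
    tau_bad = np.zeros(n, dtype=bool)
    if criteria.require_tau_lt_window:
        tau_bad = df["tau_s"].to_numpy() >= df["window_duration_s"].to_numpy()
    cyc_bad = np.zeros(n, dtype=bool)
    if criteria.min_cycles > 0:
        cyc_bad = (
            df["frequency_hz"].to_numpy() * df["window_duration_s"].to_numpy()
            < criteria.min_cycles
        )
    if criteria.min_decay_cycles > 0:
        cyc_bad |= (
            df["frequency_hz"].to_numpy() * df["tau_s"].to_numpy()
            < criteria.min_decay_cycles
        )

    for i in range(n):
        if eps_bad[i]:
            reasons[i].append("epsilon")
        if tau_bad[i]:
            reasons[i].append("tau_vs_window")
        if pos_bad[i]:
            reasons[i].append("nonpositive")
        if cyc_bad[i]:
            reasons[i].append("min_cycles")

    core_mask = ~(eps_bad | tau_bad | pos_bad | cyc_bad)
    keys = [k for k in criteria.group_keys if k in df.columns]
    z_bad = np.zeros(n, dtype=bool)
    z_skipped = np.zeros(n, dtype=bool)
    if keys:
        groups = df.groupby(list(keys), sort=False).indices.values()
    else:
        groups = [np.arange(n)]
    for idx in groups:
        idx = np.asarray(idx)
        core = idx[core_mask[idx]]
        if core.size < 2:
            z_skipped[idx] = True
            continue
        for col in ("frequency_hz", "tau_s"):
            vals = df[col].to_numpy()
            z = _zscores(vals[idx], vals[core])
            z_bad[idx] |= z > criteria.z_max
    for i in np.nonzero(z_bad)[0]:
        reasons[i].append("z_outlier")

    df["z_skipped"] = z_skipped
    df["rejection_reasons"] = [";".join(r) for r in reasons]
    df["accepted"] = [len(r) == 0 for r in reasons]
    accepted = df[df["accepted"]].copy()
    rejected = df[~df["accepted"]].copy()
    return accepted, rejected
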