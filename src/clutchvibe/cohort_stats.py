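"""Group summaries, Welch two-sample comparisons, and recovery scoring.

Welch's unequal-variance t-test is computed in closed form from group
summaries (n, mean, SD), so it works equally from raw measurements and from
printed summary tables:

    t  = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
    df = (s1^2/n1 + s2^2/n2)^2 /
         [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ]   (Welch-Satterthwaite)

with a two-sided p from the t distribution.  Recovery scoring joins a fit
table against a simulation truth table and reports bias, median relative
error and RMSE per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "WelchResult",
    "RecoveryReport",
    "summarize",
    "welch_t",
    "welch_t_raw",
    "recovery_metrics",
]


@dataclass
class GroupSummary:
    """n / mean / SD / range of one variable in one group (SD uses n-1)."""

    n: int
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def summarize(values) -> GroupSummary:
    """Summary of a sample; a single value gets sd 0 by convention."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return GroupSummary(
        n=int(x.size), mean=float(x.mean()), sd=sd,
        min=float(x.min()), max=float(x.max()),
    )


def welch_t(s1: GroupSummary, s2: GroupSummary) -> WelchResult:
    """Welch two-sample t-test from group summaries (two-sided p)."""
    if s1.n < 2 or s2.n < 2:
        raise ValueError("Welch test needs n >= 2 per group")
    if s1.sd == 0 and s2.sd == 0:
        raise ValueError("both group SDs are zero; t undefined")
    v1 = s1.sd**2 / s1.n
    v2 = s2.sd**2 / s2.n
    se = np.sqrt(v1 + v2)
    t = (s1.mean - s2.mean) / se
    df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def welch_t_raw(x1, x2) -> WelchResult:
    """Welch test from raw samples (equals welch_t of their summaries)."""
    return welch_t(summarize(x1), summarize(x2))


@dataclass
class RecoveryReport:
    """Parameter-recovery scores of fitted vs. generating values."""

    n_matched: int
    n_unmatched_truth: int
    n_unmatched_fits: int
    per_parameter: pd.DataFrame   # parameter, bias, median_rel_error, rmse
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "n_unmatched_truth": self.n_unmatched_truth,
            "n_unmatched_fits": self.n_unmatched_fits,
            "per_parameter": self.per_parameter.to_dict(orient="records"),
            "flags": self.flags,
        }


#: (estimate column in fit table, truth column in truth table)
_RECOVERY_PAIRS = [
    ("frequency_hz", "true_frequency_hz"),
    ("tau_s", "true_tau_s"),
]


def recovery_metrics(
    truth_table: pd.DataFrame,
    fit_table: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> RecoveryReport:
    """Score fitted frequency and tau against simulation ground truth.

    Joins on ``recording_id``; reports per-parameter bias (mean of
    estimate - truth), median relative error |est - true| / true, and RMSE.
    ``thresholds`` optionally maps parameter name to a maximum acceptable
    median relative error, producing pass flags.
    """
    merged = fit_table.merge(truth_table, on="recording_id", how="inner",
                             suffixes=("", "_truth"))
    if merged.empty:
        raise ValueError("no recording_id overlap between fits and truth")
    rows = []
    flags: dict = {}
    for est_col, true_col in _RECOVERY_PAIRS:
        est = merged[est_col].to_numpy(dtype=float)
        true = merged[true_col].to_numpy(dtype=float)
        err = est - true
        rel = np.abs(err) / np.abs(true)
        rows.append(
            {
                "parameter": est_col,
                "bias": float(err.mean()),
                "median_rel_error": float(np.median(rel)),
                "rmse": float(np.sqrt(np.mean(err * err))),
            }
        )
        if thresholds and est_col in thresholds:
            flags[est_col] = bool(np.median(rel) < thresholds[est_col])
    return RecoveryReport(
        n_matched=len(merged),
        n_unmatched_truth=len(truth_table) - len(merged),
        n_unmatched_fits=len(fit_table) - len(merged),
        per_parameter=pd.DataFrame(rows),
        flags=flags,
    )
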