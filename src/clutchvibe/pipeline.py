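"""End-to-end orchestration: simulate -> window -> fit -> filter -> metrics -> stats.

A :class:`PipelineConfig` (usually loaded from a YAML file) describes either
a synthetic cohort or a manifest of WAV recordings plus all stage options.
:func:`run_pipeline` writes tidy CSV tables for every stage, a recovery
report when simulation truth exists, and a run manifest with the config
hash, seed and stage counts.  Identical config + seed gives byte-identical
CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import recovery_metrics, summarize, welch_t
from .modal_fit import (
    FitFilterCriteria,
    FitOptions,
    apply_fit_filters,
    fit_window,
)
from .signal_io import Recording, read_manifest, write_manifest, write_recording
from .synthetic_signals import CohortSpec, GroupSpec, generate_cohort
from .waveform_metrics import (
    attenuation_table,
    peak_amplitude,
    spatial_attenuation,
    total_duration,
)
from .windowing import (
    NoiseStats,
    WindowOptions,
    estimate_noise_floor,
    load_window_overrides,
    select_free_window,
    validate_window,
    window_from_bounds,
    windows_table,
)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "EmptyAcceptedError",
    "load_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class EmptyAcceptedError(RuntimeError):
    """Every fit was rejected by the acceptance filters (CLI exit code 3)."""

    def __init__(self, message: str, stage_counts: dict):
        super().__init__(message)
        self.stage_counts = stage_counts


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Exactly one of ``cohort`` (synthetic study) or ``manifest`` (CSV of WAV
    recordings) must be set.
    """

    out_dir: str = "clutchvibe_out"
    cohort: CohortSpec | None = None
    manifest: str | None = None
    seed: int = 0
    write_wav: bool = False
    quiet_s: float | None = None          # noise-floor span; default: pre segment
    threshold_factor: float = 3.0
    k_peaks: int = 2
    min_cycles: float = 1.0
    overrides_path: str | None = None     # manual window CSV
    fit: FitOptions = field(default_factory=FitOptions)
    filters: FitFilterCriteria = field(default_factory=FitFilterCriteria)
    duration_threshold_factor: float = 3.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ConfigError("config needs exactly one of 'cohort' or 'manifest'")
        for name in ("threshold_factor", "min_cycles", "duration_threshold_factor"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; nested sections map onto the dataclasses."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    try:
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            groups = [GroupSpec(**g) for g in cohort.pop("groups")]
            for g in groups:
                g.free_s_by_excitation = {
                    str(k): float(v) for k, v in g.free_s_by_excitation.items()
                }
            trend = cohort.pop("trend", None)
            cohort = CohortSpec(groups=groups, **cohort)
            if trend is not None:
                cohort.trend = tuple(float(v) for v in trend)
        fit = FitOptions(**raw.pop("fit", {}))
        filters = raw.pop("filters", {})
        if "group_keys" in filters:
            filters["group_keys"] = tuple(filters["group_keys"])
        filters = FitFilterCriteria(**filters)
        return PipelineConfig(cohort=cohort, fit=fit, filters=filters, **raw)
    except (TypeError, KeyError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid config: {exc}") from exc


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _noise_span(rec: Recording, quiet_s: float | None) -> tuple[int, int]:
    fs = rec.sample_rate_hz
    if quiet_s is not None:
        return (0, min(int(round(quiet_s * fs)), rec.n_samples))
    imp = rec.meta.extra.get("impact_start_s")
    if imp:
        return (0, int(round(imp * fs)))
    return (0, min(int(round(0.05 * fs)), rec.n_samples))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle; returns a result dict
    with the in-memory tables and stage counts."""
    config.validate()
    if config.cohort is not None and config.seed is not None:
        config.cohort.seed = int(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- acquire recordings -------------------------------------------------
    truth = None
    if config.cohort is not None:
        recordings, truth = generate_cohort(config.cohort)
        truth.to_csv(out / "truth.csv", index=False)
        if config.write_wav:
            wav_dir = out / "recordings"
            for rec in recordings:
                path = wav_dir / f"{rec.meta.recording_id}.wav"
                write_recording(rec, path)
                rec.meta.source_path = str(path)
            write_manifest(recordings, out / "manifest.csv")
    else:
        recordings = read_manifest(config.manifest)

    overrides = (
        load_window_overrides(config.overrides_path)
        if config.overrides_path
        else {}
    )
    wopts = WindowOptions(
        threshold_factor=config.threshold_factor,
        k_peaks=config.k_peaks,
        min_cycles=config.min_cycles,
    )

    # --- windows, noise, metrics -------------------------------------------
    windows = []
    noise_by_id: dict[str, NoiseStats] = {}
    metrics_rows = []
    for rec in recordings:
        rid = rec.meta.recording_id
        noise = estimate_noise_floor(rec, _noise_span(rec, config.quiet_s))
        noise_by_id[rid] = noise
        if rid in overrides:
            win = window_from_bounds(rec, *overrides[rid])
        else:
            win = select_free_window(rec, noise, wopts)
        if win is not None:
            windows.append(win)
        metrics_rows.append(
            {
                "recording_id": rid,
                "group": rec.meta.group,
                "clutch_id": rec.meta.clutch_id,
                "excitation_type": rec.meta.excitation_type,
                "replicate": rec.meta.replicate,
                "noise_rms": noise.rms,
                "peak_amplitude": peak_amplitude(rec),
                "total_duration_s": total_duration(
                    rec, noise, config.duration_threshold_factor
                ),
            }
        )
    metrics = pd.DataFrame(metrics_rows)
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    win_df = windows_table(windows)
    win_df.to_csv(out / "windows.csv", index=False, float_format="%.10g")

    # --- fits ---------------------------------------------------------------
    meta_by_id = {r.meta.recording_id: r.meta for r in recordings}
    fit_rows = []
    for win in windows:
        check = validate_window(win, min_cycles=config.min_cycles)
        if not check.passes:
            continue
        try:
            fit = fit_window(win, config.fit)
        except (ValueError, np.linalg.LinAlgError):
            continue
        m = meta_by_id[win.recording_id]
        fit_rows.append(
            {
                "recording_id": win.recording_id,
                "group": m.group,
                "clutch_id": m.clutch_id,
                "excitation_type": m.excitation_type,
                "start_s": win.start_s,
                "end_s": win.end_s,
                "window_duration_s": win.duration_s,
                "frequency_hz": fit.frequency_hz,
                "tau_s": fit.tau_s,
                "a1": fit.params.a1,
                "a2": fit.params.a2,
                "a3": fit.params.a3,
                "a4": fit.params.a4,
                "a5": fit.params.a5,
                "epsilon": fit.epsilon,
                "converged": fit.converged,
            }
        )
    fits = pd.DataFrame(fit_rows)

    counts = {
        "recordings": len(recordings),
        "windows": len(windows),
        "fits": len(fits),
    }
    if fits.empty:
        fits.to_csv(out / "fits.csv", index=False)
        _write_run_manifest(out, config, counts | {"accepted": 0})
        raise EmptyAcceptedError("no window produced a fit", counts)

    accepted, rejected = apply_fit_filters(fits, config.filters)
    full = pd.concat([accepted, rejected]).sort_index()
    full.to_csv(out / "fits.csv", index=False, float_format="%.10g")
    counts["accepted"] = len(accepted)

    # --- attenuation --------------------------------------------------------
    atten_results = []
    for clutch_id, sub in metrics.groupby("clutch_id", sort=True):
        p1 = sub.loc[sub.excitation_type == "pendulum_1cm", "peak_amplitude"]
        p2 = sub.loc[sub.excitation_type == "pendulum_2cm", "peak_amplitude"]
        if len(p1) and len(p2):
            atten_results.append(
                spatial_attenuation(p1.tolist(), p2.tolist(), str(clutch_id))
            )
    if atten_results:
        atten = attenuation_table(atten_results)
        atten = atten.merge(
            metrics[["clutch_id", "group"]].drop_duplicates(), on="clutch_id"
        )
        atten.to_csv(out / "attenuation.csv", index=False, float_format="%.10g")
    else:
        atten = pd.DataFrame()

    # --- group stats --------------------------------------------------------
    stats = _group_stats(accepted, metrics, atten)
    stats.to_csv(out / "stats.csv", index=False, float_format="%.10g")

    # --- recovery -----------------------------------------------------------
    recovery = None
    if truth is not None and not accepted.empty:
        recovery = recovery_metrics(truth, accepted)
        (out / "recovery.json").write_text(json.dumps(recovery.to_dict(), indent=1))
        recovery.per_parameter.to_csv(
            out / "recovery.csv", index=False, float_format="%.10g"
        )

    if accepted.empty:
        _write_run_manifest(out, config, counts)
        raise EmptyAcceptedError(
            "all fits rejected by acceptance filters", counts
        )
    _write_run_manifest(out, config, counts)
    return {
        "out_dir": str(out),
        "counts": counts,
        "truth": truth,
        "windows": win_df,
        "fits": full,
        "accepted": accepted,
        "metrics": metrics,
        "attenuation": atten,
        "stats": stats,
        "recovery": recovery,
    }


def _group_stats(
    accepted: pd.DataFrame, metrics: pd.DataFrame, atten: pd.DataFrame
) -> pd.DataFrame:
    """Per-group summaries plus Welch comparisons when exactly 2 groups exist."""
    rows = []
    sources = [
        (accepted, ["frequency_hz", "tau_s", "epsilon", "window_duration_s"]),
        (metrics, ["peak_amplitude", "total_duration_s"]),
    ]
    if not atten.empty:
        sources.append((atten, ["absolute_change", "proportional"]))
    for df, variables in sources:
        if df.empty or "group" not in df.columns:
            continue
        for var in variables:
            summaries = {}
            for grp, sub in df.groupby("group", sort=True):
                vals = sub[var].dropna()
                if len(vals):
                    summaries[grp] = summarize(vals)
            for grp, s in summaries.items():
                rows.append(
                    {"variable": var, "group": grp, "n": s.n, "mean": s.mean,
                     "sd": s.sd, "min": s.min, "max": s.max,
                     "t": np.nan, "df": np.nan, "p": np.nan}
                )
            if len(summaries) == 2:
                (g1, s1), (g2, s2) = sorted(summaries.items())
                try:
                    w = welch_t(s1, s2)
                except ValueError:
                    continue
                rows.append(
                    {"variable": var, "group": f"{g1} vs {g2}",
                     "n": s1.n + s2.n, "mean": np.nan, "sd": np.nan,
                     "min": np.nan, "max": np.nan,
                     "t": w.t, "df": w.df, "p": w.p}
                )
    return pd.DataFrame(rows)


def _write_run_manifest(out: Path, config: PipelineConfig, counts: dict) -> None:
    manifest = {
        "package": "clutchvibe",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": int(config.seed),
        "stage_counts": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
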