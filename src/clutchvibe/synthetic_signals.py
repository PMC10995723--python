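"""Synthetic accelerometer recordings with known ground truth.

Each synthetic excitation test strings together four segments: a quiet
baseline, a broadband forced transient (white Gaussian burst with an
exponentially decaying envelope — it exists only to exercise window
detection), a free vibration that follows the damped-sinusoid-plus-trend
model exactly, and a quiet tail.  Additive white Gaussian noise covers the
whole trace.  Cohorts draw per-clutch (frequency, tau) pairs from
truncated-normal group distributions and emit a tidy truth table so that
parameter-recovery studies can score the full pipeline against what
generated the data.

Species presets follow the two treefrogs whose clutches motivated the model:
Agalychnis spurrelli (stiff, fast-damping clutches, ~105 Hz free vibration,
tau ~ 0.02 s) and A. callidryas (soft gelatinous clutches, ~26 Hz,
tau ~ 0.10 s).

Signal-to-noise convention: SNR = RMS(noise-free free-vibration segment) /
noise_sd.  Amplitudes are arbitrary (default A1 = A2 = 1 m/s^2) since the
field study reports no absolute calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .modal_fit import ModalParams, eval_model
from .signal_io import EXCITATION_TYPES, Recording, RecordingMeta

__all__ = [
    "SyntheticSpec",
    "GroupSpec",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "noise_sd_for_snr",
    "spurrelli_signal_preset",
    "callidryas_signal_preset",
    "species_cohort_spec",
    "TRUTH_COLUMNS",
]


@dataclass
class SyntheticSpec:
    """Ground-truth description of one synthetic excitation recording."""

    frequency_hz: float = 25.65
    tau_s: float = 0.10
    amp_cos: float = 1.0           # A1, m/s^2
    amp_sin: float = 1.0           # A2, m/s^2
    trend: tuple[float, float, float] = (0.0, 0.0, 0.0)   # A3, A4, A5
    sample_rate_hz: float = 44100.0
    pre_s: float = 0.05
    impact_s: float = 0.03
    free_s: float = 0.40
    post_s: float = 0.10
    noise_sd: float = 0.0          # m/s^2
    impact_gain: float = 5.0       # transient peak scale, m/s^2

    def validate(self) -> None:
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be > 0")
        if not self.tau_s > 0:
            raise ValueError("tau_s must be > 0")
        if not self.sample_rate_hz > 2 * self.frequency_hz:
            raise ValueError(
                f"sample rate {self.sample_rate_hz} Hz violates Nyquist for "
                f"a {self.frequency_hz} Hz mode (need > {2 * self.frequency_hz})"
            )
        for name in ("pre_s", "impact_s", "free_s", "post_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.free_s > 0:
            raise ValueError("free_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def total_s(self) -> float:
        return self.pre_s + self.impact_s + self.free_s + self.post_s

    def modal_params(self) -> ModalParams:
        a3, a4, a5 = self.trend
        return ModalParams(
            omega=2.0 * np.pi * self.frequency_hz,
            tau=self.tau_s,
            a1=self.amp_cos,
            a2=self.amp_sin,
            a3=a3,
            a4=a4,
            a5=a5,
        )

    def boundaries(self) -> tuple[int, int, int, int]:
        """Cumulative-rounded segment boundaries (samples), so the total
        sample count equals round(total_s * sample_rate_hz) exactly."""
        fs = self.sample_rate_hz
        b1 = round(self.pre_s * fs)
        b2 = round((self.pre_s + self.impact_s) * fs)
        b3 = round((self.pre_s + self.impact_s + self.free_s) * fs)
        n = round(self.total_s * fs)
        return int(b1), int(b2), int(b3), int(n)


def _clean_free_segment(spec: SyntheticSpec) -> np.ndarray:
    b1, b2, b3, _ = spec.boundaries()
    t = np.arange(b3 - b2) / spec.sample_rate_hz
    return eval_model(spec.modal_params(), t)


def noise_sd_for_snr(spec: SyntheticSpec, snr: float) -> float:
    """Noise SD giving the requested SNR = RMS(clean free segment) / noise_sd."""
    if not snr > 0:
        raise ValueError("snr must be > 0")
    clean = _clean_free_segment(spec)
    return float(np.sqrt(np.mean(clean * clean)) / snr)


def generate_recording(
    spec: SyntheticSpec, seed: int, meta: RecordingMeta | None = None
) -> Recording:
    """Render one synthetic recording; a pure function of (spec, seed).

    The free segment equals the model evaluated with t=0 at its own start
    (computed by the same routine the fitter uses, so noise-free generation
    reproduces model output bitwise).  Ground truth and segment boundaries
    are recorded in ``meta.extra``.
    """
    spec.validate()
    b1, b2, b3, n = spec.boundaries()
    fs = spec.sample_rate_hz
    rng = np.random.default_rng(seed)

    x = np.zeros(n)
    if b2 > b1 and spec.impact_gain != 0:
        t_imp = np.arange(b2 - b1) / fs
        decay_tc = max(spec.impact_s / 3.0, 1.0 / fs)
        x[b1:b2] = (
            spec.impact_gain
            * rng.standard_normal(b2 - b1)
            * np.exp(-t_imp / decay_tc)
        )
    x[b2:b3] = _clean_free_segment(spec)
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(n)

    meta = meta or RecordingMeta()
    meta.extra = dict(
        meta.extra,
        true_frequency_hz=spec.frequency_hz,
        true_tau_s=spec.tau_s,
        a1=spec.amp_cos,
        a2=spec.amp_sin,
        a3=spec.trend[0],
        a4=spec.trend[1],
        a5=spec.trend[2],
        noise_sd=spec.noise_sd,
        seed=int(seed),
        impact_start_s=b1 / fs,
        free_start_s=b2 / fs,
        free_end_s=b3 / fs,
    )
    return Recording(samples=x, sample_rate_hz=fs, meta=meta)


@dataclass
class GroupSpec:
    """Between-clutch distribution of modal parameters for one group."""

    label: str
    n_clutches: int
    freq_mean_hz: float
    freq_sd_hz: float
    tau_mean_s: float
    tau_sd_s: float
    #: free-vibration duration per excitation type: seconds, or a
    #: (mean, sd) pair for per-recording truncated-normal draws
    free_s_by_excitation: dict[str, float | tuple[float, float]] = field(
        default_factory=dict
    )
    replicates_per_type: int = 5

    def validate(self) -> None:
        if self.n_clutches < 1:
            raise ValueError("n_clutches must be >= 1")
        if self.replicates_per_type < 1:
            raise ValueError("replicates_per_type must be >= 1")
        if self.freq_sd_hz < 0 or self.tau_sd_s < 0:
            raise ValueError("SDs must be >= 0")
        if not self.free_s_by_excitation:
            raise ValueError(f"group {self.label}: no excitation types")
        unknown = set(self.free_s_by_excitation) - EXCITATION_TYPES
        if unknown:
            raise ValueError(f"unknown excitation types {sorted(unknown)}")
        for exc, dur in self.free_s_by_excitation.items():
            mean, sd = (dur, 0.0) if np.isscalar(dur) else dur
            if not mean > 0 or sd < 0:
                raise ValueError(
                    f"group {self.label}, {exc}: bad free duration {dur}"
                )


@dataclass
class CohortSpec:
    """Full simulated study: one or more groups plus shared signal settings."""

    groups: list[GroupSpec]
    seed: int = 0
    sample_rate_hz: float = 44100.0
    snr: float | None = 10.0       # None -> use noise_sd directly
    noise_sd: float = 0.0
    amp_cos: float = 1.0
    amp_sin: float = 1.0
    trend: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pre_s: float = 0.05
    impact_s: float = 0.03
    post_s: float = 0.05
    impact_gain: float = 5.0
    #: enforce the sampling rule that a free segment holds >= 1 full cycle
    #: (free_s is floored at one period of the clutch frequency)
    enforce_one_cycle: bool = True

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            g.validate()


TRUTH_COLUMNS = [
    "recording_id", "group", "clutch_id", "excitation_type", "replicate",
    "true_frequency_hz", "true_tau_s", "a1", "a2", "a3", "a4", "a5",
    "noise_sd", "seed", "free_start_s", "free_end_s",
]

_MAX_TRUNCATION_RETRIES = 100


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   what: str, label: str, floor: float = 0.0) -> float:
    if sd == 0:
        if mean <= floor:
            raise ValueError(f"group {label}: non-positive mean {what}")
        return mean
    for _ in range(_MAX_TRUNCATION_RETRIES):
        v = rng.normal(mean, sd)
        if v > floor:
            return float(v)
    raise ValueError(
        f"group {label}: no positive {what} draw in "
        f"{_MAX_TRUNCATION_RETRIES} tries (mean {mean}, sd {sd})"
    )


def _derived_seed(*keys: int) -> int:
    """Stable per-recording seed below 2^31, order-independent across cohorts."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(
    cohort: CohortSpec,
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate every recording of a cohort and its ground-truth table.

    Per clutch one (frequency, tau) pair is drawn from the group distribution
    truncated at positive values; per excitation type,
    ``replicates_per_type`` recordings are rendered.  All randomness derives
    from the root seed via per-stream hashed seeds, so cohorts are
    reproducible and order-independent.
    """
    cohort.validate()
    recordings: list[Recording] = []
    rows = []
    for gi, grp in enumerate(cohort.groups):
        for ci in range(grp.n_clutches):
            rng = np.random.default_rng(
                np.random.SeedSequence([cohort.seed, gi, ci, 0xC1])
            )
            f = _draw_positive(rng, grp.freq_mean_hz, grp.freq_sd_hz,
                               "frequency", grp.label)
            tau = _draw_positive(rng, grp.tau_mean_s, grp.tau_sd_s,
                                 "tau", grp.label)
            clutch_id = f"{grp.label}-c{ci:02d}"
            for ti, (exc, dur) in enumerate(
                sorted(grp.free_s_by_excitation.items())
            ):
                dur_mean, dur_sd = (dur, 0.0) if np.isscalar(dur) else dur
                for ri in range(grp.replicates_per_type):
                    if dur_sd > 0:
                        rng_dur = np.random.default_rng(
                            np.random.SeedSequence(
                                [cohort.seed, gi, ci, ti, ri, 0xF5]
                            )
                        )
                        free_s = _draw_positive(
                            rng_dur, dur_mean, dur_sd,
                            f"free duration ({exc})", grp.label,
                            floor=0.004,
                        )
                    else:
                        free_s = dur_mean
                    if cohort.enforce_one_cycle:
                        free_s = max(free_s, 1.0 / f)
                    spec = SyntheticSpec(
                        frequency_hz=f,
                        tau_s=tau,
                        amp_cos=cohort.amp_cos,
                        amp_sin=cohort.amp_sin,
                        trend=cohort.trend,
                        sample_rate_hz=cohort.sample_rate_hz,
                        pre_s=cohort.pre_s,
                        impact_s=cohort.impact_s,
                        free_s=free_s,
                        post_s=cohort.post_s,
                        noise_sd=cohort.noise_sd,
                        impact_gain=cohort.impact_gain,
                    )
                    if cohort.snr is not None:
                        spec = replace(
                            spec, noise_sd=noise_sd_for_snr(spec, cohort.snr)
                        )
                    seed = _derived_seed(cohort.seed, gi, ci, ti, ri)
                    rec_id = f"{clutch_id}-{exc}-r{ri}"
                    distance = {"pendulum_1cm": 1.0, "pendulum_2cm": 2.0}.get(exc)
                    meta = RecordingMeta(
                        recording_id=rec_id,
                        group=grp.label,
                        clutch_id=clutch_id,
                        excitation_type=exc,
                        replicate=ri,
                        distance_cm=distance,
                    )
                    rec = generate_recording(spec, seed, meta=meta)
                    recordings.append(rec)
                    e = rec.meta.extra
                    rows.append(
                        [rec_id, grp.label, clutch_id, exc, ri,
                         f, tau, spec.amp_cos, spec.amp_sin,
                         spec.trend[0], spec.trend[1], spec.trend[2],
                         spec.noise_sd, seed,
                         e["free_start_s"], e["free_end_s"]]
                    )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return recordings, truth


# ---------------------------------------------------------------------------
# Species presets
# ---------------------------------------------------------------------------

#: Sampled-window lengths (mean, SD in s) per excitation test, by species,
#: from the field study's fitted windows.
SPURRELLI_WINDOW_S = {
    "pendulum_1cm": (0.036, 0.022),
    "pendulum_2cm": (0.028, 0.019),
    "drop_large": (0.018, 0.012),
    "drop_small": (0.017, 0.007),
}
CALLIDRYAS_WINDOW_S = {
    "pendulum_1cm": (0.137, 0.075),
    "pendulum_2cm": (0.160, 0.102),
    "drop_large": (0.147, 0.108),
    "drop_small": (0.16, 0.115),
}


def spurrelli_signal_preset(**overrides) -> SyntheticSpec:
    """Single-recording preset for A. spurrelli: ~105 Hz, tau ~ 0.02 s,
    event (impact + free) duration ~ 0.15 s."""
    spec = SyntheticSpec(
        frequency_hz=105.15, tau_s=0.02, impact_s=0.03, free_s=0.12
    )
    return replace(spec, **overrides)


def callidryas_signal_preset(**overrides) -> SyntheticSpec:
    """Single-recording preset for A. callidryas: ~26 Hz, tau ~ 0.10 s,
    event duration ~ 0.44 s."""
    spec = SyntheticSpec(
        frequency_hz=25.65, tau_s=0.10, impact_s=0.04, free_s=0.40
    )
    return replace(spec, **overrides)


def species_cohort_spec(
    seed: int = 0,
    sample_rate_hz: float = 44100.0,
    snr: float | None = 10.0,
    n_clutches_spurrelli: int = 16,
    n_clutches_callidryas: int = 17,
    replicates_per_type: int = 5,
) -> CohortSpec:
    """Two-species cohort matching the field study's design: 16 A. spurrelli
    and 17 A. callidryas clutches, 4 excitation types, 5 replicates each,
    between-clutch parameter spread at the reported across-clutch SDs, and
    free-segment durations set to the species' mean fitted-window lengths."""
    groups = [
        GroupSpec(
            label="A_spurrelli",
            n_clutches=n_clutches_spurrelli,
            freq_mean_hz=105.15,
            freq_sd_hz=36.7,
            tau_mean_s=0.02,
            tau_sd_s=0.02,
            free_s_by_excitation=dict(SPURRELLI_WINDOW_S),
            replicates_per_type=replicates_per_type,
        ),
        GroupSpec(
            label="A_callidryas",
            n_clutches=n_clutches_callidryas,
            freq_mean_hz=25.65,
            freq_sd_hz=26.06,
            tau_mean_s=0.10,
            tau_sd_s=0.06,
            free_s_by_excitation=dict(CALLIDRYAS_WINDOW_S),
            replicates_per_type=replicates_per_type,
        ),
    ]
    return CohortSpec(groups=groups, seed=seed,
                      sample_rate_hz=sample_rate_hz, snr=snr)
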