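"""Locating the free-vibration segment of an excitation recording.

After an impact (pendulum strike or water drop) a recording shows three
phases: quiet baseline, an irregular broadband forced transient, and a free
decaying oscillation that eventually sinks below the noise floor.  Only the
free phase obeys the single-mode damped-sinusoid model, so fitting windows
must start once the forced transient has rung down and stop when the signal
is indistinguishable from noise.  The field workflow selected such windows
by eye; here an envelope heuristic does the same job and a manual-override
table can replace it for any recording.

The envelope operator is the magnitude of the analytic (Hilbert) signal
smoothed by a moving average of roughly one vibration period; the nominal
period is bootstrapped from the dominant spectral peak after the impact
maximum unless a frequency hint is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert

from .signal_io import Recording

__all__ = [
    "NoiseStats",
    "Window",
    "WindowOptions",
    "WindowCheck",
    "count_zero_crossings",
    "estimate_noise_floor",
    "smoothed_envelope",
    "coarse_frequency",
    "bootstrap_f_nominal",
    "select_free_window",
    "window_from_bounds",
    "validate_window",
    "load_window_overrides",
    "windows_table",
]


def count_zero_crossings(x: np.ndarray) -> int:
    """Number of sign changes, ignoring exact zeros."""
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


@dataclass
class NoiseStats:
    """Noise-floor estimate from a quiet span of a recording."""

    rms: float                       # m/s^2
    segment: tuple[int, int]         # half-open sample span used

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("rms must be >= 0")


@dataclass
class Window:
    """Half-open sample span of a recording holding a candidate free vibration.

    Times are measured from the window start (t=0 at start_idx), which shifts
    only the phase/trend coefficients of the model, never omega or tau.
    """

    recording_id: str
    start_idx: int
    end_idx: int
    sample_rate_hz: float
    samples: np.ndarray
    detection_mode: str = "auto"     # auto | manual

    def __post_init__(self) -> None:
        if not (0 <= self.start_idx < self.end_idx):
            raise ValueError(
                f"invalid span [{self.start_idx}, {self.end_idx})"
            )
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != self.end_idx - self.start_idx:
            raise ValueError("samples length does not match index span")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def start_s(self) -> float:
        return self.start_idx / self.sample_rate_hz

    @property
    def end_s(self) -> float:
        return self.end_idx / self.sample_rate_hz

    @property
    def n_zero_crossings(self) -> int:
        return count_zero_crossings(self.samples - self.samples.mean())


@dataclass
class WindowOptions:
    threshold_factor: float = 3.0    # noise-floor multiple ending the window
    k_peaks: int = 2                 # consecutive non-increasing envelope peaks
    min_cycles: float = 1.0          # shortest admissible window, in periods
    smooth_periods: float = 1.0      # envelope moving-average width, in periods
    f_hint_hz: float | None = None   # skip the spectral bootstrap if known


def estimate_noise_floor(
    recording: Recording, quiet_span: tuple[int, int]
) -> NoiseStats:
    """RMS of a linearly detrended quiet span (>= 10 ms long)."""
    lo, hi = quiet_span
    if not (0 <= lo < hi <= recording.n_samples):
        raise ValueError(f"span {quiet_span} outside recording")
    if (hi - lo) / recording.sample_rate_hz < 0.010:
        raise ValueError(
            f"quiet span of {hi - lo} samples is shorter than 10 ms"
        )
    x = recording.samples[lo:hi]
    t = np.arange(x.size, dtype=float)
    coef = np.polynomial.polynomial.polyfit(t, x, 1)
    resid = x - np.polynomial.polynomial.polyval(t, coef)
    return NoiseStats(rms=float(np.sqrt(np.mean(resid * resid))), segment=(lo, hi))


def coarse_frequency(samples: np.ndarray, sample_rate_hz: float) -> float:
    """Dominant spectral frequency (Hz) of a mean-removed segment."""
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    if x.size < 4 or not np.any(x):
        return sample_rate_hz / x.size if x.size else sample_rate_hz
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate_hz)
    k = int(np.argmax(spec[1:])) + 1
    f = freqs[k]
    return float(f) if f > 0 else sample_rate_hz / x.size


def bootstrap_f_nominal(
    samples: np.ndarray, sample_rate_hz: float, i_max: int, noise_rms: float
) -> float:
    """Coarse vibration frequency for envelope smoothing.

    Estimated from the ringing region after the |a| maximum — the span where
    |a| still clears the noise floor (or 10% of the peak when the floor is
    zero) — so that trailing noise cannot drag the estimate down and widen
    the smoother.
    """
    tail = np.asarray(samples, dtype=float)[i_max:]
    if tail.size < 8:
        return 0.0
    level = max(5.0 * noise_rms, 0.1 * np.abs(tail[0]))
    above = np.nonzero(np.abs(tail) > level)[0]
    i_hi = int(above[-1]) + 1 if above.size else tail.size
    i_hi = max(i_hi, 8)
    return coarse_frequency(tail[:i_hi], sample_rate_hz)


def smoothed_envelope(
    samples: np.ndarray, sample_rate_hz: float, f_nominal_hz: float,
    smooth_periods: float = 1.0,
) -> np.ndarray:
    """|analytic signal| smoothed by a moving average of ~one nominal period."""
    env = np.abs(hilbert(np.asarray(samples, dtype=float)))
    width = max(1, int(round(smooth_periods * sample_rate_hz / f_nominal_hz)))
    width = min(width, env.size)
    kernel = np.ones(width) / width
    return np.convolve(env, kernel, mode="same")


def _onset_after_dip(env: np.ndarray, i_max: int) -> int | None:
    """Free-vibration onset peak after a significant envelope dip.

    A broadband burst shows several comparable envelope spikes with deep
    dips between them, while the smoothed envelope of the free decay is far
    too regular for measurement noise to fake a 20%+ dip; the last dip
    followed by a dominant rise therefore marks the transient/free boundary.
    The post-dip peak must also carry a substantial fraction of the overall
    envelope so that noise-floor wiggles late in the decay cannot qualify.
    """
    seg = env[i_max:]
    if seg.size < 3:
        return None
    top = seg.max()
    minima, _ = find_peaks(-seg, prominence=0.1 * top)
    for m in reversed(minima):
        rest = seg[m:]
        p = m + int(np.argmax(rest))
        if p == m:
            continue
        if seg[m] < 0.8 * seg[p] and seg[p] >= 0.1 * top:
            return i_max + p
    return None


def select_free_window(
    recording: Recording,
    noise: NoiseStats,
    opts: WindowOptions | None = None,
) -> Window | None:
    """Automatic free-vibration window, or None when no span qualifies.

    The window starts at the first envelope peak after the global |a| maximum
    from which the smoothed envelope is non-increasing for ``k_peaks``
    consecutive peaks (the forced transient has rung down) and ends at the
    first sample where the envelope drops below ``threshold_factor`` times
    the noise-floor RMS (or at the last nonzero sample when the noise floor
    is zero, or at the recording end).  Absence of a qualifying span is a
    value, not an error.
    """
    opts = opts or WindowOptions()
    x = recording.samples
    fs = recording.sample_rate_hz
    i_max = int(np.argmax(np.abs(x)))

    if opts.f_hint_hz is not None:
        f_nom = opts.f_hint_hz
    else:
        f_nom = bootstrap_f_nominal(x, fs, i_max, noise.rms)
    if not f_nom > 0:
        return None

    env_raw = np.abs(hilbert(x))
    width = max(1, min(int(round(opts.smooth_periods * fs / f_nom)), x.size))
    env = np.convolve(env_raw, np.ones(width) / width, mode="same")
    threshold = opts.threshold_factor * noise.rms

    # Preferred onset: the forced transient rings down before the free
    # vibration, so its end shows as a clear envelope dip followed by a
    # dominant rise.  When impact and free vibration blend into one hump
    # (slow modes), fall back to the first envelope peak after the maximum
    # from which k consecutive peaks are non-increasing.
    start = _onset_after_dip(env, i_max)
    if start is None:
        # No clear dip: the smoother has merged the forced and free humps.
        p_top = i_max + int(np.argmax(env[i_max:]))
        if env[p_top] > 1.1 * env[i_max]:
            # the envelope still rises after the |a| maximum, so the free
            # vibration dominates the merged hump: start at its top
            start = p_top
        else:
            # forced energy dominates: wait for the envelope to shed half
            # the crown (which sits at the forced/free boundary), then take
            # the first nearby peak from which k consecutive peaks are
            # non-increasing
            crown = 0.5 * env[i_max]
            below = np.nonzero(env[i_max:] <= crown)[0]
            if below.size:
                start = i_max + int(below[0])
                peaks, _ = find_peaks(env[i_max:])
                peaks = peaks + i_max
                for j in range(len(peaks)):
                    if peaks[j] < start or peaks[j] > start + len(env) // 20:
                        continue
                    upper = peaks[j : j + opts.k_peaks + 1]
                    if upper.size < opts.k_peaks + 1:
                        break
                    vals = env[upper]
                    if np.all(np.diff(vals) <= 0):
                        start = int(peaks[j])
                        break
    if start is None:
        return None
    if threshold > 0 and env[start] < threshold:
        return None   # nothing above the noise floor: e.g. pure-noise input

    if threshold > 0:
        below = np.nonzero(env[start:] < threshold)[0]
        if below.size:
            # the moving average lags a decaying edge by up to w/2; walk back
            # from the smoothed crossing to where the raw envelope itself
            # last cleared the threshold
            i_cross = start + int(below[0])
            still_above = np.nonzero(env_raw[start:i_cross] >= threshold)[0]
            end = start + int(still_above[-1]) + 1 if still_above.size else start + 2
        else:
            end = recording.n_samples
    else:
        nonzero = np.nonzero(x)[0]
        end = int(nonzero[-1]) + 1 if nonzero.size else recording.n_samples
    if end <= start + 1:
        return None
    return Window(
        recording_id=recording.meta.recording_id,
        start_idx=start,
        end_idx=end,
        sample_rate_hz=fs,
        samples=x[start:end],
        detection_mode="auto",
    )


def window_from_bounds(
    recording: Recording, start_s: float, end_s: float, detection_mode: str = "manual"
) -> Window:
    """Window from explicit second bounds (manual override path)."""
    fs = recording.sample_rate_hz
    start = int(round(start_s * fs))
    end = int(round(end_s * fs))
    start = max(start, 0)
    end = min(end, recording.n_samples)
    return Window(
        recording_id=recording.meta.recording_id,
        start_idx=start,
        end_idx=end,
        sample_rate_hz=fs,
        samples=recording.samples[start:end],
        detection_mode=detection_mode,
    )


@dataclass
class WindowCheck:
    passes: bool
    reasons: list[str] = field(default_factory=list)


#: fewest samples a fittable window may hold; the model has 7 parameters and
#: anything close to that is guaranteed to overfit
MIN_WINDOW_SAMPLES = 32


def validate_window(
    window: Window, min_cycles: float = 1.0, f_hint: float | None = None
) -> WindowCheck:
    """Check the sampling criteria: at least ``min_cycles`` full cycles of
    the (hinted or estimated) frequency, at least 2 zero crossings, and
    enough samples to constrain the 7-parameter model."""
    reasons = []
    if f_hint is None:
        f_hint = coarse_frequency(window.samples, window.sample_rate_hz)
    if not f_hint > 0:
        raise ValueError("f_hint must be positive")
    if window.duration_s < min_cycles / f_hint:
        reasons.append("below_min_cycles")
    if window.n_zero_crossings < 2:
        reasons.append("zero_crossings")
    if window.samples.size < MIN_WINDOW_SAMPLES:
        reasons.append("too_few_samples")
    return WindowCheck(passes=not reasons, reasons=reasons)


def load_window_overrides(csv_path: str | Path) -> dict[str, tuple[float, float]]:
    """Manual window table: CSV with recording_id, start_s, end_s columns."""
    df = pd.read_csv(csv_path)
    return {
        str(r.recording_id): (float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    }


def windows_table(windows: list[Window]) -> pd.DataFrame:
    """Tidy table of selected windows (one row per window)."""
    return pd.DataFrame(
        {
            "recording_id": [w.recording_id for w in windows],
            "start_s": [w.start_s for w in windows],
            "end_s": [w.end_s for w in windows],
            "duration_s": [w.duration_s for w in windows],
            "n_zero_crossings": [w.n_zero_crossings for w in windows],
            "detection_mode": [w.detection_mode for w in windows],
        }
    )
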