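"""Reading, writing and calibration of accelerometer recordings.

Recordings are mono acceleration traces (m/s^2) with provenance metadata.
On disk a recording is an IEEE float32 mono RIFF/WAV file plus a JSON
sidecar holding the metadata; batches are described by a manifest CSV whose
columns mirror :class:`RecordingMeta`.  Raw sensor units are converted to
acceleration by dividing by a single scalar calibration factor
(volts per m/s^2 times amplifier gain); frequency-dependent sensor response
is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "EXCITATION_TYPES",
    "RecordingMeta",
    "Recording",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
]

#: Closed vocabulary of mechanical excitation tests: pendulum impacts at 1 or
#: 2 cm from the embedded accelerometer, standardized large/small water drops.
EXCITATION_TYPES = frozenset(
    {"pendulum_1cm", "pendulum_2cm", "drop_large", "drop_small", "other"}
)


@dataclass
class RecordingMeta:
    """Provenance metadata for one excitation-test recording."""

    recording_id: str = ""
    group: str = ""               # species or treatment label
    clutch_id: str = ""
    excitation_type: str = "other"
    replicate: int = 0
    distance_cm: float | None = None
    calibration: float = 1.0      # raw units per (m/s^2); divides raw samples
    source_path: str = ""
    extra: dict = field(default_factory=dict)   # e.g. simulation ground truth

    def __post_init__(self) -> None:
        if self.excitation_type not in EXCITATION_TYPES:
            raise ValueError(
                f"excitation_type {self.excitation_type!r} not in "
                f"{sorted(EXCITATION_TYPES)}"
            )
        if self.calibration is not None and not self.calibration > 0:
            raise ValueError(f"calibration must be > 0, got {self.calibration}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Recording:
    """Calibrated, uniformly sampled acceleration trace.

    Attributes
    ----------
    samples : ndarray
        Acceleration in m/s^2.
    sample_rate_hz : float
        Sampling rate (44100 Hz in the field study).
    meta : RecordingMeta
    """

    samples: np.ndarray
    sample_rate_hz: float
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(
                f"samples must be 1-D (mono), got {self.samples.ndim} dims"
            )
        if self.samples.size < 2:
            raise ValueError("a recording needs at least 2 samples")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, t=0 at the first sample."""
        return np.arange(self.samples.size) / self.sample_rate_hz


def _sidecar_path(wav_path: Path) -> Path:
    return wav_path.with_suffix(".json")


def read_recording(
    wav_path: str | Path,
    meta: RecordingMeta | None = None,
    calibration: float | None = None,
) -> Recording:
    """Read a mono WAV file and return a calibrated Recording.

    The sample rate is taken from the file header.  Raw sample values are
    divided by the calibration factor (``meta.calibration`` unless
    ``calibration`` overrides it; default 1, i.e. the file already stores
    m/s^2).  If no metadata is supplied and a JSON sidecar exists next to the
    file, it is loaded.
    """
    wav_path = Path(wav_path)
    rate, raw = wavfile.read(wav_path)
    if raw.ndim != 1:
        raise ValueError(
            f"{wav_path} has {raw.shape[1]} channels; only mono is supported"
        )
    if meta is None:
        sidecar = _sidecar_path(wav_path)
        if sidecar.exists():
            meta = RecordingMeta(**json.loads(sidecar.read_text()))
        else:
            meta = RecordingMeta()
    meta.source_path = str(wav_path)
    cal = calibration if calibration is not None else meta.calibration
    if cal is None:
        cal = 1.0
    if not cal > 0:
        raise ValueError(f"calibration must be > 0, got {cal}")
    samples = np.asarray(raw, dtype=float) / cal
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{wav_path} contains non-finite samples")
    return Recording(samples=samples, sample_rate_hz=float(rate), meta=meta)


def write_recording(recording: Recording, wav_path: str | Path) -> Path:
    """Write a Recording as a 32-bit float mono WAV plus a JSON sidecar.

    The sidecar (same stem, ``.json``) holds every RecordingMeta field so the
    recording can be re-read without external bookkeeping.
    """
    wav_path = Path(wav_path)
    wav_path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(
        wav_path,
        int(round(recording.sample_rate_hz)),
        recording.samples.astype(np.float32),
    )
    meta = recording.meta.to_dict()
    _sidecar_path(wav_path).write_text(json.dumps(meta, indent=1, default=str))
    return wav_path


_MANIFEST_COLUMNS = [
    "recording_id",
    "group",
    "clutch_id",
    "excitation_type",
    "replicate",
    "distance_cm",
    "calibration",
    "source_path",
]


def write_manifest(recordings: list[Recording], csv_path: str | Path) -> Path:
    """Write a batch manifest CSV (one row per recording, RecordingMeta columns)."""
    rows = []
    for rec in recordings:
        d = rec.meta.to_dict()
        d.pop("extra", None)
        rows.append(d)
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(csv_path, index=False)
    return csv_path


def read_manifest(csv_path: str | Path) -> list[Recording]:
    """Read all recordings listed in a manifest CSV (source_path column)."""
    df = pd.read_csv(csv_path)
    recordings = []
    for _, row in df.iterrows():
        d = {k: row[k] for k in _MANIFEST_COLUMNS if k in row and pd.notna(row[k])}
        path = d.pop("source_path")
        meta = RecordingMeta(**d, source_path=str(path))
        recordings.append(read_recording(path, meta=meta))
    return recordings
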