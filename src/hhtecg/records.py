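"""Domain containers for single-lead ECG analysis and frame extraction.

The pipeline works on uniformly sampled single-channel (MLII-style) voltage
series.  Rhythm classes are identified by integer symptom IDs::

    1 = NSR   normal sinus rhythm
    2 = APC   atrial premature complex
    3 = AFib  atrial fibrillation
    4 = VPC   ventricular premature complex
    5 = VT    ventricular tachycardia

Analysis operates on fixed-length frames (default 3 s), each long enough to
contain a complete waveform of the symptom of interest.  Time is measured in
seconds from the start of the record and windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SYMPTOM_IDS: tuple[int, ...] = (1, 2, 3, 4, 5)
SYMPTOM_NAMES: dict[int, str] = {1: "NSR", 2: "APC", 3: "AFib", 4: "VPC", 5: "VT"}

#: Column order of the 6-dimensional centroid feature vector:
#: (frequency, power) centroids of the first three intrinsic mode functions.
FEATURE_NAMES: tuple[str, ...] = (
    "f1_freq", "f1_pow", "f2_freq", "f2_pow", "f3_freq", "f3_pow",
)


def _validate_label(label: int) -> int:
    label = int(label)
    if label not in SYMPTOM_IDS:
        raise ValueError(f"symptom label must be in 1..5, got {label}")
    return label


@dataclass
class ECGRecord:
    """A uniformly sampled single-channel voltage series.

    Parameters
    ----------
    samples
        Voltage samples in mV.
    fs
        Sampling rate in Hz (MIT-BIH-style records use 360 Hz).
    record_id
        Free-text identifier, used in output file names.
    annotations
        Optional interest points as ``(time_s, label)`` pairs with labels in
        1..5; times must lie within the record.
    """

    samples: np.ndarray
    fs: float = 360.0
    record_id: str = ""
    annotations: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("empty record")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        cleaned = []
        for time_s, label in self.annotations:
            label = _validate_label(label)
            if not 0.0 <= time_s <= self.duration_s:
                raise ValueError(
                    f"annotation time {time_s:g}s outside record [0, {self.duration_s:g}]s"
                )
            cleaned.append((float(time_s), label))
        self.annotations = cleaned

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Frame:
    """A fixed-length analysis window cut from an :class:`ECGRecord`."""

    samples: np.ndarray
    fs: float
    start_s: float = 0.0
    duration_s: float = 3.0
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_expected = round(self.duration_s * self.fs)
        if self.samples.size != n_expected:
            raise ValueError(
                f"frame has {self.samples.size} samples, expected {n_expected} "
                f"for {self.duration_s:g}s at {self.fs:g}Hz"
            )
        if self.label is not None:
            self.label = _validate_label(self.label)

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.fs


@dataclass
class AnnotationTrack:
    """Per-frame predicted labels, suitable for traceable display.

    Entries are ``(frame_start_s, frame_end_s, predicted_label, model_name)``,
    sorted by start time.
    """

    entries: list[tuple[float, float, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, label, _model in self.entries:
            if not end > start:
                raise ValueError("track entry must have end > start")
            _validate_label(label)
        self.entries = sorted(self.entries, key=lambda e: e[0])


@dataclass
class FeatureRecord:
    """A 6-dimensional centroid feature vector with an optional symptom label.

    ``flags`` carries quality warnings, e.g. ``"padded_imfs"`` when a frame
    decomposed into fewer than three modes and missing centroids were reported
    as (0, 0).
    """

    features: np.ndarray
    label: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).ravel()
        if self.features.size != len(FEATURE_NAMES):
            raise ValueError(
                f"feature vector must have {len(FEATURE_NAMES)} entries, "
                f"got {self.features.size}"
            )
        if self.label is not None:
            self.label = _validate_label(self.label)


def feature_matrix(records: list[FeatureRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature records into ``(X, y)`` arrays; unlabeled records get -1."""
    if not records:
        return np.empty((0, len(FEATURE_NAMES))), np.empty((0,), dtype=int)
    X = np.vstack([r.features for r in records])
    y = np.array([r.label if r.label is not None else -1 for r in records], dtype=int)
    return X, y


def frame_at_annotation(rec: ECGRecord, time_s: float, duration_s: float = 3.0) -> Frame:
    """Cut a frame covering the interest point at ``time_s``.

    The frame is centered on the annotation timestamp so the symptomatic
    waveform stays whole, and shifted inward (never truncated) when the
    centered window would cross a record edge.  The label of an annotation at
    exactly ``time_s`` is copied onto the frame.
    """
    n = duration_s * rec.fs
    n_samples = round(n)
    if not math.isclose(n, n_samples, rel_tol=0, abs_tol=1e-6):
        raise ValueError("duration_s times fs must be a whole number of samples")
    if rec.samples.size < n_samples:
        raise ValueError(
            f"record ({rec.duration_s:g}s) shorter than frame ({duration_s:g}s)"
        )
    start = time_s - duration_s / 2.0
    start = min(max(start, 0.0), rec.duration_s - duration_s)
    i0 = round(start * rec.fs)
    i0 = min(max(i0, 0), rec.samples.size - n_samples)
    label = None
    for t, lab in rec.annotations:
        if math.isclose(t, time_s, rel_tol=0, abs_tol=1e-9):
            label = lab
            break
    return Frame(
        samples=rec.samples[i0:i0 + n_samples],
        fs=rec.fs,
        start_s=i0 / rec.fs,
        duration_s=duration_s,
        label=label,
    )


def sliding_frames(
    rec: ECGRecord, duration_s: float = 3.0, overlap_s: float = 1.0
) -> list[Frame]:
    """Tile the record with overlapping frames for scanning.

    Frames start at 0 and advance by ``duration_s - overlap_s``; the last frame
    lies fully inside the record, so the count is
    ``floor((T - duration) / step) + 1``.
    """
    if not 0 <= overlap_s < duration_s:
        raise ValueError("overlap must satisfy 0 <= overlap < duration")
    step = duration_s - overlap_s
    n_samples = round(duration_s * rec.fs)
    if rec.samples.size < n_samples:
        raise ValueError(
            f"record ({rec.duration_s:g}s) shorter than frame ({duration_s:g}s)"
        )
    n_frames = int(math.floor((rec.duration_s - duration_s) / step + 1e-9)) + 1
    frames = []
    for i in range(n_frames):
        start = i * step
        i0 = round(start * rec.fs)
        frames.append(
            Frame(
                samples=rec.samples[i0:i0 + n_samples],
                fs=rec.fs,
                start_s=i0 / rec.fs,
                duration_s=duration_s,
            )
        )
    return frames
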