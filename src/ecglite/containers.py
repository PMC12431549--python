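"""Core in-memory containers shared across the pipeline.

The pipeline moves data through three representations:

* :class:`EcgRecord` — one patient's continuous single-lead ECG with beat
  annotations, as read from disk or produced by the synthetic generator.
* :class:`SegmentTable` — pre-segmented, pre-labeled 30-s segments in the
  smartwatch-export style (class codes 0.0=NSR, 1.0=AF, 2.0=PAC, 3.0=PVC).
* :class:`WindowSet` — the model-ready tensor of fixed-length, z-scored
  windows with one-hot labels and per-window patient IDs (patient IDs are
  what make leakage-free patient-wise splitting possible downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed enumeration of beat symbols the pipeline classifies.
BEAT_SYMBOLS = ("N", "L", "R", "A", "V")
NOISE = "NOISE"
OTHER = "OTHER"

#: Valid smartwatch-style segment class codes and their meanings.
SEGMENT_CODES = {0.0: "NSR", 1.0: "AF", 2.0: "PAC", 3.0: "PVC"}

#: Fixed class orders used for one-hot encoding.
MULTICLASS_ORDER = ("N", "L", "R", "A", "V")
BINARY_ORDER = ("Normal", "Arrhythmia")


@dataclass(frozen=True)
class BeatAnnotation:
    """A single annotation: 0-based sample index plus a symbol.

    ``symbol`` is one of the beat symbols N/L/R/A/V, the noise marker
    ``NOISE``, or ``OTHER`` for anything outside the closed enumeration.
    """

    index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"annotation index must be non-negative, got {self.index}")
        allowed = set(BEAT_SYMBOLS) | {NOISE, OTHER}
        if self.symbol not in allowed:
            raise ValueError(f"unknown annotation symbol {self.symbol!r}")

    @property
    def is_beat(self) -> bool:
        return self.symbol in BEAT_SYMBOLS


@dataclass
class EcgRecord:
    """One patient's continuous single-lead ECG.

    Amplitudes are in millivolts; ``fs`` is the sampling rate in Hz.
    Annotations are kept sorted by sample index and must fall inside the
    signal.
    """

    patient_id: str
    fs: float
    signal: np.ndarray
    annotations: list[BeatAnnotation] = field(default_factory=list)
    lead_name: str = "ECG"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.annotations = sorted(self.annotations, key=lambda a: a.index)
        for ann in self.annotations:
            if ann.index >= len(self.signal):
                raise ValueError(
                    f"annotation index {ann.index} beyond signal length {len(self.signal)}"
                )

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs

    def beat_annotations(self) -> list[BeatAnnotation]:
        return [a for a in self.annotations if a.is_beat]


@dataclass
class SegmentTable:
    """Rows of (patient_id, fixed-length segment, class code)."""

    patient_ids: list[str]
    segments: np.ndarray  # (n, segment_len)
    class_codes: np.ndarray  # (n,) floats from SEGMENT_CODES

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.class_codes = np.asarray(self.class_codes, dtype=np.float64)
        if self.segments.ndim != 2:
            raise ValueError("segments must be a 2-D array")
        n = self.segments.shape[0]
        if not (len(self.patient_ids) == n == len(self.class_codes)):
            raise ValueError("patient_ids, segments and class_codes disagree in length")
        for i, code in enumerate(self.class_codes):
            if float(code) not in SEGMENT_CODES:
                raise ValueError(
                    f"row {i}: unknown class code {code!r}; valid codes are "
                    f"{sorted(SEGMENT_CODES)}"
                )

    def __len__(self) -> int:
        return self.segments.shape[0]


@dataclass
class WindowSet:
    """Model-ready windows: n x window_len samples, one-hot labels, patient IDs."""

    windows: np.ndarray  # (n, window_len)
    labels_onehot: np.ndarray  # (n, K)
    patient_ids: list[str]
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels_onehot = np.asarray(self.labels_onehot, dtype=np.float64)
        self.patient_ids = list(self.patient_ids)
        self.class_order = tuple(self.class_order)
        if self.windows.ndim != 2 or self.labels_onehot.ndim != 2:
            raise ValueError("windows and labels_onehot must be 2-D arrays")
        n = self.windows.shape[0]
        if self.labels_onehot.shape[0] != n or len(self.patient_ids) != n:
            raise ValueError("windows, labels and patient_ids disagree in length")
        if self.labels_onehot.shape[1] != len(self.class_order):
            raise ValueError("label width does not match class_order")
        if n:
            rows = self.labels_onehot
            if not (np.all(rows.sum(axis=1) == 1) and np.all((rows == 0) | (rows == 1))):
                raise ValueError("labels_onehot rows must be one-hot")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def label_indices(self) -> np.ndarray:
        return np.argmax(self.labels_onehot, axis=1)

    def subset(self, idx: np.ndarray | list[int]) -> "WindowSet":
        idx = np.asarray(idx, dtype=np.intp)
        return WindowSet(
            windows=self.windows[idx],
            labels_onehot=self.labels_onehot[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            class_order=self.class_order,
        )

    def for_patients(self, patients: set[str] | list[str]) -> "WindowSet":
        patients = set(patients)
        idx = [i for i, p in enumerate(self.patient_ids) if p in patients]
        return self.subset(idx)
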