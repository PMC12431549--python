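"""Five-stage ECG preprocessing: baseline removal, wavelet denoising,
z-score normalization, fixed-window segmentation, and class coding.

The stages run in that order: the high-pass filter is applied to the
continuous signal (baseline wander is a record-level artifact), then
fixed 1000-sample windows are cut and each window is denoised with a
level-thresholded sym4 wavelet transform and z-scored.  Windows whose span
contains a noise annotation are dropped, as is any trailing remainder
shorter than the window length.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .containers import (
    BINARY_ORDER,
    MULTICLASS_ORDER,
    NOISE,
    OTHER,
    SEGMENT_CODES,
    BeatAnnotation,
    EcgRecord,
    SegmentTable,
    WindowSet,
)

REJECT = "REJECT"

# Tie-break order for multi-beat windows: prefer non-N, then this fixed order.
_TIEBREAK_ORDER = {"L": 0, "R": 1, "A": 2, "V": 3, "N": 4}


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing stages.

    highpass_cutoff_hz : float
        High-pass corner for baseline-wander removal (Hz).
    butterworth_order : int
        Order of the Butterworth high-pass design.
    wavelet_name : str
        Wavelet used for per-window denoising.
    threshold_factor : float
        Per-level hard threshold as a fraction of that level's max |detail|.
    window_len : int
        Window length in samples; 1000 at 128 Hz is ~7.81 s.
    target_fs_hz : float
        Sampling rate the pipeline operates at; records at other rates are
        polyphase-resampled first.
    zero_phase : bool
        Forward-backward filtering (no phase distortion of QRS morphology).
    soft_threshold : bool
        Shrink detail coefficients instead of zeroing them.
    """

    highpass_cutoff_hz: float = 0.5
    butterworth_order: int = 4
    wavelet_name: str = "sym4"
    threshold_factor: float = 0.04
    window_len: int = 1000
    target_fs_hz: float = 128.0
    zero_phase: bool = True
    soft_threshold: bool = False

    def __post_init__(self) -> None:
        if not self.highpass_cutoff_hz < self.target_fs_hz / 2:
            raise ValueError("cutoff must lie below the Nyquist rate")
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.threshold_factor < 0:
            raise ValueError("threshold_factor must be non-negative")

    @property
    def window_duration_s(self) -> float:
        """Window length in seconds (1000 samples at 128 Hz ~ 7.81 s)."""
        return self.window_len / self.target_fs_hz


def resample_to_target(record: EcgRecord, target_fs_hz: float) -> EcgRecord:
    """Polyphase-resample a record to ``target_fs_hz``.

    Annotation indices are rescaled by the rate ratio and rounded to the
    nearest sample.  A record already at the target rate is returned as-is.
    """
    if not target_fs_hz > 0:
        raise ValueError("target sampling rate must be positive")
    if record.fs == target_fs_hz:
        return record
    ratio = Fraction(target_fs_hz / record.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    new_signal = sps.resample_poly(record.signal, up, down)
    scale = target_fs_hz / record.fs
    new_ann = []
    for a in record.annotations:
        idx = int(round(a.index * scale))
        idx = min(idx, len(new_signal) - 1)
        new_ann.append(BeatAnnotation(index=idx, symbol=a.symbol))
    return EcgRecord(
        patient_id=record.patient_id,
        fs=target_fs_hz,
        signal=new_signal,
        annotations=new_ann,
        lead_name=record.lead_name,
    )


def remove_baseline(signal: np.ndarray, fs: float,
                    cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """High-pass the signal to strip baseline wander.

    Butterworth design of ``cfg.butterworth_order`` at
    ``cfg.highpass_cutoff_hz``; applied forward-backward when
    ``cfg.zero_phase`` (the effective magnitude response is then the squared
    one-pass response, with zero phase shift).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if not fs > 2 * cfg.highpass_cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = sps.butter(cfg.butterworth_order, cfg.highpass_cutoff_hz,
                     btype="highpass", fs=fs, output="sos")
    if cfg.zero_phase:
        # sosfiltfilt pads with 3 * (2*order) samples on each side
        padlen = 3 * (2 * cfg.butterworth_order)
        if len(signal) <= padlen:
            raise ValueError(
                f"signal too short for zero-phase filtering: {len(signal)} <= {padlen}"
            )
        return sps.sosfiltfilt(sos, signal)
    if len(signal) <= 3 * cfg.butterworth_order:
        raise ValueError("signal too short for filtering")
    return sps.sosfilt(sos, signal)


def max_decomposition_level(n: int, wavelet_name: str) -> int:
    """Deepest DWT level admitted by length ``n`` and the wavelet support."""
    return pywt.dwt_max_level(n, pywt.Wavelet(wavelet_name))


def denoise_window(window: np.ndarray,
                   cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Wavelet-denoise one window.

    The window is decomposed to the maximum level its length admits; in each
    detail level the threshold is ``threshold_factor`` times that level's
    largest |coefficient|, and coefficients below it are zeroed (hard
    thresholding; soft shrinkage behind ``cfg.soft_threshold``).
    Approximation coefficients are untouched.
    """
    window = np.asarray(window, dtype=np.float64)
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    if len(window) < wavelet.dec_len:
        raise ValueError(
            f"window of {len(window)} samples is shorter than the {cfg.wavelet_name} "
            f"support ({wavelet.dec_len})"
        )
    level = pywt.dwt_max_level(len(window), wavelet)
    coeffs = pywt.wavedec(window, wavelet, level=level)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        tau = cfg.threshold_factor * np.max(np.abs(detail)) if detail.size else 0.0
        if cfg.soft_threshold:
            out.append(pywt.threshold(detail, tau, mode="soft"))
        else:
            filtered = detail.copy()
            filtered[np.abs(filtered) < tau] = 0.0
            out.append(filtered)
    rec = pywt.waverec(out, wavelet)
    return rec[: len(window)]


def zscore(window: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, population std 1; a constant window maps to zeros."""
    window = np.asarray(window, dtype=np.float64)
    mu = window.mean()
    sd = window.std()
    if sd < 1e-12:
        return np.zeros_like(window)
    return (window - mu) / sd


def segment_record(record: EcgRecord,
                   cfg: PreprocessConfig = PreprocessConfig()
                   ) -> list[tuple[int, np.ndarray]]:
    """Cut consecutive non-overlapping windows of exactly ``window_len``.

    Starts at sample 0; a trailing remainder is dropped; any window whose
    span contains a noise annotation is excluded.  Returns (start, window)
    pairs.
    """
    wl = cfg.window_len
    noise_idx = np.array(
        [a.index for a in record.annotations if a.symbol == NOISE], dtype=np.intp
    )
    out = []
    for start in range(0, len(record.signal) - wl + 1, wl):
        if noise_idx.size and np.any((noise_idx >= start) & (noise_idx < start + wl)):
            continue
        out.append((start, record.signal[start:start + wl].copy()))
    return out


def label_window_mitbih(window_span: tuple[int, int],
                        annotations: list[BeatAnnotation]) -> str:
    """Label a window from the beat annotations inside its span.

    Majority symbol among {N, L, R, A, V}; a window with no beats, or any
    beat outside the closed enumeration, is rejected.  Ties go to the
    non-N symbol, then by the fixed order L < R < A < V.
    """
    start, stop = window_span
    inside = [a for a in annotations
              if start <= a.index < stop and a.symbol != NOISE]
    if not inside:
        return REJECT
    if any(a.symbol == OTHER for a in inside):
        return REJECT
    counts: dict[str, int] = {}
    for a in inside:
        counts[a.symbol] = counts.get(a.symbol, 0) + 1
    best = max(counts.values())
    tied = [s for s, c in counts.items() if c == best]
    return min(tied, key=lambda s: _TIEBREAK_ORDER[s])


def encode_labels(labels: list, mode: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """One-hot encode labels.

    ``multiclass``: beat symbols in the fixed order (N, L, R, A, V), length-5
    vectors.  ``binary``: (Normal, Arrhythmia) length-2 vectors; smartwatch
    codes 1.0/2.0/3.0 (AF/PAC/PVC) all map to Arrhythmia and 0.0 to Normal;
    the strings "Normal"/"Arrhythmia" are accepted directly.
    """
    if mode == "multiclass":
        order = MULTICLASS_ORDER
        indices = []
        for lab in labels:
            if lab not in order:
                raise ValueError(f"unknown multiclass label {lab!r}")
            indices.append(order.index(lab))
    elif mode == "binary":
        order = BINARY_ORDER
        indices = []
        for lab in labels:
            if isinstance(lab, str) and lab in order:
                indices.append(order.index(lab))
                continue
            code = float(lab)
            if code not in SEGMENT_CODES:
                raise ValueError(f"unknown binary label {lab!r}")
            indices.append(0 if code == 0.0 else 1)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'multiclass' or 'binary'")
    onehot = np.zeros((len(indices), len(order)), dtype=np.float64)
    onehot[np.arange(len(indices)), indices] = 1.0
    return onehot, order


def run_preprocessing(data: list[EcgRecord] | SegmentTable,
                      cfg: PreprocessConfig = PreprocessConfig(),
                      mode: str = "multiclass") -> WindowSet:
    """Run the full pipeline on continuous records or a segment table.

    For records: resample to the target rate, high-pass the continuous
    signal, cut windows, drop noise-marked and unlabeled windows, denoise
    and z-score each window, one-hot the labels.  For a segment table each
    pre-labeled segment is high-passed, windowed, and its class code carried
    to every window.
    """
    windows, labels, patients = [], [], []
    if isinstance(data, SegmentTable):
        for pid, segment, code in zip(data.patient_ids, data.segments, data.class_codes):
            filtered = remove_baseline(segment, cfg.target_fs_hz, cfg)
            rec = EcgRecord(patient_id=pid, fs=cfg.target_fs_hz, signal=filtered)
            for _start, w in segment_record(rec, cfg):
                windows.append(zscore(denoise_window(w, cfg)))
                labels.append(float(code))
                patients.append(pid)
        if mode != "binary":
            raise ValueError("segment tables carry binary (Normal/Arrhythmia) labels")
    else:
        for record in data:
            record = resample_to_target(record, cfg.target_fs_hz)
            filtered = remove_baseline(record.signal, record.fs, cfg)
            record = EcgRecord(
                patient_id=record.patient_id, fs=record.fs, signal=filtered,
                annotations=record.annotations, lead_name=record.lead_name,
            )
            for start, w in segment_record(record, cfg):
                lab = label_window_mitbih((start, start + cfg.window_len),
                                          record.annotations)
                if lab == REJECT:
                    continue
                if mode == "binary":
                    lab = "Normal" if lab == "N" else "Arrhythmia"
                windows.append(zscore(denoise_window(w, cfg)))
                labels.append(lab)
                patients.append(record.patient_id)
    if not windows:
        return WindowSet(
            windows=np.zeros((0, cfg.window_len)),
            labels_onehot=np.zeros((0, 5 if mode == "multiclass" else 2)),
            patient_ids=[],
            class_order=MULTICLASS_ORDER if mode == "multiclass" else BINARY_ORDER,
        )
    onehot, order = encode_labels(labels, mode)
    return WindowSet(
        windows=np.stack(windows),
        labels_onehot=onehot,
        patient_ids=patients,
        class_order=order,
    )
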