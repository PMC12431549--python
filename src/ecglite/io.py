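"""Reading and writing the on-disk formats the pipeline touches.

Continuous records travel in the WFDB layout used by PhysioNet (``.hea``
header, format-16 ``.dat`` signal, MIT-format ``.atr`` annotations).  The
reader and writer here cover the subset of that format the pipeline needs:
single-channel format-16 signals and single-byte-pair annotations with SKIP
escapes, which is what ``mitdb``-style records use.  Amplitudes are converted
to millivolts at read time using the header gain, so everything downstream
works in physical units.

Windowed tensors round-trip through NPZ; smartwatch-style segment tables
through CSV with columns ``patient_id, class_code, s0..s{L-1}``.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    NOISE,
    OTHER,
    SEGMENT_CODES,
    BeatAnnotation,
    EcgRecord,
    SegmentTable,
    WindowSet,
)

# MIT annotation code <-> symbol, restricted to the closed enumeration.
# 14 is the format's noise marker ('~').
_CODE_TO_SYMBOL = {1: "N", 2: "L", 3: "R", 5: "V", 8: "A", 14: NOISE}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

#: ADC gain (adu per mV) used when writing records; MIT-BIH's own value.
DEFAULT_GAIN = 200.0


class WfdbFormatError(ValueError):
    """Raised when a header/signal/annotation file fails to parse or validate."""


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    return path


def read_wfdb_record(path: str | os.PathLike) -> EcgRecord:
    """Read a WFDB record given its path without extension (or ``.hea`` path).

    Annotation symbols outside {N, L, R, A, V} map to ``OTHER``; the format's
    noise marker maps to ``NOISE``.  The sampling rate comes from the header
    and amplitudes are scaled to mV with the header gain.
    """
    base = Path(path)
    if base.suffix == ".hea":
        base = base.with_suffix("")
    hea = _require(base.with_suffix(".hea"))

    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    try:
        rec_fields = lines[0].split()
        record_name = rec_fields[0]
        n_sig = int(rec_fields[1])
        fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
        n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else -1
    except (IndexError, ValueError) as exc:
        raise WfdbFormatError(f"corrupt header line in {hea}: {lines[0]!r}") from exc
    if n_sig != 1:
        raise WfdbFormatError(f"{hea}: only single-channel records are supported (n_sig={n_sig})")

    sig_fields = lines[1].split()
    dat_name = sig_fields[0]
    fmt = sig_fields[1].split("x")[0] if len(sig_fields) > 1 else "16"
    if fmt != "16":
        raise WfdbFormatError(f"{hea}: unsupported signal format {fmt!r} (only 16)")
    gain = DEFAULT_GAIN
    baseline = None
    if len(sig_fields) > 2:
        # gain may carry "(baseline)/units" decorations, e.g. "200(1024)/mV"
        gain_field = sig_fields[2].split("/")[0]
        if "(" in gain_field:
            gain_field, base_part = gain_field.split("(")
            baseline = int(base_part.rstrip(")"))
        gain = float(gain_field) or DEFAULT_GAIN
    adc_zero = int(sig_fields[4]) if len(sig_fields) > 4 else 0
    if baseline is None:
        baseline = adc_zero
    lead_name = sig_fields[8] if len(sig_fields) > 8 else "ECG"

    dat = _require(base.parent / dat_name)
    adc = np.fromfile(dat, dtype="<i2")
    if n_samples >= 0 and len(adc) != n_samples:
        raise WfdbFormatError(
            f"{dat}: header promises {n_samples} samples but file holds {len(adc)}"
        )
    signal = (adc.astype(np.float64) - baseline) / gain

    atr = base.with_suffix(".atr")
    annotations: list[BeatAnnotation] = []
    if atr.exists():
        annotations = _read_annotations(atr)
    for ann in annotations:
        if ann.index >= len(signal):
            raise WfdbFormatError(
                f"{atr}: annotation index {ann.index} beyond signal length {len(signal)}"
            )
    return EcgRecord(
        patient_id=record_name,
        fs=fs,
        signal=signal,
        annotations=annotations,
        lead_name=lead_name,
    )


def _read_annotations(path: Path) -> list[BeatAnnotation]:
    data = path.read_bytes()
    out: list[BeatAnnotation] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:
            break  # end of annotation stream
        if code == _SKIP:
            if i + 3 >= len(data):
                raise WfdbFormatError(f"{path}: truncated SKIP escape")
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            i += 4
            pending_skip = (high << 16) | low
            continue
        if code in (_NUM, _SUB, _CHN):
            continue  # field modifiers; no time advance
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        t += interval + pending_skip
        pending_skip = 0
        out.append(BeatAnnotation(index=t, symbol=_CODE_TO_SYMBOL.get(code, OTHER)))
    return out


def write_wfdb_record(record: EcgRecord, directory: str | os.PathLike,
                      gain: float = DEFAULT_GAIN) -> Path:
    """Write an :class:`EcgRecord` as ``<patient_id>.hea/.dat/.atr``.

    Returns the record base path (without extension).  Samples are stored as
    16-bit ADC counts at ``gain`` adu/mV; a signal already on that grid
    round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / record.patient_id

    adc = np.rint(record.signal * gain).astype(np.int64)
    if adc.min() < -32768 or adc.max() > 32767:
        raise WfdbFormatError(f"record {record.patient_id}: amplitudes overflow 16-bit range")
    adc16 = adc.astype("<i2")
    adc16.tofile(base.with_suffix(".dat"))

    fs_txt = f"{record.fs:g}"
    header = (
        f"{record.patient_id} 1 {fs_txt} {len(record.signal)}\n"
        f"{record.patient_id}.dat 16 {gain:g} 16 0 {int(adc16[0]) if len(adc16) else 0} "
        f"0 0 {record.lead_name}\n"
    )
    base.with_suffix(".hea").write_text(header)

    _write_annotations(record.annotations, base.with_suffix(".atr"))
    return base


def _write_annotations(annotations: list[BeatAnnotation], path: Path) -> None:
    buf = bytearray()
    prev = 0
    for ann in sorted(annotations, key=lambda a: a.index):
        code = _SYMBOL_TO_CODE.get(ann.symbol)
        if code is None:
            raise WfdbFormatError(f"cannot encode symbol {ann.symbol!r} in annotation file")
        interval = ann.index - prev
        if interval >= 1024:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (interval >> 16) & 0xFFFF, interval & 0xFFFF)
            interval = 0
        buf += struct.pack("<H", (code << 10) | interval)
        prev = ann.index
    buf += b"\x00\x00"
    path.write_bytes(bytes(buf))


def write_window_set(ws: WindowSet, path: str | os.PathLike) -> None:
    """Store a WindowSet as NPZ (arrays: windows, labels, patients, class_order)."""
    if len(ws) == 0:
        raise ValueError("refusing to write an empty WindowSet")
    np.savez(
        path,
        windows=ws.windows,
        labels=ws.labels_onehot,
        patients=np.asarray(ws.patient_ids, dtype=str),
        class_order=np.asarray(ws.class_order, dtype=str),
    )


def read_window_set(path: str | os.PathLike) -> WindowSet:
    with np.load(path, allow_pickle=False) as z:
        return WindowSet(
            windows=z["windows"],
            labels_onehot=z["labels"],
            patient_ids=[str(p) for p in z["patients"]],
            class_order=tuple(str(c) for c in z["class_order"]),
        )


def write_segment_table(table: SegmentTable, path: str | os.PathLike) -> None:
    seg_len = table.segments.shape[1]
    df = pd.DataFrame(table.segments, columns=[f"s{i}" for i in range(seg_len)])
    df.insert(0, "class_code", table.class_codes)
    df.insert(0, "patient_id", table.patient_ids)
    df.to_csv(path, index=False)


def read_segment_table(path: str | os.PathLike) -> SegmentTable:
    """Read a CSV segment table, validating class codes and segment lengths."""
    df = pd.read_csv(path)
    required = {"patient_id", "class_code"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: segment table needs columns {sorted(required)}")
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns (s0, s1, ...) found")
    codes = df["class_code"].astype(float).to_numpy()
    for i, code in enumerate(codes):
        if code not in SEGMENT_CODES:
            raise ValueError(
                f"{path}: row {i} (patient {df['patient_id'].iloc[i]!r}) has unknown "
                f"class code {code}; valid codes are {sorted(SEGMENT_CODES)}"
            )
    return SegmentTable(
        patient_ids=[str(p) for p in df["patient_id"]],
        segments=df[sample_cols].to_numpy(dtype=np.float64),
        class_codes=codes,
    )
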