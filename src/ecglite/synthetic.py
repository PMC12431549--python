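"""Seeded synthetic single-lead ECG cohorts at 128 Hz.

The generator emulates the statistical structure of the two kinds of input
the pipeline consumes — continuous annotated records and pre-segmented
30-s tables — with class-dependent rhythm and morphology:

* NSR: regular RR intervals (low coefficient of variation), full PQRST.
* AF: irregular RR (high CV), absent P waves, faster mean rate.
* PAC: sinus rhythm with early narrow atrial ectopics (labeled A).
* PVC: sinus rhythm with wide, P-free ventricular ectopics (labeled V).

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative
to the R-peak time; records add a sinusoidal baseline wander and white
noise, then quantize amplitudes to the ADC grid used by the WFDB writer so
that disk round-trips are exact.  R-peak times are emitted as ground-truth
annotations by construction — no detector is involved.  Everything is
reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BeatAnnotation, EcgRecord, NOISE, SegmentTable

CLASS_NAMES = ("NSR", "AF", "PAC", "PVC")
CLASS_CODES = {"NSR": 0.0, "AF": 1.0, "PAC": 2.0, "PVC": 3.0}

# Gaussian bump parameters per wave: (amplitude mV, center s rel. R, width s)
_N_TEMPLATE = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.10, 0.0, 0.014),
    "S": (-0.18, 0.035, 0.012),
    "T": (0.30, 0.28, 0.060),
}


@dataclass(frozen=True)
class BeatTemplate:
    """PQRST morphology as five (amplitude, center, width) Gaussian bumps."""

    waves: dict[str, tuple[float, float, float]]

    def scaled(self, amplitude: float = 1.0, qrs_width: float = 1.0,
               p_present: bool = True) -> "BeatTemplate":
        out = {}
        for name, (a, mu, sigma) in self.waves.items():
            if name == "P" and not p_present:
                continue
            if name in ("Q", "R", "S") and qrs_width != 1.0:
                sigma = sigma * qrs_width
                mu = mu * qrs_width
            out[name] = (a * amplitude, mu, sigma)
        return BeatTemplate(waves=out)


NORMAL_BEAT = BeatTemplate(waves=dict(_N_TEMPLATE))
# atrial ectopic: P closer to the QRS and smaller; QRS itself narrow/normal
PAC_BEAT = BeatTemplate(waves={**_N_TEMPLATE, "P": (0.08, -0.12, 0.018)})
# ventricular ectopic: no P, wide QRS, discordant T
PVC_BEAT = NORMAL_BEAT.scaled(amplitude=1.0, qrs_width=2.5, p_present=False)
PVC_BEAT = BeatTemplate(waves={**PVC_BEAT.waves, "T": (-0.35, 0.30, 0.08),
                               "R": (0.95, 0.0, 0.035)})


@dataclass(frozen=True)
class ClassParams:
    heart_rate_bpm: float
    heart_rate_sd_bpm: float
    rr_cv: float
    p_wave_present: bool
    qrs_width_scale: float = 1.0
    ectopic_rate: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation parameters.

    Rates are per-class; ``rr_cv`` is the coefficient of variation of the
    RR intervals (AF far above NSR).  ``baseline_amp_mv`` /
    ``baseline_freq_hz`` control the respiratory wander sinusoid;
    ``noise_sd_mv`` the white-noise floor; ``adc_gain`` the quantization
    grid (adu per mV) matching the record writer.
    """

    fs: float = 128.0
    duration_s: float = 120.0
    classes: dict[str, ClassParams] = field(default_factory=lambda: {
        "NSR": ClassParams(70.0, 5.0, 0.03, True),
        "AF": ClassParams(95.0, 10.0, 0.25, False),
        "PAC": ClassParams(72.0, 5.0, 0.04, True, ectopic_rate=0.18),
        "PVC": ClassParams(68.0, 5.0, 0.04, True, qrs_width_scale=2.5,
                           ectopic_rate=0.18),
    })
    baseline_amp_mv: float = 0.15
    baseline_freq_hz: float = 0.25
    noise_sd_mv: float = 0.04
    adc_gain: float = 200.0
    n_noise_markers: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.baseline_amp_mv < 0 or self.noise_sd_mv < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.classes["AF"].rr_cv <= self.classes["NSR"].rr_cv:
            raise ValueError("AF rr_cv must exceed NSR rr_cv")


@dataclass
class SynthCohort:
    records: list[EcgRecord]
    manifest: list[dict]  # per record: patient_id, class, seed


def _wave_sum(t_rel: np.ndarray, template: BeatTemplate) -> np.ndarray:
    y = np.zeros_like(t_rel)
    for amp, mu, sigma in template.waves.values():
        y += amp * np.exp(-0.5 * ((t_rel - mu) / sigma) ** 2)
    return y


def p_wave_correlation(waveform: np.ndarray, fs: float, r_offset_s: float) -> float:
    """|corr| of a beat waveform with the canonical P-wave basis bump."""
    t_rel = np.arange(len(waveform)) / fs - r_offset_s
    amp, mu, sigma = _N_TEMPLATE["P"]
    basis = np.exp(-0.5 * ((t_rel - mu) / sigma) ** 2)
    denom = np.linalg.norm(basis) * np.linalg.norm(waveform)
    if denom == 0:
        return 0.0
    return float(abs(basis @ waveform) / denom)


def synth_beat(template: BeatTemplate, rr_s: float, fs: float,
               r_offset_s: float | None = None) -> np.ndarray:
    """One RR interval worth of samples with the R peak at ``r_offset_s``.

    The default R offset (0.38 of the interval) leaves room for the P wave
    before and the T wave after.  The waveform is linear in the template
    amplitudes.
    """
    if rr_s <= 0 or fs <= 0:
        raise ValueError("rr_s and fs must be positive")
    n = int(round(rr_s * fs))
    if r_offset_s is None:
        r_offset_s = 0.38 * rr_s
    t_rel = np.arange(n) / fs - r_offset_s
    return _wave_sum(t_rel, template)


def _rr_sequence(params: ClassParams, duration_s: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """R-peak times (s) and beat symbols covering [0, duration_s)."""
    rr_mean = 60.0 / params.heart_rate_bpm
    times, symbols = [], []
    t = float(rng.uniform(0.1, 0.5))
    pending_pause = 1.0
    while t < duration_s:
        symbol = "N"
        rr = rng.normal(rr_mean, params.rr_cv * rr_mean) * pending_pause
        pending_pause = 1.0
        if params.ectopic_rate > 0 and times and rng.random() < params.ectopic_rate:
            # premature beat: short coupling interval, then compensatory pause
            rr = rr_mean * rng.uniform(0.55, 0.70)
            symbol = "V" if params.qrs_width_scale > 1.0 else "A"
            pending_pause = 1.3
        rr = float(np.clip(rr, 0.3, 2.0))
        times.append(t)
        symbols.append(symbol)
        t += rr
    return np.asarray(times), symbols


def synth_record(class_name: str, cfg: SynthConfig = SynthConfig(),
                 seed: int = 0, patient_id: str | None = None) -> EcgRecord:
    """Generate one annotated record of the given rhythm class."""
    if class_name not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_name!r}; valid: {CLASS_NAMES}")
    params = cfg.classes[class_name]
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    # per-patient heart-rate offset
    hr = float(np.clip(rng.normal(params.heart_rate_bpm, params.heart_rate_sd_bpm),
                       40.0, 160.0))
    params = ClassParams(hr, params.heart_rate_sd_bpm, params.rr_cv,
                         params.p_wave_present, params.qrs_width_scale,
                         params.ectopic_rate)
    r_times, symbols = _rr_sequence(params, cfg.duration_s, rng)

    signal = np.zeros(n)
    for r_time, symbol in zip(r_times, symbols):
        if symbol == "V":
            template = PVC_BEAT
        elif symbol == "A":
            template = PAC_BEAT
        else:
            template = NORMAL_BEAT if params.p_wave_present else NORMAL_BEAT.scaled(
                p_present=False)
        lo = max(0, int((r_time - 0.6) * cfg.fs))
        hi = min(n, int((r_time + 0.7) * cfg.fs))
        signal[lo:hi] += _wave_sum(t[lo:hi] - r_time, template)

    phase = rng.uniform(0, 2 * np.pi)
    signal += cfg.baseline_amp_mv * np.sin(2 * np.pi * cfg.baseline_freq_hz * t + phase)
    signal += rng.normal(0.0, cfg.noise_sd_mv, size=n)
    # quantize to the ADC grid so WFDB round-trips are exact
    signal = np.rint(signal * cfg.adc_gain) / cfg.adc_gain

    annotations = [
        BeatAnnotation(index=min(int(round(rt * cfg.fs)), n - 1), symbol=s)
        for rt, s in zip(r_times, symbols)
    ]
    for idx in rng.choice(n, size=cfg.n_noise_markers, replace=False):
        annotations.append(BeatAnnotation(index=int(idx), symbol=NOISE))
    pid = patient_id or f"{class_name.lower()}{seed:04d}"
    return EcgRecord(patient_id=pid, fs=cfg.fs, signal=signal,
                     annotations=annotations, lead_name="ECG")


def _largest_remainder(n: int, mix: dict[str, float]) -> dict[str, int]:
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"class mix must sum to 1, got {total}")
    raw = {c: n * f for c, f in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def synth_cohort(n_patients: int, class_mix: dict[str, float],
                 cfg: SynthConfig = SynthConfig(), seed: int = 0) -> SynthCohort:
    """Generate a cohort; per-patient seeds derive from the master seed.

    Class counts follow largest-remainder rounding of the mix.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    for c in class_mix:
        if c not in CLASS_NAMES:
            raise ValueError(f"unknown class {c!r} in mix")
    counts = _largest_remainder(n_patients, class_mix)
    records, manifest = [], []
    i = 0
    for class_name in CLASS_NAMES:
        for _ in range(counts.get(class_name, 0)):
            sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
            pid = f"p{i:03d}_{class_name.lower()}"
            rec = synth_record(class_name, cfg, seed=sub, patient_id=pid)
            records.append(rec)
            manifest.append({"patient_id": pid, "class": class_name, "seed": sub})
            i += 1
    return SynthCohort(records=records, manifest=manifest)


def cohort_to_segment_table(cohort: SynthCohort, segment_s: float = 30.0) -> SegmentTable:
    """Cut each record into fixed 30-s segments labeled with its class code."""
    patient_ids, segments, codes = [], [], []
    for rec, meta in zip(cohort.records, cohort.manifest):
        seg_len = int(round(segment_s * rec.fs))
        for start in range(0, len(rec.signal) - seg_len + 1, seg_len):
            patient_ids.append(rec.patient_id)
            segments.append(rec.signal[start:start + seg_len])
            codes.append(CLASS_CODES[meta["class"]])
    if not segments:
        raise ValueError("records shorter than one segment")
    return SegmentTable(patient_ids=patient_ids, segments=np.stack(segments),
                        class_codes=np.asarray(codes))
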