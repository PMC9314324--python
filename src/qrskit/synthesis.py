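"""Synthetic single-lead Holter ECG generator.

Emulates short ambulatory recordings (default 45 s at 200 Hz) containing
normal beats, premature atrial contractions and premature ventricular
contractions, optionally disturbed by baseline wander, broadband noise and
high-amplitude movement-artifact bursts.  Beat waveforms are analytic
Gaussian mixtures (P/QRS/T components), not recorded data, so no external
download is needed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .records_io import AnnotatedRecord, BeatAnnotation, BeatClass, EcgRecord

__all__ = [
    "SynthesisConfig",
    "BeatTemplate",
    "make_beat_template",
    "simulate_record",
    "add_movement_noise",
    "make_dataset",
]

#: Physiological floor on the gap between consecutive fiducials (seconds);
#: kept above the 0.15 s post-processing suppression threshold.
MIN_FIDUCIAL_GAP_S = 0.25


@dataclass
class SynthesisConfig:
    duration_s: float = 45.0
    fs: float = 200.0
    heart_rate_bpm: float = 70.0
    rhythm: str = "sinus"  # "sinus" or "irregular"
    pac_fraction: float = 0.0
    pvc_fraction: float = 0.0
    noise_level: float = 0.0
    artifact_burst_rate: float = 0.0
    invert: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if self.pac_fraction + self.pvc_fraction > 1 + 1e-12:
            raise ValueError("pac_fraction + pvc_fraction must be <= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.rhythm not in ("sinus", "irregular"):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")


@dataclass
class BeatTemplate:
    """A fixed-length beat waveform kernel with its fiducial offset."""

    waveform: np.ndarray
    qrs_offset: int
    beat_class: BeatClass

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if not (0 <= self.qrs_offset < self.waveform.size):
            raise ValueError("qrs_offset outside kernel")


def _gauss(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


# Gaussian mixture parameters (center s, width s, amplitude) per component,
# with time 0 at the R peak.  PVC: wide/large QRS, no P wave, discordant T.
# PAC: narrow QRS with an inverted, earlier P wave.
_TEMPLATE_PARAMS: dict[BeatClass, list[tuple[float, float, float]]] = {
    BeatClass.N: [
        (-0.200, 0.025, 0.15),   # P
        (-0.025, 0.010, -0.10),  # Q
        (0.000, 0.012, 1.00),    # R
        (0.028, 0.010, -0.20),   # S
        (0.300, 0.060, 0.30),    # T
    ],
    BeatClass.PAC: [
        (-0.130, 0.030, -0.30),  # prominent ectopic (inverted) P
        (0.000, 0.012, 0.80),
        (0.030, 0.012, -0.35),   # deeper S
        (0.280, 0.050, 0.20),
    ],
    BeatClass.PVC: [
        (-0.020, 0.030, -0.25),
        (0.000, 0.042, 1.40),    # wide, tall QRS
        (0.090, 0.045, -0.45),
        (0.330, 0.080, -0.40),   # discordant T
    ],
}


def make_beat_template(beat_class: BeatClass, fs: float) -> BeatTemplate:
    """Build the analytic waveform kernel for one beat class at ``fs``."""
    if beat_class == BeatClass.NOQRS:
        raise ValueError("no template for NOQRS")
    half_s = 0.45
    n_half = int(round(half_s * fs))
    t = (np.arange(2 * n_half + 1) - n_half) / fs
    waveform = np.zeros_like(t)
    for center, width, amp in _TEMPLATE_PARAMS[beat_class]:
        waveform += _gauss(t, center, width, amp)
    return BeatTemplate(waveform=waveform, qrs_offset=n_half, beat_class=beat_class)


def template_qrs_width_s(template: BeatTemplate, fs: float) -> float:
    """Duration (s) for which |waveform| exceeds 10% of its peak, measured
    in a +/-0.15 s window around the fiducial (QRS region only)."""
    w = np.abs(template.waveform)
    halfwin = int(round(0.15 * fs))
    lo = max(0, template.qrs_offset - halfwin)
    hi = min(w.size, template.qrs_offset + halfwin + 1)
    seg = w[lo:hi]
    return float(np.sum(seg > 0.1 * w.max())) / fs


def _draw_rr_intervals(config: SynthesisConfig, rng: np.random.Generator) -> tuple:
    """Lay out fiducial times and classes covering the record duration."""
    mean_rr = 60.0 / config.heart_rate_bpm
    expected_beats = config.duration_s / mean_rr
    if expected_beats < 1:
        raise ValueError(
            f"infeasible config: {config.heart_rate_bpm} bpm over "
            f"{config.duration_s} s yields < 1 beat"
        )
    times: list[float] = []
    classes: list[BeatClass] = []
    # start part-way into the first interval so the record does not always
    # open with a beat at t=0
    t = float(rng.uniform(0.2, 0.8)) * mean_rr
    while t < config.duration_s:
        u = rng.random()
        if u < config.pvc_fraction:
            beat_class = BeatClass.PVC
        elif u < config.pvc_fraction + config.pac_fraction:
            beat_class = BeatClass.PAC
        else:
            beat_class = BeatClass.N
        if beat_class != BeatClass.N and times:
            # premature beat: pull the fiducial earlier
            t = times[-1] + 0.7 * (t - times[-1])
        if times and t - times[-1] < MIN_FIDUCIAL_GAP_S:
            t = times[-1] + MIN_FIDUCIAL_GAP_S
        if t >= config.duration_s:
            break
        times.append(t)
        classes.append(beat_class)
        if config.rhythm == "sinus":
            rr = mean_rr * (1.0 + 0.04 * rng.standard_normal())
        else:
            rr = mean_rr * rng.uniform(0.7, 1.3)
        rr = max(rr, MIN_FIDUCIAL_GAP_S)
        if beat_class == BeatClass.PVC:
            rr *= 1.3  # compensatory pause
        t = t + rr
    return times, classes


def simulate_record(config: SynthesisConfig) -> AnnotatedRecord:
    """Generate one annotated synthetic record.

    Identical configs (including seed) produce bit-identical output.
    Consecutive fiducials are guaranteed >= 0.25 s apart.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    signal = np.zeros(n)
    templates = {
        c: make_beat_template(c, config.fs)
        for c in (BeatClass.N, BeatClass.PAC, BeatClass.PVC)
    }

    times, classes = _draw_rr_intervals(config, rng)
    annotations: list[BeatAnnotation] = []
    for t, beat_class in zip(times, classes):
        idx = int(round(t * config.fs))
        if idx >= n:
            continue
        tpl = templates[beat_class]
        start = idx - tpl.qrs_offset
        k_lo = max(0, -start)
        k_hi = min(tpl.waveform.size, n - start)
        if k_hi <= k_lo:
            continue
        signal[start + k_lo : start + k_hi] += tpl.waveform[k_lo:k_hi]
        annotations.append(BeatAnnotation(idx, beat_class))

    record = EcgRecord(
        samples=signal,
        fs=config.fs,
        lead_name="I",
        record_id=f"synth-{config.seed}",
    )
    if config.noise_level > 0 or config.artifact_burst_rate > 0:
        noise_seed = int(rng.integers(0, 2**31))
        record = add_movement_noise(
            record, config.noise_level, config.artifact_burst_rate, noise_seed
        )
    if config.invert:
        record = EcgRecord(
            samples=-record.samples,
            fs=record.fs,
            lead_name=record.lead_name,
            record_id=record.record_id,
        )
    return AnnotatedRecord(record=record, annotations=annotations)


def draw_artifact_bursts(
    rng: np.random.Generator, rate: float, duration_s: float
) -> list[tuple[float, float]]:
    """Draw (center_s, width_s) artifact bursts; the count is Poisson with
    mean ``rate`` per record, positions uniform over the record."""
    n_bursts = int(rng.poisson(rate))
    return [
        (float(rng.uniform(0, duration_s)), float(rng.uniform(0.2, 1.0)))
        for _ in range(n_bursts)
    ]


def add_movement_noise(
    record: EcgRecord,
    noise_level: float,
    artifact_burst_rate: float,
    seed: int,
) -> EcgRecord:
    """Add baseline wander + broadband noise + Poisson artifact bursts.

    ``noise_level=0`` with ``artifact_burst_rate=0`` returns the input
    samples unchanged.  The burst count over the record is Poisson with
    mean ``artifact_burst_rate``.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    samples = record.samples.copy()
    n = samples.size
    t = np.arange(n) / record.fs

    if noise_level > 0:
        for _ in range(2):  # sub-1 Hz drift components
            freq = rng.uniform(0.1, 0.6)
            phase = rng.uniform(0, 2 * np.pi)
            amp = noise_level * rng.uniform(0.3, 0.8)
            samples += amp * np.sin(2 * np.pi * freq * t + phase)
        samples += noise_level * 0.25 * rng.standard_normal(n)

    if artifact_burst_rate > 0:
        burst_amp = max(1.5, 3.0 * noise_level)
        for center, width in draw_artifact_bursts(
            rng, artifact_burst_rate, record.duration_s
        ):
            env = np.exp(-0.5 * ((t - center) / (width / 2)) ** 2)
            samples += burst_amp * env * rng.standard_normal(n)

    return EcgRecord(
        samples=samples,
        fs=record.fs,
        lead_name=record.lead_name,
        record_id=record.record_id,
    )


def make_dataset(
    n_records: int,
    base_config: SynthesisConfig,
    seed: int,
    heart_rate_range: tuple[float, float] | None = (55.0, 95.0),
    noise_range: tuple[float, float] | None = None,
) -> tuple[list[AnnotatedRecord], dict]:
    """Generate ``n_records`` records with per-record seeds spawned from the
    master seed; returns the records plus a manifest describing each one.

    Heart rate (and optionally noise level) are drawn per record from the
    given ranges; all other parameters come from ``base_config``.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    master = np.random.default_rng(seed)
    records: list[AnnotatedRecord] = []
    entries = []
    totals = {c.name: 0 for c in (BeatClass.N, BeatClass.PVC, BeatClass.PAC)}
    for i in range(n_records):
        cfg = replace(base_config, seed=int(master.integers(0, 2**31)))
        if heart_rate_range is not None:
            cfg = replace(cfg, heart_rate_bpm=float(master.uniform(*heart_rate_range)))
        if noise_range is not None:
            cfg = replace(cfg, noise_level=float(master.uniform(*noise_range)))
        annotated = simulate_record(cfg)
        record_id = f"synth-{seed:08d}-{i:04d}"
        annotated.record.record_id = record_id
        counts = {c.name: 0 for c in (BeatClass.N, BeatClass.PVC, BeatClass.PAC)}
        for ann in annotated.annotations:
            counts[ann.beat_class.name] += 1
            totals[ann.beat_class.name] += 1
        entries.append(
            {"record_id": record_id, "config": asdict(cfg), "class_counts": counts}
        )
        records.append(annotated)
    manifest = {
        "seed": seed,
        "n_records": n_records,
        "records": entries,
        "class_totals": totals,
    }
    return records, manifest
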