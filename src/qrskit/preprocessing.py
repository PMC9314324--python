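"""Signal conditioning, training-time augmentation and target construction.

The model consumes 30 s windows at 100 Hz (3000 samples), standardized to
zero mean and unit (population) variance.  Targets are per-sample class
indices in which each annotated beat is widened to a 10-sample run centered
on its fiducial (samples ``i-5 .. i+4``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .records_io import AnnotatedRecord, BeatAnnotation, BeatClass, EcgRecord

logger = logging.getLogger(__name__)

TARGET_FS = 100.0
WINDOW_S = 30.0
WINDOW_SAMPLES = int(WINDOW_S * TARGET_FS)  # 3000
WIDEN_SAMPLES = 10
INVERT_P = 0.5

__all__ = [
    "TARGET_FS",
    "WINDOW_SAMPLES",
    "WIDEN_SAMPLES",
    "ModelInput",
    "resample_to_100hz",
    "standardize",
    "random_crop_30s",
    "random_invert",
    "encode_targets",
    "one_hot",
    "oversampling_weights",
    "WindowSampler",
    "validation_window",
]


@dataclass
class ModelInput:
    """A standardized 100 Hz window ready for inference."""

    signal: np.ndarray
    record_id: str = ""
    crop_offset: int = 0


def resample_to_100hz(annotated: AnnotatedRecord) -> AnnotatedRecord:
    """Resample the record to 100 Hz, rescaling annotation indices.

    Output length is ``round(n_in * 100 / fs_in)``; annotation indices are
    rescaled by index arithmetic (``round(i * 100 / fs)``), never
    re-detected.  Duplicate post-rounding indices keep the first.
    """
    record = annotated.record
    if record.fs <= 0:
        raise ValueError("fs must be positive")
    if record.fs < TARGET_FS:
        logger.info(
            "record %s: upsampling from %.1f Hz to %.1f Hz",
            record.record_id, record.fs, TARGET_FS,
        )
    n_out = int(round(record.n_samples * TARGET_FS / record.fs))
    if record.fs == TARGET_FS:
        samples = record.samples.copy()
    else:
        samples = scipy.signal.resample(record.samples, n_out)

    annotations: list[BeatAnnotation] = []
    seen: set[int] = set()
    for ann in annotated.annotations:
        idx = int(round(ann.sample_index * TARGET_FS / record.fs))
        idx = min(idx, n_out - 1)
        if idx in seen:
            continue
        seen.add(idx)
        annotations.append(BeatAnnotation(idx, ann.beat_class))

    out = EcgRecord(
        samples=samples,
        fs=TARGET_FS,
        lead_name=record.lead_name,
        record_id=record.record_id,
    )
    return AnnotatedRecord(record=out, annotations=annotations)


def standardize(signal: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance (population) standardization.

    Constant signals map to all zeros (guarded divide).
    """
    signal = np.asarray(signal, dtype=np.float64)
    centered = signal - signal.mean()
    std = np.sqrt(np.mean(centered**2))
    if std == 0 or not np.isfinite(std):
        return np.zeros_like(signal)
    return centered / std


def random_crop_30s(
    annotated: AnnotatedRecord, rng: np.random.Generator
) -> AnnotatedRecord:
    """Crop a random 30 s window (3000 samples at 100 Hz).

    Records shorter than 3000 samples are right-padded with zeros.
    Annotations outside the crop are dropped; the rest are re-indexed
    relative to the crop start.
    """
    record = annotated.record
    n = record.n_samples
    if n < WINDOW_SAMPLES:
        logger.info("record %s shorter than 30 s; zero-padding", record.record_id)
        padded = np.zeros(WINDOW_SAMPLES)
        padded[:n] = record.samples
        samples, offset = padded, 0
    else:
        offset = int(rng.integers(0, n - WINDOW_SAMPLES + 1))
        samples = record.samples[offset : offset + WINDOW_SAMPLES].copy()

    annotations = [
        BeatAnnotation(a.sample_index - offset, a.beat_class)
        for a in annotated.annotations
        if offset <= a.sample_index < offset + WINDOW_SAMPLES
    ]
    out = EcgRecord(
        samples=samples,
        fs=record.fs,
        lead_name=record.lead_name,
        record_id=record.record_id,
    )
    cropped = AnnotatedRecord(record=out, annotations=annotations)
    cropped.crop_offset = offset  # type: ignore[attr-defined]
    return cropped


def random_invert(
    signal: np.ndarray, rng: np.random.Generator, p: float = INVERT_P
) -> np.ndarray:
    """Return ``-signal`` with probability ``p``, else the signal unchanged."""
    if rng.random() < p:
        return -np.asarray(signal)
    return np.asarray(signal).copy()


def encode_targets(annotations: list[BeatAnnotation], length: int) -> np.ndarray:
    """Per-sample class-index target of shape (length,).

    Each beat at index ``i`` contributes the run ``[i-5, i+5)`` of its class
    (clipped at window edges).  Overlapping runs of different classes are
    resolved later-beat-wins.
    """
    mask = np.zeros(length, dtype=np.int64)
    half = WIDEN_SAMPLES // 2
    for ann in sorted(annotations, key=lambda a: a.sample_index):
        if not (0 <= ann.sample_index < length):
            raise ValueError(
                f"annotation index {ann.sample_index} outside [0, {length})"
            )
        lo = max(0, ann.sample_index - half)
        hi = min(length, ann.sample_index + half)
        if np.any((mask[lo:hi] != 0) & (mask[lo:hi] != int(ann.beat_class))):
            logger.debug("overlapping widened runs at %d; later beat wins",
                         ann.sample_index)
        mask[lo:hi] = int(ann.beat_class)
    return mask


def one_hot(target: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Class-index target (L,) -> one-hot probability mask (n_classes, L)."""
    out = np.zeros((n_classes, target.size))
    out[target, np.arange(target.size)] = 1.0
    return out


def oversampling_weights(manifest: dict) -> np.ndarray:
    """Per-record sampling weights balancing expected class exposure.

    Weight of record r is ``sum_c count_{r,c} / total_c`` over beat classes
    present anywhere in the dataset, normalized to sum to 1.  Classes absent
    from the whole dataset are excluded (with a warning).
    """
    entries = manifest["records"]
    class_names = [c.name for c in (BeatClass.N, BeatClass.PVC, BeatClass.PAC)]
    totals = {c: 0 for c in class_names}
    for entry in entries:
        for c in class_names:
            totals[c] += entry["class_counts"].get(c, 0)
    active = [c for c in class_names if totals[c] > 0]
    for c in class_names:
        if totals[c] == 0:
            logger.warning("class %s absent from dataset; excluded from balancing", c)
    if not active:
        return np.full(len(entries), 1.0 / len(entries))
    weights = np.array(
        [
            sum(entry["class_counts"].get(c, 0) / totals[c] for c in active)
            for entry in entries
        ],
        dtype=np.float64,
    )
    total = weights.sum()
    if total == 0:
        return np.full(len(entries), 1.0 / len(entries))
    return weights / total


def validation_window(annotated: AnnotatedRecord) -> tuple[ModelInput, np.ndarray]:
    """Deterministic evaluation window: the first 30 s, standardized."""
    record = annotated.record
    n = min(record.n_samples, WINDOW_SAMPLES)
    samples = np.zeros(WINDOW_SAMPLES)
    samples[:n] = record.samples[:n]
    annotations = [
        a for a in annotated.annotations if a.sample_index < WINDOW_SAMPLES
    ]
    signal = standardize(samples)
    target = encode_targets(annotations, WINDOW_SAMPLES)
    return ModelInput(signal=signal, record_id=record.record_id), target


class WindowSampler:
    """Draws augmented (ModelInput, target) training batches.

    Records are sampled with replacement using the oversampling weights,
    then randomly cropped to 30 s and randomly inverted; the window is
    standardized and its 10-sample-widened target encoded, fresh for every
    batch draw.
    """

    def __init__(
        self,
        records: list[AnnotatedRecord],
        manifest: dict,
        rng: np.random.Generator,
        invert_p: float = INVERT_P,
    ):
        by_id = {e["record_id"]: e for e in manifest["records"]}
        ids = [r.record.record_id for r in records]
        if set(ids) != set(by_id) or len(ids) != len(by_id):
            raise ValueError("manifest does not match records")
        self.records = [resample_to_100hz(r) for r in records]
        self.weights = oversampling_weights({"records": [by_id[i] for i in ids]})
        self.rng = rng
        self.invert_p = invert_p

    def __len__(self) -> int:
        return len(self.records)

    def sample_batch(self, batch_size: int) -> tuple[np.ndarray, np.ndarray]:
        """Returns (signals (B, 1, L), targets (B, L))."""
        idx = self.rng.choice(len(self.records), size=batch_size, p=self.weights)
        signals = np.empty((batch_size, 1, WINDOW_SAMPLES), dtype=np.float64)
        targets = np.empty((batch_size, WINDOW_SAMPLES), dtype=np.int64)
        for b, i in enumerate(idx):
            cropped = random_crop_30s(self.records[i], self.rng)
            sig = random_invert(cropped.record.samples, self.rng, self.invert_p)
            signals[b, 0] = standardize(sig)
            targets[b] = encode_targets(cropped.annotations, WINDOW_SAMPLES)
        return signals, targets
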