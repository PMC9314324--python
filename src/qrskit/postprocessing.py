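"""Turn 4-channel probability masks into classified beat annotations.

Pipeline: per-sample argmax -> maximal same-class runs -> segment centers
become candidate peaks -> iterative suppression of the weaker of any two
peaks closer than 0.15 s (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records_io import AnnotatedRecord, BeatAnnotation, BeatClass, EcgRecord
from . import preprocessing
from .preprocessing import TARGET_FS, WINDOW_SAMPLES

__all__ = [
    "CandidatePeak",
    "DetectionResult",
    "MIN_GAP_S",
    "argmax_labels",
    "labels_to_segments",
    "segments_to_peaks",
    "suppress_close_peaks",
    "mask_to_peaks",
    "detect",
]

MIN_GAP_S = 0.15
MIN_SEGMENT_LEN = 2  # samples; rejects single-sample argmax flicker


@dataclass
class CandidatePeak:
    center_index: int          # sample index at 100 Hz
    beat_class: BeatClass
    strength: float            # mean assigned-class probability over the segment
    segment_span: tuple[int, int]

    def time_s(self, fs: float = TARGET_FS) -> float:
        return self.center_index / fs


@dataclass
class DetectionResult:
    record_id: str
    fs: float
    peaks: list[CandidatePeak] = field(default_factory=list)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([p.center_index / self.fs for p in self.peaks])

    def to_annotations(self) -> list[BeatAnnotation]:
        return [BeatAnnotation(p.center_index, p.beat_class) for p in self.peaks]


def argmax_labels(mask: np.ndarray) -> np.ndarray:
    """Per-sample class with maximum likelihood; ties break toward the
    lower channel index (NOQRS first).  ``mask`` is (4, L)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != 4:
        raise ValueError(f"expected (4, L) mask, got {mask.shape}")
    return np.argmax(mask, axis=0)  # np.argmax ties -> first (lowest) index


def labels_to_segments(
    labels: np.ndarray, min_segment_len: int = MIN_SEGMENT_LEN
) -> list[tuple[tuple[int, int], BeatClass]]:
    """Maximal runs of identical non-NOQRS labels, as ((start, end), class);
    runs shorter than ``min_segment_len`` are discarded as noise."""
    labels = np.asarray(labels)
    segments = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [labels.size]))
    for start, end in zip(starts, ends):
        cls = int(labels[start])
        if cls == int(BeatClass.NOQRS):
            continue
        if end - start < min_segment_len:
            continue
        segments.append(((int(start), int(end)), BeatClass(cls)))
    return segments


def segments_to_peaks(
    segments: list[tuple[tuple[int, int], BeatClass]], mask: np.ndarray
) -> list[CandidatePeak]:
    """Candidate peak per segment: center = floor((start+end-1)/2) (the
    middle sample; even lengths round down), strength = mean probability of
    the segment's class over its span."""
    mask = np.asarray(mask)
    peaks = []
    for (start, end), beat_class in segments:
        center = (start + end - 1) // 2
        strength = float(np.mean(mask[int(beat_class), start:end]))
        peaks.append(
            CandidatePeak(
                center_index=center,
                beat_class=beat_class,
                strength=strength,
                segment_span=(start, end),
            )
        )
    return peaks


def suppress_close_peaks(
    peaks: list[CandidatePeak],
    min_gap_s: float = MIN_GAP_S,
    fs: float = TARGET_FS,
) -> list[CandidatePeak]:
    """Remove the weaker peak of pairs closer than ``min_gap_s`` (strict).

    Repeatedly takes the closest offending pair and drops its weaker member
    (ties: the later peak) until no pair is closer than the threshold.  A
    gap of exactly ``min_gap_s`` survives.
    """
    alive = sorted(peaks, key=lambda p: p.center_index)
    min_gap = min_gap_s * fs
    while len(alive) > 1:
        gaps = [
            (alive[i + 1].center_index - alive[i].center_index, i)
            for i in range(len(alive) - 1)
        ]
        gap, i = min(gaps)
        if gap >= min_gap:
            break
        a, b = alive[i], alive[i + 1]
        drop = b if a.strength >= b.strength else a
        alive.remove(drop)
    return alive


def mask_to_peaks(
    mask: np.ndarray, min_gap_s: float = MIN_GAP_S
) -> list[CandidatePeak]:
    """Full post-processing for one (4, L) probability mask."""
    labels = argmax_labels(mask)
    segments = labels_to_segments(labels)
    peaks = segments_to_peaks(segments, mask)
    return suppress_close_peaks(peaks, min_gap_s=min_gap_s)


def _window_starts(n: int) -> list[int]:
    """Start offsets of 30 s windows with 50% overlap covering n samples."""
    if n <= WINDOW_SAMPLES:
        return [0]
    step = WINDOW_SAMPLES // 2
    starts = list(range(0, n - WINDOW_SAMPLES + 1, step))
    if starts[-1] != n - WINDOW_SAMPLES:
        starts.append(n - WINDOW_SAMPLES)
    return starts


def detect(
    model,
    record: AnnotatedRecord | EcgRecord,
    min_gap_s: float = MIN_GAP_S,
) -> DetectionResult:
    """End-to-end detection: resample -> standardize -> window -> infer ->
    post-process, with peak centers mapped back to the native rate.

    Records longer than 30 s are processed in 50%-overlapping 30 s windows;
    in overlap zones each peak is kept only from the window whose center is
    nearest, and residual cross-window duplicates are removed by the final
    suppression pass.
    """
    from .network import infer  # local import to avoid a cycle

    if isinstance(record, EcgRecord):
        record = AnnotatedRecord(record=record, annotations=[])
    native_fs = record.record.fs
    if record.record.duration_s < 1.0:
        raise ValueError("record shorter than 1 s")
    resampled = resample_for_inference(record)
    n = resampled.record.n_samples

    starts = _window_starts(n)
    centers = np.array([s + WINDOW_SAMPLES / 2 for s in starts])
    all_peaks: list[CandidatePeak] = []
    for w, start in enumerate(starts):
        window = np.zeros(WINDOW_SAMPLES)
        chunk = resampled.record.samples[start : start + WINDOW_SAMPLES]
        window[: chunk.size] = chunk
        signal = preprocessing.standardize(window)
        mask = infer(model, signal)
        labels = argmax_labels(mask)
        segments = labels_to_segments(labels)
        for peak in segments_to_peaks(segments, mask):
            global_center = peak.center_index + start
            if len(starts) > 1:
                nearest = int(np.argmin(np.abs(centers - global_center)))
                if nearest != w:
                    continue
            all_peaks.append(
                CandidatePeak(
                    center_index=global_center,
                    beat_class=peak.beat_class,
                    strength=peak.strength,
                    segment_span=(
                        peak.segment_span[0] + start,
                        peak.segment_span[1] + start,
                    ),
                )
            )
    kept = suppress_close_peaks(all_peaks, min_gap_s=min_gap_s)

    scale = native_fs / TARGET_FS
    native_peaks = [
        CandidatePeak(
            center_index=int(round(p.center_index * scale)),
            beat_class=p.beat_class,
            strength=p.strength,
            segment_span=(
                int(round(p.segment_span[0] * scale)),
                int(round(p.segment_span[1] * scale)),
            ),
        )
        for p in kept
    ]
    return DetectionResult(
        record_id=record.record.record_id, fs=native_fs, peaks=native_peaks
    )


def resample_for_inference(record: AnnotatedRecord) -> AnnotatedRecord:
    if record.record.fs == TARGET_FS:
        return record
    return preprocessing.resample_to_100hz(record)
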