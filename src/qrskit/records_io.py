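"""Annotated single-lead ECG records and readers/writers.

Coordinate convention: 0-based sample indices everywhere; a time in seconds
is ``sample_index / fs``.  Amplitudes are passed through unscaled (the
downstream standardization step makes physical units irrelevant).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from ._wfdb import read_wfdb_annotations, read_wfdb_signals

logger = logging.getLogger(__name__)

__all__ = [
    "BeatClass",
    "EcgRecord",
    "BeatAnnotation",
    "AnnotatedRecord",
    "BEAT_SYMBOL_MAP",
    "select_lead",
    "read_wfdb_record",
    "read_csv_annotations",
    "write_csv_annotations",
    "read_json_record",
    "write_json_record",
]


class BeatClass(IntEnum):
    """Per-sample segmentation classes; the value is the channel index."""

    NOQRS = 0
    N = 1
    PVC = 2
    PAC = 3


#: Frozen mapping from WFDB beat annotation symbols to the three supported
#: beat classes.  Bundle/paced/escape/fusion-with-normal morphologies fold
#: into N; atrial/junctional premature beats into PAC; ventricular ectopy
#: into PVC.  Unknown *beat* symbols fall back to N with a logged warning;
#: non-beat symbols are dropped entirely.
BEAT_SYMBOL_MAP: dict[str, BeatClass] = {
    "N": BeatClass.N,
    "L": BeatClass.N,   # left bundle branch block beat
    "R": BeatClass.N,   # right bundle branch block beat
    "B": BeatClass.N,   # bundle branch block beat (unspecified)
    "e": BeatClass.N,   # atrial escape beat
    "j": BeatClass.N,   # nodal (junctional) escape beat
    "f": BeatClass.N,   # fusion of paced and normal beat
    "/": BeatClass.N,   # paced beat
    "Q": BeatClass.N,   # unclassifiable beat
    "A": BeatClass.PAC,  # atrial premature beat
    "a": BeatClass.PAC,  # aberrated atrial premature beat
    "J": BeatClass.PAC,  # nodal (junctional) premature beat
    "S": BeatClass.PAC,  # supraventricular premature beat
    "n": BeatClass.PAC,  # supraventricular escape beat
    "V": BeatClass.PVC,  # premature ventricular contraction
    "E": BeatClass.PVC,  # ventricular escape beat
    "F": BeatClass.PVC,  # fusion of ventricular and normal beat
    "r": BeatClass.PVC,  # R-on-T premature ventricular contraction
}


@dataclass
class EcgRecord:
    """A single-lead ECG signal.

    Parameters
    ----------
    samples : ndarray
        1-D float array of amplitudes (arbitrary units, typically mV).
    fs : float
        Sampling frequency in Hz; must be positive.
    lead_name : str
        Lead label, e.g. ``"I"`` or ``"MLII"``.
    record_id : str
        Identifier used to key annotations and splits.
    """

    samples: np.ndarray
    fs: float
    lead_name: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("record must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            bad = np.flatnonzero(~np.isfinite(self.samples))
            raise ValueError(
                f"record {self.record_id!r} contains non-finite samples "
                f"(first at index {bad[0]})"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True, order=True)
class BeatAnnotation:
    """One annotated beat: fiducial sample index plus its class."""

    sample_index: int
    beat_class: BeatClass

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError(f"sample_index must be >= 0, got {self.sample_index}")
        if self.beat_class == BeatClass.NOQRS:
            raise ValueError("beat annotations cannot carry the NOQRS class")

    def time_s(self, fs: float) -> float:
        return self.sample_index / fs


@dataclass
class AnnotatedRecord:
    """An :class:`EcgRecord` with its beat annotations.

    Annotations are kept sorted by sample index; duplicate indices are
    rejected, and every index must fall inside the signal.
    """

    record: EcgRecord
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.annotations = sorted(self.annotations, key=lambda a: a.sample_index)
        n = self.record.n_samples
        bad = [a.sample_index for a in self.annotations if a.sample_index >= n]
        if bad:
            raise ValueError(
                f"annotation indices beyond signal end (length {n}): {bad}"
            )
        idx = [a.sample_index for a in self.annotations]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise ValueError(f"duplicate annotation sample indices: {dupes}")

    @property
    def beat_indices(self) -> np.ndarray:
        return np.array([a.sample_index for a in self.annotations], dtype=np.int64)

    @property
    def beat_classes(self) -> list[BeatClass]:
        return [a.beat_class for a in self.annotations]


def select_lead(
    signals: np.ndarray, lead_names: list[str]
) -> tuple[np.ndarray, str]:
    """Pick the working lead from a multi-channel recording.

    Lead "I" (case-insensitive exact match) is preferred; otherwise the
    first channel is used.

    Parameters
    ----------
    signals : ndarray, shape (n_samples, n_channels) or (n_samples,)
    lead_names : list of str, parallel to the channels.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim == 1:
        signals = signals[:, None]
    if signals.shape[1] == 0 or len(lead_names) == 0:
        raise ValueError("record has no channels")
    if signals.shape[1] != len(lead_names):
        raise ValueError(
            f"{signals.shape[1]} channels but {len(lead_names)} lead names"
        )
    for i, name in enumerate(lead_names):
        if name.strip().upper() == "I":
            return signals[:, i].copy(), name
    return signals[:, 0].copy(), lead_names[0]


def read_wfdb_record(
    path: str | Path, annotation_extension: str | None = "atr"
) -> AnnotatedRecord:
    """Read a WFDB header/signal pair (plus optional annotations).

    ``path`` is the record path without extension.  Multi-lead records are
    reduced to one lead via :func:`select_lead`.  Beat symbols outside
    {N, PAC, PVC} are mapped through :data:`BEAT_SYMBOL_MAP`; non-beat
    symbols are dropped; unknown beat symbols map to N with a warning.
    """
    path = Path(path)
    signals, fields = read_wfdb_signals(path)
    channel, lead = select_lead(signals, fields["sig_name"])
    record = EcgRecord(
        samples=channel,
        fs=fields["fs"],
        lead_name=lead,
        record_id=fields["record_name"],
    )

    annotations: list[BeatAnnotation] = []
    if annotation_extension:
        ann_path = path.with_suffix("." + annotation_extension)
        if ann_path.exists():
            samples, symbols = read_wfdb_annotations(ann_path)
            seen: set[int] = set()
            out_of_range: list[int] = []
            for s, sym in zip(samples, symbols):
                beat_class = _map_symbol(sym)
                if beat_class is None:
                    continue
                if s >= record.n_samples or s < 0:
                    out_of_range.append(int(s))
                    continue
                if s in seen:
                    continue
                seen.add(int(s))
                annotations.append(BeatAnnotation(int(s), beat_class))
            if out_of_range:
                raise ValueError(
                    f"annotation indices beyond signal end "
                    f"(length {record.n_samples}): {out_of_range}"
                )
    return AnnotatedRecord(record=record, annotations=annotations)


# WFDB non-beat symbols we silently drop (rhythm changes, noise marks,
# waveform boundaries, comments...).
_NON_BEAT_SYMBOLS = set('~|s T*D"=pt^u+!x[]()@?')


def _map_symbol(symbol: str) -> BeatClass | None:
    if symbol in BEAT_SYMBOL_MAP:
        return BEAT_SYMBOL_MAP[symbol]
    if symbol in _NON_BEAT_SYMBOLS or not symbol.strip():
        return None
    logger.warning("unknown beat symbol %r mapped to class N", symbol)
    return BeatClass.N


# ---------------------------------------------------------------------------
# CSV annotation dialect: header "sample_index,beat_class", classes spelled
# "N" / "PVC" / "PAC".
# ---------------------------------------------------------------------------

def write_csv_annotations(
    annotations: list[BeatAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "beat_class"])
        for ann in sorted(annotations, key=lambda a: a.sample_index):
            writer.writerow([ann.sample_index, ann.beat_class.name])


def read_csv_annotations(path: str | Path) -> list[BeatAnnotation]:
    annotations = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != [
            "sample_index",
            "beat_class",
        ]:
            raise ValueError(f"{path}: expected header 'sample_index,beat_class'")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            token = row[1].strip()
            try:
                beat_class = BeatClass[token]
            except KeyError:
                raise ValueError(
                    f"{path}: line {lineno}: unknown beat class token {token!r}"
                ) from None
            if beat_class == BeatClass.NOQRS:
                raise ValueError(
                    f"{path}: line {lineno}: unknown beat class token {token!r}"
                )
            annotations.append(BeatAnnotation(int(row[0]), beat_class))
    return sorted(annotations, key=lambda a: a.sample_index)


# ---------------------------------------------------------------------------
# JSON record container (used for synthetic fixtures and the CLI).
# ---------------------------------------------------------------------------

def write_json_record(annotated: AnnotatedRecord, path: str | Path) -> None:
    payload = {
        "record_id": annotated.record.record_id,
        "fs": annotated.record.fs,
        "lead_name": annotated.record.lead_name,
        "samples": [float(x) for x in annotated.record.samples],
        "annotations": [
            {"sample_index": a.sample_index, "beat_class": a.beat_class.name}
            for a in annotated.annotations
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_json_record(path: str | Path) -> AnnotatedRecord:
    with open(path) as fh:
        payload = json.load(fh)
    record = EcgRecord(
        samples=np.asarray(payload["samples"], dtype=np.float64),
        fs=float(payload["fs"]),
        lead_name=payload.get("lead_name", ""),
        record_id=payload.get("record_id", ""),
    )
    annotations = [
        BeatAnnotation(int(a["sample_index"]), BeatClass[a["beat_class"]])
        for a in payload.get("annotations", [])
    ]
    return AnnotatedRecord(record=record, annotations=annotations)
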