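"""Minimal WFDB reader: header parsing, signal formats 16 and 212, and the
binary annotation format.

Only the subset needed to load standard single- and multi-lead Holter/ECG
database records is implemented.  Values are converted to physical units as
``(adc - baseline) / gain``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_wfdb_signals", "read_wfdb_annotations", "WfdbFormatError"]


class WfdbFormatError(ValueError):
    """Raised for missing or malformed WFDB files."""


_DEFAULT_GAIN = 200.0


def _parse_header(path: Path) -> tuple[dict, list[dict]]:
    try:
        text = path.read_text()
    except OSError as exc:
        raise WfdbFormatError(f"cannot read WFDB header {path}: {exc}") from exc
    lines = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise WfdbFormatError(f"{path}: empty WFDB header")
    head = lines[0].split()
    if len(head) < 2:
        raise WfdbFormatError(f"{path}: malformed record line {lines[0]!r}")
    record_name = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except ValueError as exc:
        raise WfdbFormatError(f"{path}: malformed record line {lines[0]!r}") from exc
    if n_sig < 1:
        raise WfdbFormatError(f"{path}: record declares {n_sig} signals")
    if len(lines) < 1 + n_sig:
        raise WfdbFormatError(
            f"{path}: header declares {n_sig} signals but lists {len(lines) - 1}"
        )

    signal_specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise WfdbFormatError(f"{path}: malformed signal line {ln!r}")
        fname = parts[0]
        fmt_field = parts[1]
        fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = _DEFAULT_GAIN, None
        adc_zero = 0
        if len(parts) > 2:
            gfield = parts[2].split("/")[0]
            if "(" in gfield:
                gpart, bpart = gfield.split("(")
                gain = float(gpart) if gpart else _DEFAULT_GAIN
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gfield)
            if gain == 0:
                gain = _DEFAULT_GAIN
        if len(parts) > 4:
            try:
                adc_zero = int(parts[4])
            except ValueError:
                adc_zero = 0
        description = " ".join(parts[8:]) if len(parts) > 8 else ""
        signal_specs.append(
            {
                "file_name": fname,
                "format": fmt,
                "gain": gain,
                "baseline": baseline if baseline is not None else adc_zero,
                "description": description,
            }
        )
    meta = {"record_name": record_name, "n_sig": n_sig, "fs": fs, "n_samples": n_samples}
    return meta, signal_specs


def _read_dat(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """Return raw ADC values with shape (n_samples, n_sig)."""
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise WfdbFormatError(f"cannot read WFDB signal file {path}: {exc}") from exc
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        n = data.size // n_sig
        return data[: n * n_sig].reshape(n, n_sig).astype(np.int32)
    if fmt == 212:
        # pairs of 12-bit samples packed into 3 bytes
        b = np.frombuffer(raw, dtype=np.uint8)
        n_triplets = b.size // 3
        b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(2 * n_triplets, dtype=np.int32)
        flat[0::2] = first
        flat[1::2] = second
        n = flat.size // n_sig
        return flat[: n * n_sig].reshape(n, n_sig)
    if fmt == 8:
        # first differences, signed bytes
        d = np.frombuffer(raw, dtype=np.int8).astype(np.int32)
        n = d.size // n_sig
        return np.cumsum(d[: n * n_sig].reshape(n, n_sig), axis=0)
    raise WfdbFormatError(f"{path}: unsupported WFDB signal format {fmt}")


def read_wfdb_signals(record_path: Path) -> tuple[np.ndarray, dict]:
    """Read a WFDB record.

    Parameters
    ----------
    record_path : Path
        Path to the record WITHOUT extension (``.hea`` appended here).

    Returns
    -------
    signals : ndarray, shape (n_samples, n_sig), physical units
    fields : dict with record_name, fs, sig_name
    """
    header = record_path.with_suffix(".hea")
    if not header.exists():
        raise WfdbFormatError(f"missing WFDB header: {header}")
    meta, specs = _parse_header(header)

    # group channels by data file, preserving channel order
    by_file: dict[str, list[int]] = {}
    for i, spec in enumerate(specs):
        by_file.setdefault(spec["file_name"], []).append(i)

    columns: dict[int, np.ndarray] = {}
    for fname, channel_idx in by_file.items():
        fmts = {specs[i]["format"] for i in channel_idx}
        if len(fmts) != 1:
            raise WfdbFormatError(f"{header}: mixed formats in one signal file")
        adc = _read_dat(record_path.parent / fname, fmts.pop(), len(channel_idx))
        for col, i in enumerate(channel_idx):
            spec = specs[i]
            columns[i] = (adc[:, col] - spec["baseline"]) / spec["gain"]

    n = min(c.size for c in columns.values())
    if meta["n_samples"]:
        n = min(n, meta["n_samples"])
    signals = np.column_stack([columns[i][:n] for i in range(meta["n_sig"])])
    fields = {
        "record_name": meta["record_name"],
        "fs": meta["fs"],
        "sig_name": [s["description"] or f"ch{i}" for i, s in enumerate(specs)],
    }
    return signals, fields


# ---------------------------------------------------------------------------
# Annotation format: 2-byte little-endian words; code = word >> 10,
# time increment = word & 0x3FF.  Codes 59-63 are pseudo-annotations
# (SKIP carries a 4-byte interval, AUX carries a byte payload).
# ---------------------------------------------------------------------------

_ANN_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_wfdb_annotations(path: Path) -> tuple[np.ndarray, list[str]]:
    """Read a WFDB annotation file; returns (sample_indices, symbols)."""
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise WfdbFormatError(f"cannot read annotation file {path}: {exc}") from exc

    samples: list[int] = []
    symbols: list[str] = []
    time = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:  # EOF
            break
        if code == _SKIP:
            if i + 3 >= n:
                raise WfdbFormatError(f"{path}: truncated SKIP annotation")
            high = raw[i] | (raw[i + 1] << 8)
            low = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            skip = (high << 16) | low
            if skip >= 1 << 31:
                skip -= 1 << 32
            time += skip
        elif code == _AUX:
            i += interval + (interval & 1)  # payload padded to even length
        elif code in (_NUM, _SUB, _CHN):
            pass
        else:
            time += interval
            samples.append(time)
            symbols.append(_ANN_SYMBOLS.get(code, "?"))
    return np.asarray(samples, dtype=np.int64), symbols
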