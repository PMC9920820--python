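"""Minimal reader/writer for the PhysioNet WFDB format family.

Covers the subset the package needs: ``.hea`` headers, signal files in
format 16 (16-bit little-endian) and format 212 (packed 12-bit pairs, the
MIT-BIH layout), and MIT-format annotation files.  Multi-channel records
are supported on read; writing is single-channel (the detectors are
single-lead).

Physical units follow the WFDB convention: ``physical = (digital -
baseline) / gain``.  Sample indices are 0-based throughout.

A plain two-column CSV dialect (``time_s`` or ``sample``, then amplitude,
header optional) is also supported.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import ECGRecord

# MIT annotation codes for the beat classes this package reads and writes.
SYMBOL_TO_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "e": 34, "f": 38,
}
CODE_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CODE.items()}
#: Annotation codes that denote beats (rhythm labels, artefacts and other
#: non-beat annotations are excluded from ground truth before scoring).
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13,
                        25, 34, 35, 38, 41})

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class WFDBError(IOError):
    """Raised when a WFDB file cannot be parsed."""


def _strip_ext(path) -> Path:
    p = Path(path)
    if p.suffix in {".hea", ".dat", ".atr", ".qrs"}:
        p = p.with_suffix("")
    return p


def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WFDBError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 3:
        raise WFDBError(f"{hea_path}: malformed record line {lines[0]!r}")
    record_name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0])
    nsamp = int(head[3]) if len(head) > 3 else None
    signals = []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        fmt_tok = tok[1]
        for sep in ("x", ":", "+"):
            fmt_tok = fmt_tok.split(sep)[0]
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_tok = gain_tok.split("/")[0]
        if "(" in gain_tok:
            gain_s, base_s = gain_tok.rstrip(")").split("(")
            gain, baseline = float(gain_s), int(base_s)
        else:
            gain = float(gain_tok)
            baseline = int(tok[4]) if len(tok) > 4 else 0
        if gain == 0:
            gain = 200.0
        signals.append({
            "filename": tok[0], "format": int(fmt_tok),
            "gain": gain, "baseline": baseline,
            "description": " ".join(tok[8:]) if len(tok) > 8 else "",
        })
    return record_name, nsig, fs, nsamp, signals


def _read_digital(dat_path: Path, fmt: int, nsig: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        n = len(data) // nsig
        return data[: n * nsig].reshape(n, nsig)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        n_triplets = len(b) // 3
        b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        flat = np.empty(2 * n_triplets, dtype=np.int32)
        flat[0::2], flat[1::2] = s0, s1
        n = len(flat) // nsig
        return flat[: n * nsig].reshape(n, nsig)
    raise WFDBError(f"{dat_path}: unsupported signal format {fmt}")


def read_record(path, channel: int = 0) -> ECGRecord:
    """Read a WFDB record; the first listed signal is used by default."""
    base = _strip_ext(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise WFDBError(f"header not found: {hea}")
    record_name, nsig, fs, nsamp, signals = _parse_header(hea)
    if not 0 <= channel < nsig:
        raise WFDBError(f"{hea}: channel {channel} out of range (nsig={nsig})")
    sig = signals[channel]
    dat = base.parent / sig["filename"]
    digital = _read_digital(dat, sig["format"], nsig)
    if nsamp is not None:
        digital = digital[:nsamp]
    physical = (digital[:, channel] - sig["baseline"]) / sig["gain"]
    return ECGRecord(samples=physical, fs=fs, record_id=record_name)


def write_record(record: ECGRecord, path, gain: float = 1000.0,
                 fmt: int = 16) -> None:
    """Write a single-channel record as ``.hea`` + format-16 ``.dat``."""
    if fmt != 16:
        raise WFDBError(f"only format 16 writing is supported, got {fmt}")
    base = _strip_ext(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    digital = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    n = len(digital)
    name = base.name
    fs = record.fs
    fs_str = f"{fs:g}"
    hea = (f"{name} 1 {fs_str} {n}\n"
           f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(digital[0]) if n else 0} 0 0 ECG\n")
    base.with_suffix(".hea").write_text(hea)
    base.with_suffix(".dat").write_bytes(digital.tobytes())


def read_annotations(path, extension: str = "atr",
                     beats_only: bool = True) -> list[tuple[int, str]]:
    """Read a MIT-format annotation file as (sample_index, symbol) pairs."""
    base = _strip_ext(path)
    ann_path = base.with_suffix("." + extension)
    if not ann_path.exists():
        raise WFDBError(f"annotation file not found: {ann_path}")
    raw = ann_path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        dt = word & 0x3FF
        if code == 0 and dt == 0:
            break
        if code == _SKIP and dt == 0:
            if i + 3 >= len(raw):
                raise WFDBError(f"{ann_path}: truncated SKIP")
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            jump = (hi << 16) | lo
            if jump >= 1 << 31:
                jump -= 1 << 32
            t += jump
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += dt + (dt & 1)
            continue
        t += dt
        if beats_only and code not in BEAT_CODES:
            continue
        out.append((t, CODE_TO_SYMBOL.get(code, f"#{code}")))
    return out


def write_annotations(path, annotations: list[tuple[int, str]],
                      extension: str = "atr") -> None:
    """Write (sample_index, symbol) pairs as a MIT-format annotation file."""
    base = _strip_ext(path)
    buf = bytearray()
    t_prev = 0
    for idx, symbol in annotations:
        code = SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise WFDBError(f"cannot encode annotation symbol {symbol!r}")
        dt = idx - t_prev
        if dt < 0:
            raise WFDBError("annotation indices must be non-decreasing")
        if dt > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        buf += struct.pack("<H", (code << 10) | dt)
        t_prev = idx
    buf += struct.pack("<H", 0)
    base.with_suffix("." + extension).write_bytes(bytes(buf))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_csv_record(path, fs: float | None = None) -> ECGRecord:
    """Read a two-column CSV (time_s-or-sample, amplitude; header optional).

    If the first column is time in seconds the sampling rate is inferred
    from the median step; if it is a sample counter, ``fs`` must be given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise WFDBError(f"{path}: cannot parse CSV ({exc})") from exc
    # drop a header row if the first row is not numeric
    first = df.iloc[0]
    if any(not _is_number(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 1:
        col0 = None
        amp = df.iloc[:, 0].astype(float).to_numpy()
    else:
        col0 = df.iloc[:, 0].astype(float).to_numpy()
        amp = df.iloc[:, 1].astype(float).to_numpy()
    if fs is None:
        if col0 is None:
            raise WFDBError(f"{path}: sampling rate required for single-column CSV")
        step = float(np.median(np.diff(col0)))
        if step <= 0:
            raise WFDBError(f"{path}: non-increasing first column")
        if abs(step - round(step)) < 1e-9 and step >= 1:
            raise WFDBError(
                f"{path}: first column looks like a sample counter; pass fs")
        fs = 1.0 / step
    return ECGRecord(samples=amp, fs=float(fs), record_id=path.stem)


def write_csv_record(record: ECGRecord, path) -> None:
    """Write a record as ``time_s,amplitude`` CSV with a header row."""
    t = np.arange(len(record.samples)) / record.fs
    pd.DataFrame({"time_s": t, "amplitude": record.samples}).to_csv(
        Path(path), index=False)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False
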