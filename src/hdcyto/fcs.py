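"""Minimal Flow Cytometry Standard (FCS) 3.0/3.1 reader and writer.

Covers the subset of the standard that cytometry exports in practice use for
downstream analysis: list-mode (``$MODE L``) data with floating-point events
(``$DATATYPE F`` or ``D``), either byte order.  Spillover/compensation is not
touched — files are assumed compensated upstream.

The writer emits FCS 3.1 with float32 events, which is why a write/read
round-trip of float64 values is only exact to float32 precision (~1e-6
relative).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["FcsError", "read_fcs", "write_fcs"]

_HEADER_LEN = 58
_DELIM = b"/"


class FcsError(ValueError):
    """Raised when a file cannot be parsed as FCS."""


def _ascii_int(raw: bytes, path: Path, offset: int) -> int:
    txt = raw.decode("ascii", errors="replace").strip()
    if txt == "":
        return 0
    try:
        return int(txt)
    except ValueError as exc:
        raise FcsError(
            f"{path}: malformed ASCII offset at byte {offset}: {txt!r}"
        ) from exc


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], list[str], dict]:
    """Read an FCS file.

    Returns
    -------
    data : (events, channels) float64 array
    pnn : detector names ($PnN)
    pns : stain names ($PnS; empty string where absent)
    text : the full TEXT-segment keyword dictionary
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FcsError(f"{path}: file shorter than FCS header (byte 0)")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS"):
        raise FcsError(f"{path}: bad magic {version!r} at byte 0")

    text_start = _ascii_int(raw[10:18], path, 10)
    text_end = _ascii_int(raw[18:26], path, 18)
    data_start = _ascii_int(raw[26:34], path, 26)
    data_end = _ascii_int(raw[34:42], path, 34)
    if text_end <= text_start or text_end >= len(raw):
        raise FcsError(f"{path}: invalid TEXT segment offsets at byte 10")

    seg = raw[text_start : text_end + 1]
    delim = seg[:1]
    parts = seg[1:].split(delim)
    # trailing delimiter produces an empty final token
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FcsError(f"{path}: odd keyword count in TEXT segment at byte {text_start}")
    text = {
        parts[i].decode("ascii", errors="replace").strip().upper():
        parts[i + 1].decode("ascii", errors="replace").strip()
        for i in range(0, len(parts), 2)
    }

    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
    except KeyError as exc:
        raise FcsError(f"{path}: missing required keyword {exc}") from exc
    datatype = text.get("$DATATYPE", "F").upper()
    if datatype not in ("F", "D"):
        raise FcsError(
            f"{path}: unsupported $DATATYPE {datatype!r} (only F/D handled)"
        )
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsError(f"{path}: unsupported $MODE {mode!r}")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    itemsize = 4 if datatype == "F" else 8
    dtype = np.dtype(("<" if little else ">") + ("f4" if datatype == "F" else "f8"))

    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    n_bytes = n_par * n_tot * itemsize
    if data_start <= 0 or data_start + n_bytes > len(raw):
        raise FcsError(
            f"{path}: DATA segment (offset {data_start}, {n_bytes} bytes) "
            f"exceeds file size {len(raw)}"
        )
    data = (
        np.frombuffer(raw, dtype=dtype, count=n_par * n_tot, offset=data_start)
        .reshape(n_tot, n_par)
        .astype(np.float64)
    )
    pnn = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    pns = [text.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    return data, pnn, pns, text


def write_fcs(path: str | Path, data: np.ndarray, channel_names: list[str]) -> Path:
    """Write an FCS 3.1 list-mode file with float32 events."""
    path = Path(path)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events x channels)")
    n_tot, n_par = data.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length must match data columns")

    payload = data.astype("<f4").tobytes()

    def build_text(begin_data: int, end_data: int) -> bytes:
        kv: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINDATA", f"{begin_data:010d}"),
            ("$ENDDATA", f"{end_data:010d}"),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
        ]
        col_max = np.nanmax(data, axis=0) if n_tot else np.ones(n_par)
        for i, name in enumerate(channel_names, start=1):
            rng = max(float(col_max[i - 1]), 1.0)
            kv += [
                (f"$P{i}N", str(name)),
                (f"$P{i}S", str(name)),
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", f"{rng:.0f}"),
            ]
        out = _DELIM
        for k, v in kv:
            out += k.encode("ascii") + _DELIM + v.encode("ascii") + _DELIM
        return out

    # data offsets depend on text length; the zero-padded $BEGINDATA/$ENDDATA
    # keep the text length fixed across the two passes
    text = build_text(0, 0)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    text = build_text(data_start, data_end)

    def fld(v: int) -> bytes:
        return (str(v) if v <= 99_999_999 else "0").rjust(8).encode("ascii")

    header = b"FCS3.1    " + fld(text_start) + fld(text_end) + fld(data_start) + fld(data_end) + fld(0) + fld(0)
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)
    return path
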