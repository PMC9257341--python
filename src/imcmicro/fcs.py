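"""Minimal FCS 3.0 writer/reader for cell tables.

Writes list-mode float32 little-endian data with one event per cell and one
parameter per numeric column, which is what downstream cytometry viewers
expect of segmentation-derived single-cell tables. Only the subset of the
standard needed for round-tripping numeric matrices is implemented: single
data segment, ``$DATATYPE F``, ``$MODE L``, no analysis segment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_fcs", "read_fcs"]

_DELIM = "/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(path: str | Path, names: list[str], data: np.ndarray) -> None:
    """Write ``data`` (n_events × n_params) as an FCS 3.0 file.

    Values are stored as float32; callers should not expect better than
    float32 round-trip precision.
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2 or data.shape[1] != len(names):
        raise ValueError("data must be 2-D with one column per parameter name")
    n_events, n_par = data.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(names, start=1):
        keywords[f"$P{i}N"] = name.replace(_DELIM, "_")
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        rng = float(data[:, i - 1].max()) if n_events else 1.0
        keywords[f"$P{i}R"] = str(max(int(np.ceil(rng)) + 1, 1))

    header_len = 58  # "FCS3.0" + 4 spaces + 6 × 8-char offsets
    # Offsets depend on the TEXT length, which depends on the offsets; the
    # digit count stabilises after a couple of passes.
    begin_text = header_len
    begin_data = end_data = 0
    for _ in range(4):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _text_segment(kw)
        new_begin_data = begin_text + len(text)
        new_end_data = new_begin_data + data.nbytes - 1 if data.nbytes else new_begin_data
        if (new_begin_data, new_end_data) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin_data, new_end_data
    end_text = begin_text + len(text) - 1

    def _off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for header slot; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.0    " + _off(begin_text) + _off(end_text)
    header += _off(begin_data) + _off(end_data) + _off(0) + _off(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an FCS 3.0 file written by :func:`write_fcs` (or compatible)."""
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3"):
        raise ValueError("not an FCS 3.x file")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = raw[begin_text : end_text + 1].decode("ascii")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i]: fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise ValueError("only list-mode float FCS is supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord == "1,2,3,4" else ">f4"
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    begin_data = int(kw.get("$BEGINDATA") or raw[26:34])
    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    data = np.frombuffer(
        raw, dtype=dtype, count=n_par * n_tot, offset=begin_data
    ).reshape(n_tot, n_par)
    return names, np.asarray(data, dtype=np.float32)
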