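"""Minimal FCS 3.0 / 3.1 listmode reader and writer.

Implements the subset of the Flow Cytometry Standard needed for event
tables: list-mode ($MODE L) data in floating point ($DATATYPE F or D) or
unsigned integer ($DATATYPE I) with byte-aligned parameter widths, both byte
orders.  Analysis and supplemental-text segments are ignored on read and
never written.  This is a self-contained implementation of the published
format, not a wrapper.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["read_fcs", "write_fcs"]

_DELIM = "/"


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM * 2)


def write_fcs(data: pd.DataFrame, path, *, version: str = "FCS3.1") -> None:
    """Write a numeric DataFrame as an FCS listmode file (float32 data).

    Column names become $PnN short parameter names.
    """
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r}")
    names = list(data.columns)
    values = np.ascontiguousarray(data.to_numpy(dtype="<f4"))
    n_events, n_par = values.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(names, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(float(np.max(values[:, i - 1], initial=0.0)), 1.0)) + 1)

    data_bytes = values.tobytes()
    n_data = len(data_bytes)

    # TEXT length depends on the BEGIN/END DATA offsets it contains; the
    # digit count of those offsets depends on the TEXT length — iterate to a
    # fixed point (always converges in a few rounds).
    header_len = 58
    begin_data = 0
    for _ in range(10):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(begin_data + n_data - 1 if n_data else 0)
        text = _DELIM + _DELIM.join(
            _escape(k) + _DELIM + _escape(v) for k, v in sorted(kw.items())
        ) + _DELIM
        text_bytes = text.encode("utf-8")
        new_begin = header_len + len(text_bytes)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    begin_text = header_len
    end_text = begin_text + len(text_bytes) - 1
    end_data = begin_data + n_data - 1 if n_data else 0

    def _off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # segment beyond the 8-digit header; real offset in TEXT
        return s.rjust(8).encode("ascii")

    header = version.encode("ascii") + b"    " + _off(begin_text) + _off(end_text)
    header += _off(begin_data if len(str(end_data)) <= 8 else 0)
    header += _off(end_data if len(str(end_data)) <= 8 else 0)
    header += _off(0) + _off(0)  # no analysis segment

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    if not text:
        raise FormatError("empty TEXT segment")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # doubled delimiters are escaped literals
    parts = body.replace(delim * 2, "\x00").split(delim)
    parts = [p.replace("\x00", delim) for p in parts]
    if len(parts) % 2:
        raise FormatError("TEXT segment has an odd number of delimited fields")
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 listmode file into a DataFrame keyed by $PnN names."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS"):
        raise FormatError(f"{path}: bad magic {version!r}, not an FCS file")

    def _header_off(lo: int) -> int:
        field = raw[lo : lo + 8].decode("ascii", errors="replace").strip()
        return int(field) if field else 0

    try:
        begin_text, end_text = _header_off(10), _header_off(18)
        begin_data, end_data = _header_off(26), _header_off(34)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header offsets") from exc

    kw = _parse_text(raw[begin_text : end_text + 1])
    if begin_data == 0:
        begin_data = int(kw.get("$BEGINDATA", 0))
        end_data = int(kw.get("$ENDDATA", 0))

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FormatError(f"{path}: only list mode is supported, got $MODE={mode}")
    datatype = kw.get("$DATATYPE", "F").upper()
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    widths = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    payload = raw[begin_data : end_data + 1]
    if datatype in ("F", "D"):
        itemsize = 4 if datatype == "F" else 8
        if any(w != itemsize * 8 for w in widths):
            raise FormatError(f"{path}: $PnB inconsistent with $DATATYPE {datatype}")
        arr = np.frombuffer(payload, dtype=f"{endian}f{itemsize}", count=n_tot * n_par)
        values = arr.reshape(n_tot, n_par).astype(float)
    elif datatype == "I":
        if len(set(widths)) != 1 or widths[0] not in (8, 16, 32, 64):
            raise FormatError(f"{path}: only uniform byte-aligned integer widths supported")
        arr = np.frombuffer(payload, dtype=f"{endian}u{widths[0] // 8}", count=n_tot * n_par)
        values = arr.reshape(n_tot, n_par).astype(float)
        # $PnE log amplification: value = 10^(f1·x/range) · f2
        for i in range(n_par):
            f1f2 = kw.get(f"$P{i + 1}E", "0,0").split(",")
            f1, f2 = float(f1f2[0]), float(f1f2[1])
            if f1 != 0.0:
                rng = float(kw.get(f"$P{i + 1}R", "1024"))
                values[:, i] = 10.0 ** (f1 * values[:, i] / rng) * (f2 if f2 else 1.0)
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    frame = pd.DataFrame(values, columns=names)
    frame.attrs["fcs_keywords"] = kw
    frame.attrs["fcs_version"] = version
    return frame
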