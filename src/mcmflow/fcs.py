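"""Minimal FCS list-mode file support.

Reads FCS 3.0 / 3.1 files with list-mode (``$MODE L``) float32/float64 or
integer data, and writes FCS 3.1 files with float32 data, little-endian byte
order and one TEXT keyword set per parameter (``$PnN``, ``$PnB 32``,
``$PnE 0,0``, ``$PnR``). This intentionally covers only the subset of the
standard needed for plain list-mode cytometry tables: no ANALYSIS segment,
no supplemental TEXT, single data set per file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

_DELIM = "/"


def _escape(v: str) -> str:
    return str(v).replace(_DELIM, _DELIM + _DELIM)


def write_fcs(path, df: pd.DataFrame, long_names: dict[str, str] | None = None) -> None:
    """Write a numeric DataFrame as an FCS 3.1 float list-mode file.

    Column names become ``$PnN`` channel short names; ``long_names`` maps
    short names to optional ``$PnS`` labels.
    """
    cols = list(df.columns)
    n_par = len(cols)
    n_tot = len(df)
    if n_par == 0:
        raise InputError("cannot write an FCS file with zero parameters")
    data = np.ascontiguousarray(df.to_numpy(dtype="<f4"))
    payload = data.tobytes()

    def build_text(begin_data: int, end_data: int) -> bytes:
        kv = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": str(begin_data), "$ENDDATA": str(end_data),
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
            "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
        }
        for i, name in enumerate(cols, start=1):
            kv[f"$P{i}N"] = _escape(name)
            if long_names and name in long_names:
                kv[f"$P{i}S"] = _escape(long_names[name])
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            col = df[name].to_numpy()
            rng = float(np.max(col)) if len(col) else 1.0
            kv[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{_escape(v)}" for k, v in kv.items()) + _DELIM
        return text.encode("ascii")

    # offsets depend on the TEXT length, which depends on the offsets: iterate
    begin_data = end_data = 0
    for _ in range(4):
        text = build_text(begin_data, end_data)
        new_begin = 58 + len(text)
        new_end = new_begin + len(payload) - 1 if payload else 0
        if payload == b"":
            new_begin = 0
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = build_text(begin_data, end_data)
    text_begin = 58
    text_end = 58 + len(text) - 1

    def field(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:  # offset too large for the header; 0 defers to TEXT
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + field(text_begin) + field(text_end) \
        + field(begin_data if begin_data <= 99999999 else 0) \
        + field(end_data if end_data <= 99999999 else 0) \
        + field(0) + field(0)
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise InputError("empty FCS TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")[1:]
    if body.endswith(delim):
        body = body[:-1]
    # escaped delimiters appear as doubled delimiters
    parts = body.split(delim)
    tokens, i = [], 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            tok += delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2:
        tokens = tokens[:-1]
    return {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS 3.0/3.1 file; returns (events, TEXT keywords).

    Event columns are named by ``$PnN``; ``$PnS`` long names are kept in the
    metadata dict.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise InputError(f"{path}: truncated FCS header")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise InputError(f"{path}: unsupported FCS version {version!r} "
                         "(FCS 3.0/3.1 supported)")

    def off(a: int, b: int) -> int:
        s = raw[a:b].decode("ascii", "replace").strip()
        try:
            return int(s) if s else 0
        except ValueError:
            raise InputError(f"{path}: malformed FCS header offsets") from None

    text_begin, text_end = off(10, 18), off(18, 26)
    data_begin, data_end = off(26, 34), off(34, 42)
    if not 0 < text_begin < text_end < len(raw):
        raise InputError(f"{path}: malformed FCS header (TEXT segment offsets)")
    meta = _parse_text(raw[text_begin:text_end + 1])

    if data_begin == 0:
        data_begin = int(meta.get("$BEGINDATA", 0))
        data_end = int(meta.get("$ENDDATA", 0))
    n_par = int(meta["$PAR"])
    n_tot = int(meta["$TOT"])
    names = [meta.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if n_tot == 0:
        return pd.DataFrame({n: pd.Series(dtype=np.float32) for n in names}), meta

    dtype = meta.get("$DATATYPE", "F").upper()
    byteord = meta.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if dtype == "F":
        np_dtype = np.dtype(f"{endian}f4")
    elif dtype == "D":
        np_dtype = np.dtype(f"{endian}f8")
    elif dtype == "I":
        bits = {int(meta.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise InputError(f"{path}: unsupported integer layout")
        np_dtype = np.dtype(f"{endian}u{int(meta['$P1B']) // 8}")
    else:
        raise InputError(f"{path}: unsupported $DATATYPE {dtype!r}")

    nbytes = n_par * n_tot * np_dtype.itemsize
    if data_end and data_end - data_begin + 1 < nbytes:
        raise InputError(f"{path}: DATA segment shorter than $PAR*$TOT events")
    buf = raw[data_begin:data_begin + nbytes]
    arr = np.frombuffer(buf, dtype=np_dtype).reshape(n_tot, n_par)
    return pd.DataFrame({n: arr[:, i] for i, n in enumerate(names)}), meta
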