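"""Reading and writing event data: CSV and a minimal FCS 3.x codec.

CSV files carry one header row with channel names. FCS support covers the
single-dataset, list-mode, float32 little-endian layout that this package
writes (FCS 3.1) and reads back (FCS 3.0/3.1 with $DATATYPE F or D), which
is sufficient for exchanging the five height channels used here. Instrument
exports with vendor channel names (e.g. MACSQuant "B1-H"/"Y2-H"/"V1-H") are
mapped onto canonical names via a configurable alias table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import CHANNELS, EventTable, MissingChannelError

#: Instrument-name aliases -> canonical channel names. The defaults mirror a
#: MACSQuant VYB configuration: B1 (520/50) GFP, Y2 (615/20) mCherry,
#: V1 (450/50) SYTO 40.
DEFAULT_ALIASES = {
    "B1-H": "GFP-H",
    "Y2-H": "mCherry-H",
    "V1-H": "SYTO-H",
    "FSC-H": "FSC-H",
    "SSC-H": "SSC-H",
}


def _canonicalize(columns, aliases) -> dict:
    mapping = {}
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    for col in columns:
        mapping[col] = table.get(col, col)
    return mapping


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_csv(table: EventTable, path) -> None:
    table.data.to_csv(path, index=False)


def _read_csv(path, aliases=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(columns=_canonicalize(df.columns, aliases))


# ---------------------------------------------------------------------------
# FCS 3.1 (minimal single-dataset codec)
# ---------------------------------------------------------------------------

_DELIM = "/"


def write_fcs(table: EventTable, path) -> None:
    """Write events as FCS 3.1: list mode, float32, little-endian."""
    mat = table.channel_matrix().astype("<f4")
    n, p = mat.shape
    data = mat.tobytes()

    kw = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$PAR": str(p), "$TOT": str(n),
        "$FIL": str(Path(path).name), "$SYS": "flowdeconv",
    }
    for i, ch in enumerate(CHANNELS, start=1):
        kw[f"$P{i}N"] = ch
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"

    # fixed-width offsets so the TEXT segment length is stable
    def text_bytes(begin_data: int, end_data: int) -> bytes:
        items = {"$BEGINDATA": f"{begin_data:>10d}", "$ENDDATA": f"{end_data:>10d}", **kw}
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in items.items()) + _DELIM
        return body.encode("ascii")

    header_len = 58
    probe = text_bytes(0, 0)
    text_start = header_len
    text_end = text_start + len(probe) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1 if data else 0
    text = text_bytes(data_start if data else 0, data_end)
    assert len(text) == len(probe)

    header = (b"FCS3.1    "
              + f"{text_start:>8d}".encode() + f"{text_end:>8d}".encode()
              + f"{data_start if data else 0:>8d}".encode() + f"{data_end:>8d}".encode()
              + f"{0:>8d}".encode() + f"{0:>8d}".encode())
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header + text + data)


def _parse_text_segment(raw: bytes) -> dict:
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}


def read_fcs(path, aliases=None) -> pd.DataFrame:
    """Read a single-dataset FCS 3.0/3.1 file into a DataFrame."""
    blob = Path(path).read_bytes()
    if not blob[:6].startswith(b"FCS3"):
        raise IOError(f"{path}: not an FCS 3.x file")
    text_start, text_end = int(blob[10:18]), int(blob[18:26])
    data_start, data_end = int(blob[26:34] or b"0"), int(blob[34:42] or b"0")
    kw = _parse_text_segment(blob[text_start:text_end + 1])
    if data_start == 0:
        data_start, data_end = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])

    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code not in ("F", "D"):
        raise IOError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(f"{endian}f{4 if dtype_code == 'F' else 8}")

    p = int(kw["$PAR"])
    n = int(kw["$TOT"])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, p + 1)]
    raw = blob[data_start:data_end + 1]
    mat = np.frombuffer(raw, dtype=dtype, count=n * p).reshape(n, p).astype(float)
    df = pd.DataFrame(mat, columns=names)
    return df.rename(columns=_canonicalize(df.columns, aliases))


# ---------------------------------------------------------------------------
# Front door
# ---------------------------------------------------------------------------

def read_events(path, format: str | None = None, aliases=None,
                sample_id: str | None = None) -> EventTable:
    """Read an event table from CSV or FCS.

    ``format`` is "csv" or "fcs"; when None it is inferred from the file
    extension. Channel columns are mapped through the alias table; a missing
    canonical channel raises :class:`MissingChannelError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = _read_csv(path, aliases)
    elif fmt == "fcs":
        df = read_fcs(path, aliases)
    else:
        raise ValueError(f"unknown event format {fmt!r} (expected csv or fcs)")
    return EventTable(df, sample_id=sample_id if sample_id is not None else path.stem)
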