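"""Reading and writing flow-cytometry event tables and imaging data.

Event tables travel either as the CSV dialect written by
:mod:`splitfp.simulate` (columns ``FSC-A, SSC-A, FSC-H, green, blue`` with
the channel ceiling recorded in a leading comment line) or as FCS 3.0/3.1
files, the binary standard emitted by cytometers.  The FCS reader here
covers the list-mode subset the pipeline needs: the delimited TEXT segment,
float (``$DATATYPE F``/``D``) or unsigned-integer (``$DATATYPE I``) DATA
segments, and per-parameter ranges (``$PnR``) as saturation ceilings.
Instrument channel names are mapped to the canonical ones via a channel
map.  Writing FCS is out of scope.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flow import CHANNELS, FlowEventTable

__all__ = [
    "DEFAULT_CHANNEL_MAP",
    "write_events_csv",
    "read_events_csv",
    "read_fcs",
    "ingest_events",
    "write_field_tiff",
    "read_field_tiff",
]

#: CSV/FCS column names -> canonical channel names
DEFAULT_CHANNEL_MAP = {
    "FSC-A": "fsc_a",
    "SSC-A": "ssc_a",
    "FSC-H": "fsc_h",
    "green": "green",
    "blue": "blue",
}

_CSV_COLUMNS = list(DEFAULT_CHANNEL_MAP)


def write_events_csv(table: FlowEventTable, path: str | Path) -> None:
    """Write an event table as CSV with a ceilings metadata comment line."""
    path = Path(path)
    inv = {v: k for k, v in DEFAULT_CHANNEL_MAP.items()}
    ceilings = {inv[ch]: table.ceilings[ch] for ch in CHANNELS}
    out = table.events[list(CHANNELS)].rename(columns=inv)[_CSV_COLUMNS]
    with path.open("w") as fh:
        fh.write(f"# ceilings: {json.dumps(ceilings)}\n")
        out.to_csv(fh, index=False)


def read_events_csv(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
    ceilings: dict[str, float] | None = None,
) -> FlowEventTable:
    """Read an event-table CSV (the dialect written by :func:`write_events_csv`).

    Ceilings come from the metadata comment line unless overridden.
    """
    path = Path(path)
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    header_ceilings: dict[str, float] = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# ceilings:"):
            header_ceilings = json.loads(first.split(":", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    df = _map_channels(df, channel_map)
    resolved = _resolve_ceilings(
        ceilings, {channel_map.get(k, k): v for k, v in header_ceilings.items()}
    )
    return FlowEventTable(df, resolved)


def _map_channels(df: pd.DataFrame, channel_map: dict[str, str]) -> pd.DataFrame:
    df = df.rename(columns=channel_map)
    missing = [ch for ch in CHANNELS if ch not in df.columns]
    if missing:
        raise ValueError(
            f"required channels {missing} not found; available: {sorted(df.columns)}"
        )
    return df[list(CHANNELS)].astype(float)


def _resolve_ceilings(
    override: dict[str, float] | None, found: dict[str, float]
) -> dict[str, float]:
    out = dict(found)
    if override:
        out.update(override)
    return out


def read_fcs(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
    ceilings: dict[str, float] | None = None,
) -> FlowEventTable:
    """Read a list-mode FCS 3.0/3.1 file into a canonical event table.

    Per-channel saturation ceilings default to ``$PnR`` from the file's
    TEXT segment; pass ``ceilings`` to override.
    """
    path = Path(path)
    raw = path.read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("latin-1")
    delim = text[0]
    parts = text[1:].split(delim)
    kv = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    datatype = kv["$DATATYPE"].strip().upper()
    if kv.get("$MODE", "L").strip().upper() != "L":
        raise ValueError("only list-mode ($MODE L) FCS files are supported")
    byteord = kv.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")

    data_start = int(raw[26:34]) or int(kv.get("$BEGINDATA", 0))
    data_end = int(raw[34:42]) or int(kv.get("$ENDDATA", 0))
    buf = raw[data_start : data_end + 1]

    names = [kv[f"$P{i}N"].strip() for i in range(1, n_par + 1)]
    bits = [int(kv[f"$P{i}B"]) for i in range(1, n_par + 1)]
    order = "<" if little else ">"
    if datatype in ("F", "D"):
        width = 32 if datatype == "F" else 64
        if any(b != width for b in bits):
            raise ValueError(f"$PnB must be {width} for $DATATYPE {datatype}")
        dtype = np.dtype(f"{order}f{width // 8}")
        values = np.frombuffer(buf, dtype=dtype, count=n_par * n_tot)
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise ValueError("only uniform 16- or 32-bit integer data supported")
        dtype = np.dtype(f"{order}u{bits[0] // 8}")
        values = np.frombuffer(buf, dtype=dtype, count=n_par * n_tot).astype(float)
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")
    arr = np.asarray(values, dtype=float).reshape(n_tot, n_par)

    df = pd.DataFrame(arr, columns=names)
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    df = _map_channels(df, channel_map)
    pnr = {
        channel_map.get(name, name): float(kv[f"$P{i}R"])
        for i, name in enumerate(names, start=1)
        if f"$P{i}R" in kv
    }
    resolved = _resolve_ceilings(ceilings, {k: v for k, v in pnr.items() if k in CHANNELS})
    # recorded values may sit exactly at the ceiling; FlowEventTable requires <=
    return FlowEventTable(df, resolved)


def ingest_events(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
    ceilings: dict[str, float] | None = None,
) -> FlowEventTable:
    """Read an event table from CSV or FCS, dispatching on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        return read_fcs(path, channel_map, ceilings)
    return read_events_csv(path, channel_map, ceilings)


def write_field_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a single-channel field as 16-bit TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint16))


def read_field_tiff(path: str | Path) -> np.ndarray:
    """Read a single-channel 8/16-bit TIFF field."""
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    return img
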