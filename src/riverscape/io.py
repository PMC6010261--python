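"""CSV input/output for reach, dam, and biological sample tables.

All tables are UTF-8 CSV with a mandatory header row; the empty string
denotes a missing value.  Unknown reach-table columns are preserved and
exposed as covariates after reading, so upstream-accumulated or modelled
attributes round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MANDATORY_REACH_COLUMNS, StreamNetwork

DAM_COLUMNS = ("dam_id", "reach_id", "storage_m3")
BIOSAMPLE_COLUMNS = ("reach_id", "taxon", "year")


class SchemaError(ValueError):
    """A table is missing mandatory columns or holds unparseable cells."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _parse_floats(raw: pd.Series):
    """Exact (correctly rounded) float parsing; returns (series, bad_mask).

    Python's ``float`` round-trips the shortest-repr decimal strings that
    ``to_csv`` writes, which the pandas fast parser does not guarantee.
    """
    out = np.full(len(raw), np.nan)
    bad = np.zeros(len(raw), dtype=bool)
    for k, v in enumerate(raw.to_numpy()):
        if v is None or (isinstance(v, str) and not v.strip()):
            continue
        try:
            out[k] = float(v)
        except (TypeError, ValueError):
            bad[k] = True
    return pd.Series(out, index=raw.index), bad


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    out, bad = _parse_floats(df[column])
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"{path}: unparseable numeric value {df[column].iloc[pos]!r} "
            f"in column {column!r} (line {pos + 2})"
        )
    return out


def read_reaches(path) -> pd.DataFrame:
    """Read a reach table; numeric mandatory columns are parsed strictly,
    unknown columns are parsed numerically when possible and kept as-is
    otherwise."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, MANDATORY_REACH_COLUMNS, path)
    df = df.replace({"": None})
    for col in ("length_km", "local_area_km2", "slope"):
        df[col] = _numeric(df, col, path)
    df["reach_id"] = df["reach_id"].astype(str)
    df["downstream_id"] = df["downstream_id"].fillna("")
    if "is_impounded" in df.columns:
        df["is_impounded"] = (
            df["is_impounded"].fillna("False").astype(str).str.lower().isin(("true", "1"))
        )
    if "terminus_type" in df.columns:
        df["terminus_type"] = df["terminus_type"].fillna("interior")
    for col in df.columns:
        if col in MANDATORY_REACH_COLUMNS or col in ("terminus_type", "is_impounded"):
            continue
        converted, bad = _parse_floats(df[col])
        if converted.notna().sum() and not bad.any():
            df[col] = converted
    return df


def read_dams(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None})
    _require_columns(df, DAM_COLUMNS, path)
    df["storage_m3"] = _numeric(df, "storage_m3", path)
    df["reach_id"] = df["reach_id"].astype(str)
    return df


def read_biosamples(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None})
    _require_columns(df, BIOSAMPLE_COLUMNS, path)
    df["year"] = _numeric(df, "year", path).astype(int)
    df["reach_id"] = df["reach_id"].astype(str)
    return df


def read_tables(reaches_path, dams_path=None, biosamples_path=None):
    """Read all input tables and assemble a validated :class:`StreamNetwork`.

    Returns ``(network, dams, biosamples)``; the dam and sample tables are
    empty frames when no path is given.
    """
    network = StreamNetwork(read_reaches(reaches_path))
    dams = (
        read_dams(dams_path)
        if dams_path is not None
        else pd.DataFrame(columns=list(DAM_COLUMNS))
    )
    biosamples = (
        read_biosamples(biosamples_path)
        if biosamples_path is not None
        else pd.DataFrame(columns=list(BIOSAMPLE_COLUMNS))
    )
    return network, dams, biosamples


def write_annotations(path, records: pd.DataFrame) -> None:
    """Write per-reach records (classifications, disturbance profiles, ...)
    to CSV with missing values as empty strings."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False, na_rep="")
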