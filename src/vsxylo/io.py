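"""File readers and writers: climate/counts/anatomy CSV, Tucson .rwl,
chronology tables, and metadata-stamped output.

All tabular outputs are plain CSV with a leading ``#``-comment header
carrying the configuration hash and master seed, so any file can be
traced back to the run that produced it; readers skip those comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataError

__all__ = [
    "read_climate",
    "write_climate",
    "read_counts",
    "read_anatomy",
    "read_ring_widths",
    "read_rwl",
    "write_rwl",
    "read_chronology",
    "write_table",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """Write a tidy CSV with ``# key: value`` metadata comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read a climate CSV (``date, temp_c, precip_mm[, swc_vvs]``) into the
    tidy ``year, doy, temp, precip[, swc_obs]`` form.

    Also accepts files already in tidy form.  Violations are reported
    with 1-based data row numbers.
    """
    df = pd.read_csv(path, comment="#")
    if {"year", "doy", "temp", "precip"} <= set(df.columns):
        out = df
    else:
        missing = {"date", "temp_c", "precip_mm"} - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
        bad = np.nonzero(dates.isna().to_numpy())[0]
        if bad.size:
            raise DataError(f"{path}: unparseable date at row {bad[0] + 1}")
        out = pd.DataFrame(
            {
                "year": dates.dt.year,
                "doy": dates.dt.dayofyear,
                "temp": df["temp_c"],
                "precip": df["precip_mm"],
            }
        )
        if "swc_vvs" in df.columns:
            out["swc_obs"] = df["swc_vvs"]
    neg = np.nonzero((out["precip"] < 0).to_numpy())[0]
    if neg.size:
        raise DataError(f"{path}: negative precipitation at row {neg[0] + 1}")
    if "swc_obs" in out.columns:
        swc = out["swc_obs"].dropna()
        if ((swc < 0) | (swc > 1)).any():
            raise DataError(f"{path}: swc_obs outside [0, 1]")
    dup = out.duplicated(["year", "doy"])
    if dup.any():
        raise DataError(
            f"{path}: duplicate (year, doy) at row {int(np.nonzero(dup.to_numpy())[0][0]) + 1}"
        )
    return out


def write_climate(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_table(df, path, meta)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read microcore phase counts
    (``site_id, tree_id, year, doy, n_cambial, n_enlarging, n_wall, n_mature``)."""
    cols = {
        "site_id", "tree_id", "year", "doy",
        "n_cambial", "n_enlarging", "n_wall", "n_mature",
    }
    df = _read_csv(path, cols)
    counts = df[["n_cambial", "n_enlarging", "n_wall", "n_mature"]].to_numpy()
    bad = np.nonzero((counts < 0).any(axis=1))[0]
    if bad.size:
        raise DataError(f"{path}: negative count at row {bad[0] + 1}")
    return df


def read_anatomy(path: str | Path) -> pd.DataFrame:
    """Read tracheidogram measurements
    (``site_id, tree_id, year, file_id, cell_position, diameter_um[, wall_um]``)."""
    cols = {"site_id", "tree_id", "year", "file_id", "cell_position", "diameter_um"}
    df = _read_csv(path, cols)
    bad = np.nonzero((df["diameter_um"] <= 0).to_numpy())[0]
    if bad.size:
        raise DataError(f"{path}: nonpositive diameter at row {bad[0] + 1}")
    return df


def read_ring_widths(path: str | Path) -> dict[str, pd.Series]:
    """Read tidy ring widths (``tree_id, year, width_mm``) into per-tree
    year-indexed series."""
    df = _read_csv(path, {"tree_id", "year", "width_mm"})
    bad = np.nonzero((df["width_mm"] <= 0).to_numpy())[0]
    if bad.size:
        raise DataError(f"{path}: nonpositive width at row {bad[0] + 1}")
    return {
        str(tree): grp.set_index("year")["width_mm"].sort_index()
        for tree, grp in df.groupby("tree_id")
    }


def read_chronology(path: str | Path) -> pd.Series:
    df = _read_csv(path, {"year", "index"})
    return df.set_index("year")["index"]


# ---------------------------------------------------------------------------
# Tucson (decadal) ring-width format.  Each line: series id (cols 1-8),
# decade start year, then up to 10 values; stop marker 999 (units 0.01 mm)
# or -9999 (units 0.001 mm) ends a series.

def write_rwl(series: dict[str, pd.Series], path: str | Path) -> None:
    """Write per-tree ring widths in Tucson decadal format (0.001 mm units,
    -9999 terminator)."""
    with open(path, "w") as fh:
        for tree_id, widths in series.items():
            sid = str(tree_id)[:8]
            years = widths.index.to_numpy(dtype=int)
            first, last = years[0], years[-1]
            year = first
            while year <= last:
                decade_end = (year // 10) * 10 + 9
                row_years = range(year, min(decade_end, last) + 1)
                vals = [int(round(widths.loc[y] * 1000)) for y in row_years]
                if row_years[-1] == last:
                    vals.append(-9999)
                fh.write(
                    f"{sid:<8}{year:>4}" + "".join(f"{v:>6}" for v in vals) + "\n"
                )
                year = decade_end + 1


def read_rwl(path: str | Path) -> dict[str, pd.Series]:
    """Read a Tucson decadal ring-width file (handles both the 0.01 mm /
    999 and 0.001 mm / -9999 conventions)."""
    data: dict[str, dict[int, int]] = {}
    stops: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if len(rest) < 2:
                raise DataError(f"{path}: malformed rwl line: {line!r}")
            year = int(rest[0])
            for k, tok in enumerate(rest[1:]):
                val = int(tok)
                if val in (999, -9999):
                    stops[sid] = val
                    break
                data.setdefault(sid, {})[year + k] = val
    out = {}
    for sid, values in data.items():
        divisor = 100.0 if stops.get(sid) == 999 else 1000.0
        years = sorted(values)
        out[sid] = pd.Series(
            [values[y] / divisor for y in years],
            index=pd.Index(years, name="year"),
            name="width_mm",
        )
    return out
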