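"""Reading, validating and writing peak tables and cluster assignments.

The canonical on-disk format is a delimited text table with a header and
lowercase columns ``mz`` (Thomson), ``rt`` (minutes), ``z`` (charge) plus the
optional columns ``sample``, ``intensity`` and ``peptide``.  TSV is the
default dialect; CSV is accepted.  In memory a peak table is a pandas
DataFrame with those columns and a stable integer index (the row ordinal of
the input), which is how clusters reference their member peaks.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("mz", "rt", "z")
OPTIONAL_COLUMNS = ("sample", "intensity", "peptide")


class PeakTableError(ValueError):
    """A peak table violates the format contract (named column / row)."""


def validate_peaks(peaks: pd.DataFrame, *, reset_index: bool = False) -> pd.DataFrame:
    """Validate a peak table and return a normalized copy.

    Checks the required columns, numeric and finite ``mz``/``rt``,
    ``mz > 0`` and non-negative integer ``z``; errors name the offending
    column or row.  With ``reset_index=True`` the row ordinal 0..n-1
    becomes the index (done once at read time).
    """
    if not isinstance(peaks, pd.DataFrame):
        raise PeakTableError("peak table must be a pandas DataFrame")
    for col in REQUIRED_COLUMNS:
        if col not in peaks.columns:
            raise PeakTableError(f"missing required column {col!r}")
    out = peaks.copy()
    if reset_index:
        out = out.reset_index(drop=True)
    if not out.index.is_unique:
        raise PeakTableError("peak table index (row_index) must be unique")
    for col in ("mz", "rt"):
        values = pd.to_numeric(out[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            row = out.index[bad][0]
            raise PeakTableError(f"non-numeric or non-finite {col!r} at row {row}")
        out[col] = values.astype(float)
    nonpos = out["mz"] <= 0
    if nonpos.any():
        row = out.index[nonpos][0]
        raise PeakTableError(f"non-positive mz at row {row}")
    zvals = pd.to_numeric(out["z"], errors="coerce")
    bad = zvals.isna() | (zvals % 1 != 0) | (zvals < 0)
    if bad.any():
        row = out.index[bad][0]
        raise PeakTableError(f"charge z must be a non-negative integer at row {row}")
    out["z"] = zvals.astype(int)
    return out


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is None:
        return "," if str(path).lower().endswith(".csv") else "\t"
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")


def read_peaks(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Read and validate a delimited peak table (TSV default, CSV accepted)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    df.columns = [str(c).strip().lower() for c in df.columns]
    return validate_peaks(df, reset_index=True)


def write_peaks(peaks: pd.DataFrame, path: str, dialect: str | None = None) -> None:
    """Write a peak table with full round-trip floating-point precision."""
    peaks.to_csv(path, sep=_sep_for(path, dialect), index=False,
                 float_format="%.17g")


def cluster_table(clusters: Iterable, peaks: pd.DataFrame) -> pd.DataFrame:
    """One row per cluster: id, z, center, size and per-coordinate diameters."""
    rows = []
    for c in clusters:
        mz = peaks.loc[c.members, "mz"].to_numpy()
        rt = peaks.loc[c.members, "rt"].to_numpy()
        rows.append({
            "cluster_id": c.id, "z": c.z,
            "center_mz": c.center_mz, "center_rt": c.center_rt,
            "size": len(c.members),
            "diameter_mz": float(mz.max() - mz.min()) if len(mz) else 0.0,
            "diameter_rt": float(rt.max() - rt.min()) if len(rt) else 0.0,
        })
    return pd.DataFrame(rows, columns=["cluster_id", "z", "center_mz",
                                       "center_rt", "size", "diameter_mz",
                                       "diameter_rt"])


def assignment_table(clusters: Iterable, peaks: pd.DataFrame) -> pd.DataFrame:
    """The peak table with a ``cluster_id`` column appended (-1 = unassigned)."""
    out = peaks.copy()
    labels = pd.Series(-1, index=out.index, dtype=int)
    for c in clusters:
        labels.loc[c.members] = c.id
    out["cluster_id"] = labels
    return out


def write_clusters(clusters: Iterable, peaks: pd.DataFrame, outdir: str,
                   dialect: str | None = "tsv") -> dict[str, str]:
    """Write the per-peak assignment file and the per-cluster summary file.

    Returns the paths written, keyed by ``"assignments"`` and ``"clusters"``.
    """
    os.makedirs(outdir, exist_ok=True)
    ext = "csv" if dialect == "csv" else "tsv"
    clusters = list(clusters)
    paths = {
        "assignments": os.path.join(outdir, f"assignments.{ext}"),
        "clusters": os.path.join(outdir, f"clusters.{ext}"),
    }
    write_peaks(assignment_table(clusters, peaks), paths["assignments"], dialect)
    write_peaks(cluster_table(clusters, peaks), paths["clusters"], dialect)
    return paths
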