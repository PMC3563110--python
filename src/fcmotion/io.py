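"""Readers and writers for the on-disk artifacts of the pipeline.

Everything the pipeline touches on disk is plain text: realignment
parameter files (SPM ``rp_*.txt`` / FSL ``.par`` / AFNI ``.1D`` dialects),
ROI tables (TSV), ROI-by-time series matrices (CSV/TSV), temporal censor
masks (one 0/1 per line, 1 = keep), and phenotype tables (CSV).

Conventions fixed here and used everywhere downstream:

* rotations are stored canonically in **radians** (AFNI degrees converted
  on read) so the 50 mm arc-length conversion of framewise displacement
  is a plain multiplication;
* ROI file order is the single canonical ROI ordering; edges are indexed
  by the row-major upper triangle of the R x R matrix;
* frame indices are 0-based internally, file line numbers in error
  messages are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RealignmentSeries",
    "RoiSet",
    "CensorMask",
    "DIAGNOSES",
    "DIALECTS",
    "read_realignment",
    "write_realignment",
    "read_roi_table",
    "write_roi_table",
    "read_timeseries",
    "write_timeseries",
    "read_censor_mask",
    "write_censor_mask",
    "read_phenotype",
    "write_phenotype",
]

DIAGNOSES = ("TDC", "ADHD-I", "ADHD-C")

#: Supported realignment-parameter text dialects.
#:
#: generic / spm : columns = [tx ty tz rx ry rz], rotations in radians
#: fsl           : columns = [rx ry rz tx ty tz], rotations in radians
#: afni          : columns = [tx ty tz rx ry rz], rotations in degrees
DIALECTS = ("generic", "spm", "fsl", "afni")


class FormatError(ValueError):
    """A file does not conform to its declared text format."""


@dataclass
class RealignmentSeries:
    """Per-frame rigid-body realignment parameters for one BOLD run.

    ``params`` has shape (T, 6) in canonical order: translations x, y, z
    in mm, then rotations alpha, beta, gamma in radians.
    """

    params: np.ndarray
    tr_seconds: float = 2.5
    dialect: str = "generic"
    run_id: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"realignment parameters must be (n_frames, 6), got {self.params.shape}"
            )
        if not np.all(np.isfinite(self.params)):
            raise ValueError("realignment parameters contain non-finite values")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class RoiSet:
    """An ordered set of regions of interest with network labels.

    The table row order is the canonical ROI ordering used for every
    downstream edge index.  Columns: ``id``, ``x``, ``y``, ``z`` (mm,
    Talairach-like space), ``network``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "x", "y", "z", "network"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"ROI table missing columns: {missing}")
        ids = self.table["id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate ROI ids: {dupes}")
        coords = self.table[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("ROI coordinates must be finite")
        if (self.table["network"].astype(str).str.len() == 0).any():
            raise ValueError("empty network label in ROI table")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].astype(str).tolist()

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].astype(str).to_numpy()


@dataclass
class CensorMask:
    """Boolean per-frame retention mask (True = frame kept)."""

    keep: np.ndarray
    source_metric: str = "none"
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        keep = np.asarray(self.keep)
        if keep.dtype != bool:
            vals = np.unique(keep)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("censor mask values must be 0/1")
            keep = keep.astype(bool)
        self.keep = keep
        if self.source_metric not in ("fd", "dvars", "none"):
            raise ValueError(f"unknown source_metric {self.source_metric!r}")

    @property
    def n_frames(self) -> int:
        return self.keep.size

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def fraction_removed(self) -> float:
        return float(1.0 - self.keep.mean())


# ---------------------------------------------------------------------------
# realignment parameters
# ---------------------------------------------------------------------------

def _parse_numeric_table(path, n_cols: int | None = None) -> np.ndarray:
    """Parse a whitespace- or comma-delimited numeric text file.

    Reports malformed content with 1-based line numbers.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.replace(",", " ").split()
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value on line {lineno}") from exc
            if n_cols is not None and len(values) != n_cols:
                raise FormatError(
                    f"{path}: expected {n_cols} columns on line {lineno}, got {len(values)}"
                )
            if rows and len(values) != len(rows[0]):
                raise FormatError(
                    f"{path}: inconsistent column count on line {lineno}"
                )
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: no numeric rows")
    return np.asarray(rows, dtype=float)


def _to_canonical(raw: np.ndarray, dialect: str) -> np.ndarray:
    if dialect in ("generic", "spm"):
        return raw.copy()
    if dialect == "fsl":  # rotations (radians) first
        return np.hstack([raw[:, 3:6], raw[:, 0:3]])
    if dialect == "afni":  # translations first, rotations in degrees
        out = raw.copy()
        out[:, 3:] = np.deg2rad(out[:, 3:])
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def _from_canonical(params: np.ndarray, dialect: str) -> np.ndarray:
    if dialect in ("generic", "spm"):
        return params.copy()
    if dialect == "fsl":
        return np.hstack([params[:, 3:6], params[:, 0:3]])
    if dialect == "afni":
        out = params.copy()
        out[:, 3:] = np.rad2deg(out[:, 3:])
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def read_realignment(path, dialect: str = "generic", tr_seconds: float = 2.5,
                     run_id: str = "") -> RealignmentSeries:
    """Read a 6-column rigid-body realignment parameter file.

    The dialect must be declared by the caller; it is never sniffed from
    the file contents (column order and rotation units are ambiguous
    between packages).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    raw = _parse_numeric_table(path, n_cols=6)
    return RealignmentSeries(
        params=_to_canonical(raw, dialect),
        tr_seconds=tr_seconds,
        dialect=dialect,
        run_id=run_id or str(path),
    )


def write_realignment(path, series: RealignmentSeries, dialect: str | None = None) -> None:
    """Write realignment parameters in the requested text dialect."""
    dialect = dialect or series.dialect
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    np.savetxt(path, _from_canonical(series.params, dialect), fmt="%.10g")


# ---------------------------------------------------------------------------
# ROI tables
# ---------------------------------------------------------------------------

def read_roi_table(path) -> RoiSet:
    """Read a TSV ROI table with header ``id  x  y  z  network``."""
    table = pd.read_csv(path, sep="\t")
    if table[["x", "y", "z"]].isna().any().any():
        bad = table.index[table[["x", "y", "z"]].isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing coordinate(s) in rows {bad}")
    return RoiSet(table=table)


def write_roi_table(path, rois: RoiSet) -> None:
    rois.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def read_timeseries(path, n_rois: int | None = None) -> np.ndarray:
    """Read an ROI-by-time numeric matrix.

    Files are ROI x time by default.  A leading comment line
    ``# orientation: time_by_rois`` marks transposed storage; the returned
    array is always ROI x time.  When ``n_rois`` is given the row count is
    checked against it.
    """
    orientation = "rois_by_time"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "orientation:" in first:
        orientation = first.split("orientation:")[1].strip()
    mat = _parse_numeric_table(path)
    if orientation == "time_by_rois":
        mat = mat.T
    elif orientation != "rois_by_time":
        raise FormatError(f"{path}: unknown orientation {orientation!r}")
    if n_rois is not None and mat.shape[0] != n_rois:
        raise ValueError(
            f"{path}: {mat.shape[0]} ROI rows do not match the {n_rois}-ROI set"
        )
    return mat


def write_timeseries(path, ts: np.ndarray, orientation: str = "rois_by_time") -> None:
    ts = np.asarray(ts, dtype=float)
    if orientation == "time_by_rois":
        out = ts.T
    elif orientation == "rois_by_time":
        out = ts
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    header = f" orientation: {orientation}"
    np.savetxt(path, out, fmt="%.10g", header=header)


# ---------------------------------------------------------------------------
# censor masks
# ---------------------------------------------------------------------------

def read_censor_mask(path, source_metric: str = "none",
                     threshold: float = float("nan")) -> CensorMask:
    """Read a one-value-per-line 0/1 temporal mask (1 = keep)."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped not in ("0", "1"):
                raise FormatError(
                    f"{path}: line {lineno}: mask value must be 0 or 1, got {stripped!r}"
                )
            values.append(int(stripped))
    return CensorMask(keep=np.asarray(values, dtype=bool),
                      source_metric=source_metric, threshold=threshold)


def write_censor_mask(path, mask: CensorMask) -> None:
    with open(path, "w") as fh:
        for v in mask.keep:
            fh.write(f"{int(v)}\n")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["subject_id", "age", "diagnosis", "site", "sex", "iq"]


def read_phenotype(path) -> pd.DataFrame:
    """Read a phenotype CSV into a validated cohort table.

    Required columns: subject_id, age, diagnosis, site, sex, iq.  Optional
    motion summaries (mean_fd_pre, mean_fd_post) are carried through.
    Missing IQ is permitted and flagged in a boolean ``iq_missing`` column.
    """
    table = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {missing}")
    ids = table["subject_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    if (table["age"] <= 0).any():
        raise ValueError(f"{path}: non-positive ages")
    bad_dx = sorted(set(table["diagnosis"].astype(str)) - set(DIAGNOSES))
    if bad_dx:
        raise ValueError(
            f"{path}: unknown diagnosis value(s) {bad_dx}; expected one of {DIAGNOSES}"
        )
    table = table.copy()
    table["iq_missing"] = table["iq"].isna()
    return table


def write_phenotype(path, table: pd.DataFrame) -> None:
    table.drop(columns=[c for c in ("iq_missing",) if c in table.columns]).to_csv(
        path, index=False
    )
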