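"""Reading, writing and basic preparation of parcel timeseries data.

A subject's resting-state recording is an ``N x p`` matrix: one row per time
point, one column per brain parcel.  Everything downstream (covariance
regression, scatter-matrix regression) assumes the columns have been
mean-centered, so centering lives here, next to the readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeseriesMatrix",
    "DesignMatrix",
    "ScatterMatrix",
    "TimeseriesFormatError",
    "read_timeseries",
    "write_timeseries",
    "read_subjects",
    "center_columns",
    "scatter_matrix",
    "build_design",
    "write_scatter",
    "read_scatter",
]


class TimeseriesFormatError(ValueError):
    """Raised for ragged, non-numeric, empty or otherwise malformed input."""


@dataclass(frozen=True)
class TimeseriesMatrix:
    """One subject's ``N x p`` parcel timeseries (rows = time points).

    Parameters
    ----------
    values
        Real matrix with ``N >= 1`` rows and ``p >= 1`` columns, no missing
        entries (readers require ``N >= 2``; a single row can only arise
        from extreme thinning).  Units are arbitrary signal units.
    parcel_labels
        ``p`` display names; defaults to ``R1..Rp``.
    subject_id
        Identifier carried through scatter matrices and reports.
    """

    values: np.ndarray
    parcel_labels: tuple[str, ...] = ()
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise TimeseriesFormatError("timeseries must be a 2-D matrix")
        n, p = values.shape
        if n < 1:
            raise TimeseriesFormatError("timeseries has no rows")
        if p < 1:
            raise TimeseriesFormatError("need at least one parcel column")
        if not np.all(np.isfinite(values)):
            raise TimeseriesFormatError("timeseries contains non-finite entries")
        labels = tuple(self.parcel_labels) or tuple(f"R{j + 1}" for j in range(p))
        if len(labels) != p:
            raise TimeseriesFormatError(
                f"{len(labels)} parcel labels for {p} columns"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "parcel_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DesignMatrix:
    """``n x J`` design matrix with an intercept column first."""

    values: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] < 1:
            raise ValueError("design matrix must be 2-D with J >= 1 columns")
        if not np.allclose(values[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        if len(self.column_names) != values.shape[1]:
            raise ValueError("column_names length mismatch")
        if np.linalg.matrix_rank(values) < values.shape[1]:
            raise ValueError("design matrix is rank deficient")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "column_names", tuple(self.column_names))

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScatterMatrix:
    """``p x p`` scatter matrix ``S = Y^T Y`` of a centered timeseries.

    ``S`` is ``N`` times the sample covariance; the raw (undivided) form is
    what the Wishart regression treats as its observed response.
    """

    values: np.ndarray
    n_timepoints: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("scatter matrix must be square")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("scatter matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(values)
        largest = max(eigvals[-1], 1.0)
        if eigvals[0] < -1e-8 * largest:
            raise ValueError("scatter matrix is not positive semidefinite")
        object.__setattr__(self, "values", values)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


def _looks_like_header(fields: list[str]) -> bool:
    for cell in fields:
        try:
            float(cell)
        except ValueError:
            return True
    return False


def read_timeseries(
    path: str | Path, delimiter: str = ",", subject_id: str | None = None
) -> TimeseriesMatrix:
    """Read a delimited-text timeseries (optional single header row).

    Comma is the default dialect; tab is accepted via ``delimiter``.
    Raises :class:`TimeseriesFormatError` on ragged rows, non-numeric cells
    or an empty file.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise TimeseriesFormatError(f"{path}: empty file")
    fields = [c.strip() for c in first.rstrip("\n").split(delimiter)]
    header = 0 if _looks_like_header(fields) else None
    try:
        frame = pd.read_csv(path, sep=delimiter, header=header)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TimeseriesFormatError(f"{path}: {exc}") from exc
    if frame.isna().to_numpy().any():
        raise TimeseriesFormatError(f"{path}: missing or ragged entries")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TimeseriesFormatError(f"{path}: non-numeric cell in data rows")
    if values.shape[0] < 2:
        raise TimeseriesFormatError(f"{path}: need at least 2 time points")
    labels = tuple(str(c) for c in frame.columns) if header == 0 else ()
    return TimeseriesMatrix(
        values=values, parcel_labels=labels, subject_id=subject_id or path.stem
    )


def write_timeseries(
    ts: TimeseriesMatrix, path: str | Path, delimiter: str = ","
) -> None:
    """Write a timeseries as delimited text with a parcel-label header row."""
    frame = pd.DataFrame(ts.values, columns=list(ts.parcel_labels))
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read the subjects table CSV (columns subject_id, group, path)."""
    table = pd.read_csv(path, dtype={"subject_id": str, "group": str, "path": str})
    missing = {"subject_id", "group", "path"} - set(table.columns)
    if missing:
        raise ValueError(f"subjects table missing columns: {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        raise ValueError("subject_id values must be unique")
    return table


def center_columns(ts: TimeseriesMatrix) -> TimeseriesMatrix:
    """Subtract each column's mean; idempotent, shape preserving."""
    centered = ts.values - ts.values.mean(axis=0, keepdims=True)
    return replace(ts, values=centered)


def scatter_matrix(ts: TimeseriesMatrix, scale_by_n: bool = False) -> ScatterMatrix:
    """Form ``S = Y^T Y`` from the (defensively re-centered) timeseries.

    ``scale_by_n=True`` divides by ``N`` for numerical conditioning; the raw
    scatter is the default and is what the Wishart model expects.  ``p > N``
    merely yields a rank-deficient (still PSD) matrix.
    """
    centered = center_columns(ts)
    s = centered.values.T @ centered.values
    s = 0.5 * (s + s.T)  # exact symmetry against float noise
    if scale_by_n:
        s = s / ts.n_timepoints
    return ScatterMatrix(values=s, n_timepoints=ts.n_timepoints, subject_id=ts.subject_id)


def build_design(subjects: pd.DataFrame, reference_group: str) -> DesignMatrix:
    """Dummy-code groups into a design matrix with the reference omitted.

    Column one is the intercept.  With two groups this reduces to a single
    0/1 contrast column that is 1 for the non-reference group.
    """
    groups = subjects["group"].astype(str)
    levels = list(dict.fromkeys(groups))  # order of first appearance
    if reference_group not in levels:
        raise ValueError(f"reference group {reference_group!r} not present")
    others = [g for g in levels if g != reference_group]
    n = len(subjects)
    values = np.ones((n, 1 + len(others)))
    names = ["intercept"]
    for j, level in enumerate(others, start=1):
        values[:, j] = (groups == level).to_numpy(dtype=float)
        names.append(f"group[{level}]")
    return DesignMatrix(values=values, column_names=tuple(names))


def write_scatter(scatter: ScatterMatrix, path: str | Path) -> None:
    """Write ``p x p`` CSV plus a ``.json`` sidecar with subject_id and N."""
    path = Path(path)
    np.savetxt(path, scatter.values, delimiter=",", fmt="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"subject_id": scatter.subject_id, "n_timepoints": scatter.n_timepoints}
        )
    )


def read_scatter(path: str | Path) -> ScatterMatrix:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ScatterMatrix(
        values=values,
        n_timepoints=int(meta["n_timepoints"]),
        subject_id=str(meta.get("subject_id", "")),
    )
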