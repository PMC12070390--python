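"""Empirical quantile functions of single-cell signal intensities.

Cell-level tables hold one row per segmented cell with a cellular signal
intensity (CSI).  For each tissue (subject) the empirical quantile function
``Q_n(p)`` is tabulated on a common probability grid; the resulting
subject-by-probability matrix is the functional predictor used by all
quantile-index biomarkers.  Quantile functions from multiple regions of
interest (ROIs) of one tissue can be aggregated pointwise before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProbabilityGrid",
    "QuantileMatrix",
    "empirical_quantile",
    "tabulate_quantiles",
    "aggregate_roi",
    "read_cell_table",
]

#: columns a cell table may carry; subject_id and csi are mandatory
CELL_COLUMNS = ("subject_id", "roi_id", "csi", "x", "y")

ROI_METHODS = ("min", "median", "mean", "max")


@dataclass(frozen=True)
class ProbabilityGrid:
    """Strictly increasing probabilities in (0, 1) with integration weights.

    The weights define the discrete measure used for every quadrature
    ``∫ f(p) dp ≈ Σ_p w_p f(p)``.  On an equally spaced grid the uniform
    weights ``1/P`` give the Riemann-sum approximation.
    """

    probabilities: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probability grid must be a non-empty 1-d array")
        if not (np.all(p > 0.0) and np.all(p < 1.0)):
            raise ValueError("probabilities must lie strictly inside (0, 1)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("probabilities must be strictly increasing")
        w = self.weights
        if w is None:
            w = np.full(p.size, 1.0 / p.size)
        else:
            w = np.asarray(w, dtype=float)
            if w.shape != p.shape:
                raise ValueError("weights must match probabilities in shape")
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            if abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("weights must sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return int(self.probabilities.size)

    @classmethod
    def default(cls, n: int = 19) -> "ProbabilityGrid":
        """Equally spaced grid ``1/(n+1), …, n/(n+1)`` with uniform weights.

        ``n=19`` gives the recommended 0.05…0.95 step-0.05 grid; ``n=99``
        gives the fine 0.01…0.99 step-0.01 grid.
        """
        p = np.arange(1, n + 1, dtype=float) / (n + 1)
        return cls(p)

    @classmethod
    def from_probabilities(cls, probabilities) -> "ProbabilityGrid":
        return cls(np.asarray(probabilities, dtype=float))

    def trimmed(self, n_drop: int) -> "ProbabilityGrid":
        """Drop ``n_drop`` grid points from each tail (robustness option)."""
        if n_drop < 0 or 2 * n_drop >= len(self):
            raise ValueError("n_drop must satisfy 0 <= 2*n_drop < grid size")
        if n_drop == 0:
            return self
        p = self.probabilities[n_drop:-n_drop]
        return ProbabilityGrid(p)

    def column_labels(self) -> list[str]:
        return [f"p_{p:g}" for p in self.probabilities]

    def isclose(self, other: "ProbabilityGrid") -> bool:
        return len(self) == len(other) and np.allclose(
            self.probabilities, other.probabilities
        ) and np.allclose(self.weights, other.weights)


@dataclass
class QuantileMatrix:
    """Tabulated quantile functions: one non-decreasing row per subject."""

    subject_ids: list
    grid: ProbabilityGrid
    values: np.ndarray
    scale_tag: str = "log"  # {"raw", "log"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if self.values.shape != (len(self.subject_ids), len(self.grid)):
            raise ValueError("values shape must be (n_subjects, grid size)")
        if self.scale_tag not in ("raw", "log"):
            raise ValueError("scale_tag must be 'raw' or 'log'")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def row(self, subject_id) -> np.ndarray:
        return self.values[list(self.subject_ids).index(subject_id)]

    def median_column(self) -> np.ndarray:
        """Per-subject quantile at the grid probability nearest 0.5."""
        j = int(np.argmin(np.abs(self.grid.probabilities - 0.5)))
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.grid.column_labels())
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_tag: str = "log") -> "QuantileMatrix":
        if "subject_id" not in df.columns:
            raise ValueError("quantile table must have a 'subject_id' column")
        pcols = [c for c in df.columns if c.startswith("p_")]
        if not pcols:
            raise ValueError("quantile table must have 'p_<prob>' columns")
        probs = np.array([float(c[2:]) for c in pcols])
        order = np.argsort(probs)
        pcols = [pcols[i] for i in order]
        grid = ProbabilityGrid(probs[order])
        return cls(
            subject_ids=list(df["subject_id"]),
            grid=grid,
            values=df[pcols].to_numpy(dtype=float),
            scale_tag=scale_tag,
        )

    @classmethod
    def read_csv(cls, path, scale_tag: str = "log") -> "QuantileMatrix":
        return cls.from_frame(pd.read_csv(path), scale_tag=scale_tag)


def empirical_quantile(sample, p: float) -> float:
    """k-th order statistic with ``k = ⌈n·p⌉`` (left-continuous inverse CDF).

    Parameters
    ----------
    sample : array-like
        Non-empty finite sample.
    p : float
        Probability strictly inside (0, 1).
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("no observations")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    return float(_tabulate_one(np.sort(x), np.array([p]))[0])


def _tabulate_one(sorted_sample: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Vectorised type-1 quantiles of an already-sorted sample."""
    n = sorted_sample.size
    # 1e-9 slack guards boundaries p = k/n against binary floating-point fuzz
    k = np.ceil(n * probs - 1e-9).astype(int)
    k = np.clip(k, 1, n)
    return sorted_sample[k - 1]


def read_cell_table(path) -> pd.DataFrame:
    """Read a headered delimited cell table (CSV/TSV sniffed by pandas)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return validate_cell_table(df)


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject_id", "csi"):
        if col not in df.columns:
            raise ValueError(f"cell table is missing required column '{col}'")
    if df["csi"].isna().any():
        bad = df.index[df["csi"].isna()][0]
        raise ValueError(f"malformed csi value at row {bad + 1}")
    return df


def tabulate_quantiles(
    cells: pd.DataFrame,
    grid: ProbabilityGrid | None = None,
    log_transform: bool = True,
    roi_method: str | None = None,
) -> QuantileMatrix:
    """Tabulate one empirical quantile function per subject.

    Parameters
    ----------
    cells : DataFrame
        Columns ``subject_id``, ``csi`` and optionally ``roi_id``.  CSIs are
        log-transformed by default (intensity distributions are right-skewed).
    grid : ProbabilityGrid, optional
        Defaults to the 19-point 0.05…0.95 grid.
    log_transform : bool
        Apply ``log`` to CSIs; requires all CSIs positive.
    roi_method : {"min", "median", "mean", "max"}, optional
        If ``roi_id`` is present, ROI-level quantile functions are aggregated
        pointwise to tissue level with this method (default "mean").

    Returns
    -------
    QuantileMatrix
        Rows ordered by first appearance of each subject; every row is
        non-decreasing.
    """
    cells = validate_cell_table(cells)
    if grid is None:
        grid = ProbabilityGrid.default()
    csi = cells["csi"].to_numpy(dtype=float)
    if log_transform:
        if np.any(csi <= 0):
            offender = cells.loc[csi <= 0, "subject_id"].iloc[0]
            raise ValueError(
                f"non-positive csi for subject '{offender}'; "
                "log transform requires csi > 0"
            )
        vals = np.log(csi)
        tag = "log"
    else:
        vals = csi
        tag = "raw"

    work = pd.DataFrame({"subject_id": cells["subject_id"].to_numpy(), "_v": vals})
    has_roi = "roi_id" in cells.columns and cells["roi_id"].notna().any()
    if has_roi:
        if roi_method is None:
            roi_method = "mean"
        work["roi_id"] = cells["roi_id"].to_numpy()

    probs = grid.probabilities
    subject_ids = []
    rows_list = []
    for sid, sub in work.groupby("subject_id", sort=False):
        subject_ids.append(sid)
        if has_roi:
            roi_rows = [
                _tabulate_one(np.sort(g["_v"].to_numpy()), probs)
                for _, g in sub.groupby("roi_id", sort=False)
            ]
            rows_list.append(aggregate_roi(np.vstack(roi_rows), roi_method))
        else:
            rows_list.append(_tabulate_one(np.sort(sub["_v"].to_numpy()), probs))
    rows = np.vstack(rows_list)
    return QuantileMatrix(subject_ids=subject_ids, grid=grid, values=rows, scale_tag=tag)


def aggregate_roi(rows: np.ndarray, method: str = "mean") -> np.ndarray:
    """Pointwise aggregate of ROI-level quantile-function rows.

    ``rows`` is an (n_roi, P) array on a shared grid; the aggregate of
    non-decreasing rows is again non-decreasing for all four methods.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] < 1:
        raise ValueError("at least one ROI row is required")
    if method not in ROI_METHODS:
        raise ValueError(f"method must be one of {ROI_METHODS}")
    fn = {"min": np.min, "median": np.median, "mean": np.mean, "max": np.max}[method]
    return fn(rows, axis=0)


def subset(Q: QuantileMatrix, subject_ids) -> QuantileMatrix:
    """Rows of ``Q`` for the given subjects, in the given order."""
    index = {s: i for i, s in enumerate(Q.subject_ids)}
    missing = [s for s in subject_ids if s not in index]
    if missing:
        raise ValueError(f"subjects not in quantile matrix: {missing[:5]}")
    idx = [index[s] for s in subject_ids]
    return replace(Q, subject_ids=list(subject_ids), values=Q.values[idx])
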