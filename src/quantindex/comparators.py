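"""Non-spatial comparator biomarkers: MSI and the optimal quantile (OQ).

MSI (mean signal intensity) is the conventional quantitative-pathology
biomarker — the per-tissue average CSI.  The OQ biomarker uses the single
grid quantile whose (standardized) value is most strongly associated with
the training outcome in a univariable model; the selected probability is
frozen before test application.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .index import BiomarkerVector
from .models import BinaryOutcome, SurvivalOutcome, fit_unpenalized
from .quantiles import QuantileMatrix, validate_cell_table

__all__ = ["OQSelection", "msi", "oq_train", "oq_apply"]


def msi(cells: pd.DataFrame, log_scale: bool = True) -> BiomarkerVector:
    """Per-subject arithmetic mean of (optionally log) CSI."""
    cells = validate_cell_table(cells)
    csi = cells["csi"].to_numpy(dtype=float)
    if log_scale:
        if np.any(csi <= 0):
            offender = cells.loc[csi <= 0, "subject_id"].iloc[0]
            raise ValueError(
                f"non-positive csi for subject '{offender}'; "
                "log scale requires csi > 0"
            )
        vals = np.log(csi)
    else:
        vals = csi
    means = (
        pd.Series(vals)
        .groupby(cells["subject_id"].to_numpy(), sort=False)
        .mean()
    )
    return BiomarkerVector(list(means.index), means.to_numpy(), name="MSI")


@dataclass
class OQSelection:
    """Frozen choice of the most outcome-predictive grid quantile."""

    selected_p: float
    outcome_family: str
    trace: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def oq_train(
    Q_train: QuantileMatrix,
    outcome: BinaryOutcome | SurvivalOutcome,
    outcome_family: str | None = None,
) -> OQSelection:
    """Select the grid probability with the largest absolute Wald z.

    Each grid column is z-scored and fitted as the single covariate of an
    unpenalized logistic or Cox model; ties in |z| break toward the smaller
    probability.  Non-converged columns are skipped with a warning.
    """
    probs = Q_train.grid.probabilities
    if probs.size < 2:
        raise ValueError("OQ selection needs a grid with >= 2 probabilities")
    if outcome_family is None:
        outcome_family = "cox" if isinstance(outcome, SurvivalOutcome) else "binomial"
    rows = []
    for j, p in enumerate(probs):
        col = Q_train.values[:, j]
        sd = col.std()
        if sd == 0:
            rows.append({"p": p, "z": 0.0, "p_value": 1.0, "converged": False})
            continue
        x = (col - col.mean()) / sd
        target = outcome if outcome_family == "cox" else outcome
        try:
            summ = fit_unpenalized(x[:, None], target, family=outcome_family)
        except Exception as exc:  # singular / degenerate column fits
            warnings.warn(f"OQ column p={p:g} fit failed: {exc}", stacklevel=2)
            rows.append({"p": p, "z": np.nan, "p_value": np.nan, "converged": False})
            continue
        row = summ.iloc[0]
        conv = bool(row["converged"]) and np.isfinite(row["z"])
        if not conv:
            warnings.warn(f"OQ column p={p:g} did not converge; skipped", stacklevel=2)
        rows.append({
            "p": p, "z": float(row["z"]), "p_value": float(row["p_value"]),
            "converged": conv,
        })
    trace = pd.DataFrame(rows)
    ok = trace[trace["converged"]]
    if ok.empty:
        raise RuntimeError("no OQ candidate quantile produced a converged fit")
    # max |z|; ties toward smaller p (stable idxmax on the first occurrence)
    best = ok.loc[ok["z"].abs().round(12).idxmax()]
    return OQSelection(
        selected_p=float(best["p"]), outcome_family=outcome_family, trace=trace
    )


def oq_apply(selection: OQSelection, Q: QuantileMatrix) -> BiomarkerVector:
    """Per-subject quantile value at the selected probability."""
    probs = Q.grid.probabilities
    j = np.flatnonzero(np.isclose(probs, selection.selected_p))
    if j.size == 0:
        raise ValueError(
            f"selected probability {selection.selected_p:g} is not on the grid"
        )
    return BiomarkerVector(
        list(Q.subject_ids), Q.values[:, int(j[0])], name="OQ"
    )
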