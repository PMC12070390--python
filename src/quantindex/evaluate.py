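"""Biomarker scoring and the simulation benchmark harness.

Biomarkers are scored by the Mann–Whitney estimate of the AUC-ROC for
predicting high-risk group membership on held-out subjects, and by
univariable / covariate-adjusted association models mirroring how a derived
index would be reported for a clinical cohort.  ``run_benchmark`` sweeps
scenarios × study sizes × grids × outcome kinds over independent replicate
train/test pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import comparators
from .index import IndexConfig, compute_index, train_index_model
from .models import BinaryOutcome, SurvivalOutcome, fit_unpenalized
from .quantiles import ProbabilityGrid, tabulate_quantiles
from .simulate import ScenarioSpec, SimulatedStudy, generate_pair, scenario_spec

__all__ = [
    "BenchmarkConfig",
    "auc_mann_whitney",
    "evaluate_replicate",
    "run_benchmark",
    "summarize_benchmark",
    "association_report",
]

BIOMARKERS = ("QI", "nlQI", "MSI", "OQ")


def auc_mann_whitney(scores, labels) -> float:
    """Pairwise U-statistic AUC with 0.5 credit for ties.

    ``labels`` are 0/1 with 1 the positive (high-risk) class; the result is
    the probability that a random positive outscores a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    ranks = rankdata(scores)  # midranks give the tie credit
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class BenchmarkConfig:
    """Sweep definition for the scenario benchmark."""

    scenarios: tuple = ("A", "B", "C", "D")
    n_subjects: tuple = (120,)
    n_cells: tuple = (100,)
    grid_sizes: tuple = (19,)
    outcome_kinds: tuple = ("binary", "survival")
    n_replicates: int = 200
    master_seed: int = 0
    index_config: IndexConfig = field(default_factory=IndexConfig)


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-replicate integer seeds derived from one master seed."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def _oriented_test_auc(train_vals, train_labels, test_vals, test_labels):
    """Test AUC with the score direction fixed on the training half.

    The direction making the training AUC ≥ 0.5 is applied to the test
    scores, so a biomarker that decreases with risk is still scored fairly
    while a null biomarker keeps an unbiased test AUC around 0.5.
    """
    auc_tr = auc_mann_whitney(train_vals, train_labels)
    direction = 1 if auc_tr >= 0.5 else -1
    auc_te = auc_mann_whitney(test_vals, test_labels)
    return auc_te if direction == 1 else 1.0 - auc_te, direction


def evaluate_replicate(
    study: SimulatedStudy,
    grid_size: int = 19,
    index_config: IndexConfig | None = None,
) -> pd.DataFrame:
    """Train all biomarkers on the training half, score AUC on the test half.

    Returns one row per biomarker with the oriented test AUC; model failures
    are recorded as missing AUC with the reason, never silently dropped.
    """
    if index_config is None:
        index_config = IndexConfig()
    grid = ProbabilityGrid.default(grid_size)
    train, test = study.train, study.test
    lab_tr = (train.groups == "high").astype(int).to_numpy()
    lab_te = (test.groups == "high").astype(int).to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Q_tr = tabulate_quantiles(train.cells, grid)
        Q_te = tabulate_quantiles(test.cells, grid)

    rows = []

    def record(name, tr_vals, te_vals, note=""):
        auc, direction = _oriented_test_auc(tr_vals, lab_tr, te_vals, lab_te)
        rows.append({"biomarker": name, "auc": auc, "direction": direction,
                     "note": note})

    for name, kind in (("QI", "linear_QI"), ("nlQI", "nonlinear_nlQI")):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = train_index_model(
                    Q_tr, train.outcome, kind=kind, config=index_config
                )
                tr_vals = compute_index(model, Q_tr).values
                te_vals = compute_index(model, Q_te).values
            record(name, tr_vals, te_vals,
                   "" if model.metadata.get("converged", True) else "non-converged")
        except Exception as exc:
            rows.append({"biomarker": name, "auc": np.nan, "direction": 0,
                         "note": f"failed: {exc}"})

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = comparators.oq_train(Q_tr, train.outcome)
            tr_vals = comparators.oq_apply(sel, Q_tr).values
            te_vals = comparators.oq_apply(sel, Q_te).values
        record("OQ", tr_vals, te_vals, f"p*={sel.selected_p:g}")
    except Exception as exc:
        rows.append({"biomarker": "OQ", "auc": np.nan, "direction": 0,
                     "note": f"failed: {exc}"})

    msi_tr = comparators.msi(train.cells).values
    msi_te = comparators.msi(test.cells).values
    record("MSI", msi_tr, msi_te)

    return pd.DataFrame(rows)


def run_benchmark(config: BenchmarkConfig, progress: bool = False) -> pd.DataFrame:
    """Sweep the configured grid of simulation conditions.

    Replicate studies are shared across grid sizes (the grid only changes the
    tabulation), so the 19- vs 99-quantile comparison is paired.  Partial
    failures are logged in the ``note`` column and the run continues.
    """
    records = []
    seeds = replicate_seeds(config.master_seed, config.n_replicates)
    for scenario in config.scenarios:
        for n_sub in config.n_subjects:
            for n_cells in config.n_cells:
                for outcome_kind in config.outcome_kinds:
                    spec = scenario_spec(
                        scenario, n_subjects_per_group=n_sub,
                        n_cells_per_subject=n_cells, outcome_kind=outcome_kind,
                    )
                    for rep, seed in enumerate(seeds):
                        study = generate_pair(spec, int(seed))
                        for grid_size in config.grid_sizes:
                            res = evaluate_replicate(
                                study, grid_size, config.index_config
                            )
                            for _, r in res.iterrows():
                                records.append({
                                    "scenario": scenario,
                                    "n_subjects": n_sub,
                                    "n_cells": n_cells,
                                    "grid_size": grid_size,
                                    "outcome_kind": outcome_kind,
                                    "replicate": rep,
                                    "seed": int(seed),
                                    **r.to_dict(),
                                })
                    if progress:
                        print(f"done: {scenario} n={n_sub} cells={n_cells} "
                              f"{outcome_kind}", flush=True)
    return pd.DataFrame.from_records(records)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the AUC distribution per condition cell."""
    keys = ["scenario", "n_subjects", "n_cells", "grid_size", "outcome_kind",
            "biomarker"]
    def _agg(g):
        ok = g["auc"].dropna()
        return pd.Series({
            "n_replicates": len(g),
            "n_failed": int(g["auc"].isna().sum()),
            "auc_median": ok.median(),
            "auc_q1": ok.quantile(0.25),
            "auc_q3": ok.quantile(0.75),
        })
    out = results.groupby(keys, sort=True).apply(_agg, include_groups=False)
    return out.reset_index()


def plot_benchmark(results: pd.DataFrame, path) -> None:
    """Box plots of test AUC per biomarker, one panel per scenario."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = sorted(results["scenario"].unique())
    fig, axes = plt.subplots(
        1, len(scenarios), figsize=(3.2 * len(scenarios), 3.4), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, sc in zip(axes, scenarios):
        sub = results[results["scenario"] == sc]
        data = [sub.loc[sub["biomarker"] == b, "auc"].dropna() for b in BIOMARKERS]
        ax.boxplot(data, tick_labels=BIOMARKERS)
        ax.axhline(0.5, ls=":", color="grey", lw=0.8)
        ax.set_title(f"Scenario {sc}")
        ax.set_ylabel("test AUC-ROC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def association_report(
    biomarker,
    outcome,
    covariates: pd.DataFrame | None = None,
    family: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Univariable and covariate-adjusted association models for one index.

    ``biomarker`` is a (typically standardized) BiomarkerVector aligned with
    the outcome subjects.  Returns Wald summaries (HR/OR with 95% CI)
    mirroring how a derived biomarker is reported for a validation cohort.
    """
    vals = np.asarray(biomarker.values, dtype=float)
    if family is None:
        family = "cox" if isinstance(outcome, SurvivalOutcome) else "binomial"
    name = getattr(biomarker, "name", "index")
    out = {"univariable": fit_unpenalized(vals[:, None], outcome, family, [name])}
    if covariates is not None:
        X = np.column_stack([vals, covariates.to_numpy(dtype=float)])
        names = [name] + list(covariates.columns)
        out["adjusted"] = fit_unpenalized(X, outcome, family, names)
    return out
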