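"""Training and application of quantile-index biomarkers.

A quantile index summarizes a subject's whole CSI distribution in one
scalar.  The linear index is ``QI_i = ∫ β(p) Q_i(p) dp`` with the weight
function ``β`` estimated from a training set; the nonlinear index is
``nlQI_i = ∫ F(p, Q_i(p)) dp`` with a tensor-product P-spline surface ``F``.
Either is fitted against a binary, Gaussian, or right-censored survival
outcome, sign-adjusted so that larger index values correspond to larger
median CSI, and then applied unchanged to test subjects.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import models, splines
from .models import BinaryOutcome, SmoothingConfig, SurvivalOutcome, select_lambda
from .quantiles import ProbabilityGrid, QuantileMatrix, tabulate_quantiles

__all__ = [
    "IndexConfig",
    "FittedIndexModel",
    "BiomarkerVector",
    "train_index_model",
    "compute_index",
    "sign_adjust",
    "standardize",
    "crossfit",
]

SCHEMA_VERSION = 1


@dataclass
class IndexConfig:
    """Basis sizes, penalty order and smoothing grid for index training."""

    n_basis_p_linear: int = 8
    n_basis_p: int = 8
    n_basis_q: int = 5
    degree: int = 3
    penalty_order: int = 2
    q_margin: float = 0.05
    #: both index kinds search the same 13-point log-spaced λ grid so the
    #: nonlinear surface's additive limit competes on equal footing
    smoothing: SmoothingConfig = field(
        default_factory=lambda: SmoothingConfig(
            lambda_grid=np.logspace(-4, 6, 13), criterion="bic"
        )
    )
    #: per-margin grid size for the anisotropic tensor smoothing search
    n_lambda_margin: int = 13
    #: criterion improvement (deviance scale) required before the surface
    #: may leave the additive linear-in-q limit; 2 ≈ "positive evidence"
    evidence_threshold: float = 2.0


@dataclass
class BiomarkerVector:
    """Per-subject scalar biomarker values with provenance metadata."""

    subject_ids: list
    values: np.ndarray
    name: str
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids),):
            raise ValueError("one value per subject is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("biomarker values must be finite")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"subject_id": self.subject_ids, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FittedIndexModel:
    """A trained, self-contained quantile-index model.

    Stores everything needed to score new subjects: basis specifications,
    coefficient vector, centering constants absorbing the identifiability
    constraint, the orientation sign, and the training probability grid.
    """

    kind: str  # {"linear_QI", "nonlinear_nlQI"}
    outcome_family: str  # {"gaussian", "binomial", "cox"}
    grid: ProbabilityGrid
    basis_p: splines.BasisSpec
    coefficients: np.ndarray
    column_centers: np.ndarray
    sign: int = 1
    basis_q: splines.BasisSpec | None = None
    intercept: float | None = None
    lam: float = np.nan
    edf: float = np.nan
    scale_tag: str = "log"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("linear_QI", "nonlinear_nlQI"):
            raise ValueError("kind must be 'linear_QI' or 'nonlinear_nlQI'")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        k = self.basis_p.n_basis
        if self.kind == "nonlinear_nlQI":
            if self.basis_q is None:
                raise ValueError("nonlinear model requires basis_q")
            k *= self.basis_q.n_basis
        if len(self.coefficients) != k:
            raise ValueError("coefficient length does not match basis spec")

    # -- serialization (versioned structured text) --------------------------
    def to_json(self) -> str:
        d = {
            "schema_version": SCHEMA_VERSION,
            "kind": self.kind,
            "outcome_family": self.outcome_family,
            "grid_probabilities": self.grid.probabilities.tolist(),
            "grid_weights": self.grid.weights.tolist(),
            "basis_p": self.basis_p.to_dict(),
            "basis_q": self.basis_q.to_dict() if self.basis_q else None,
            "coefficients": np.asarray(self.coefficients).tolist(),
            "column_centers": np.asarray(self.column_centers).tolist(),
            "sign": int(self.sign),
            "intercept": self.intercept,
            "lambda": None if np.isnan(self.lam) else float(self.lam),
            "edf": None if np.isnan(self.edf) else float(self.edf),
            "scale_tag": self.scale_tag,
            "metadata": self.metadata,
        }
        return json.dumps(d, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "FittedIndexModel":
        try:
            d = json.loads(text)
            if d.get("schema_version") != SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported model schema version {d.get('schema_version')!r}"
                )
            return cls(
                kind=d["kind"],
                outcome_family=d["outcome_family"],
                grid=ProbabilityGrid(
                    np.array(d["grid_probabilities"]), np.array(d["grid_weights"])
                ),
                basis_p=splines.BasisSpec.from_dict(d["basis_p"]),
                basis_q=(
                    splines.BasisSpec.from_dict(d["basis_q"]) if d["basis_q"] else None
                ),
                coefficients=np.array(d["coefficients"], dtype=float),
                column_centers=np.array(d["column_centers"], dtype=float),
                sign=int(d["sign"]),
                intercept=d["intercept"],
                lam=np.nan if d["lambda"] is None else float(d["lambda"]),
                edf=np.nan if d["edf"] is None else float(d["edf"]),
                scale_tag=d["scale_tag"],
                metadata=d.get("metadata", {}),
            )
        except (KeyError, json.JSONDecodeError, TypeError) as exc:
            raise ValueError(f"corrupt or incompatible model file: {exc}") from exc

    @classmethod
    def load(cls, path) -> "FittedIndexModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _null_complement(v: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the complement of the column span of ``v``."""
    K = v.shape[0]
    q, _ = np.linalg.qr(v, mode="complete")
    return q[:, v.shape[1]:].reshape(K, K - v.shape[1])


def _build_design(
    Q: QuantileMatrix, kind: str, basis_p, basis_q, clamp_q: bool = True
) -> splines.FunctionalDesign:
    if kind == "linear_QI":
        return splines.linear_functional_design(Q, basis_p)
    return splines.tensor_functional_design(Q, basis_p, basis_q, clamp_q=clamp_q)


def train_index_model(
    Q_train: QuantileMatrix,
    outcome: BinaryOutcome | SurvivalOutcome | np.ndarray,
    kind: str = "nonlinear_nlQI",
    outcome_family: str | None = None,
    config: IndexConfig | None = None,
) -> FittedIndexModel:
    """Fit a linear QI or nonlinear nlQI model on a training set.

    Builds the functional design, centers it (identifiability constraint),
    fits the penalized model with smoothing selection, and orients the sign
    so that larger indices correspond to larger median CSI.
    """
    if config is None:
        config = IndexConfig()
    if outcome_family is None:
        outcome_family = (
            "cox" if isinstance(outcome, SurvivalOutcome)
            else "binomial" if isinstance(outcome, BinaryOutcome)
            else "gaussian"
        )
    M = Q_train.n_subjects
    if M < 20:
        warnings.warn(f"only {M} training subjects; >= 20 recommended", stacklevel=2)
    if np.ptp(Q_train.values) <= 0:
        raise ValueError("degenerate functional predictor: all quantile functions identical")

    if kind == "linear_QI":
        basis_p = splines.BasisSpec(config.n_basis_p_linear, config.degree, (0.0, 1.0))
        basis_q = None
    elif kind == "nonlinear_nlQI":
        basis_p = splines.BasisSpec(config.n_basis_p, config.degree, (0.0, 1.0))
        basis_q = splines.BasisSpec(
            config.n_basis_q, config.degree,
            splines.q_domain_from_training(Q_train, config.q_margin),
        )
    else:
        raise ValueError("kind must be 'linear_QI' or 'nonlinear_nlQI'")

    design = _build_design(Q_train, kind, basis_p, basis_q)
    design = splines.center_columns(design)
    X = design.matrix

    if outcome_family == "cox":
        if not isinstance(outcome, SurvivalOutcome):
            raise TypeError("cox family requires a SurvivalOutcome")
        def base_fitter(S, lam, beta0=None, design=None):
            return models.fit_penalized_cox(
                X_fit if design is None else design, outcome, S, lam, beta0=beta0
            )
    else:
        y = outcome.y if isinstance(outcome, BinaryOutcome) else np.asarray(outcome)
        if outcome_family == "binomial":
            BinaryOutcome(list(Q_train.subject_ids), y).check_fittable()
        def base_fitter(S, lam, beta0=None, design=None):
            return models.fit_penalized_glm(
                X_fit if design is None else design, y, S, lam,
                family=outcome_family, beta0=beta0
            )

    if kind == "linear_QI":
        X_fit = X
        S = splines.difference_penalty(basis_p.n_basis, config.penalty_order).matrix
        # apply the lambda grid relative to the design/penalty scale so the
        # search spans the whole effective-df range for any data magnitude
        rho = np.trace(X.T @ X) / np.trace(S)
        lam, fit = select_lambda(
            lambda lam: base_fitter(S, lam * rho), config.smoothing
        )
        lam_info = {"lambda": lam * rho}
        coef = np.asarray(fit.coef, dtype=float)
        lam_store = lam * rho
    else:
        # Constraint absorption: the constant surface (all θ equal) lies in
        # the null space of both the centered design and the difference
        # penalty, so it is unidentifiable at every λ.  Reparametrize to the
        # orthogonal complement of the constant coefficient vector and map
        # the fitted coefficients back afterwards.
        K = X.shape[1]
        ones = np.full((K, 1), 1.0 / np.sqrt(K))
        Z = _null_complement(ones)
        X_fit = X @ Z
        S_margin_p = splines.difference_penalty(
            basis_p.n_basis, config.penalty_order).matrix
        # Greville-scaled curvature penalty: its null space is exactly
        # {1, q}, so the fully smoothed q-margin is truly linear in q
        S_margin_q = splines.curvature_penalty(basis_q).matrix
        Sp = Z.T @ np.kron(S_margin_p, np.eye(basis_q.n_basis)) @ Z
        Sq = Z.T @ np.kron(np.eye(basis_p.n_basis), S_margin_q) @ Z
        (lam_p, lam_q), fit = _select_tensor_lambda(
            base_fitter, X_fit, Sp, Sq, config
        )
        lam_info = {"lambda_p": lam_p, "lambda_q": lam_q}
        coef = Z @ np.asarray(fit.coef, dtype=float)
        lam_store = np.nan

    model = FittedIndexModel(
        kind=kind,
        outcome_family=outcome_family,
        grid=Q_train.grid,
        basis_p=basis_p,
        basis_q=basis_q,
        coefficients=coef,
        column_centers=np.asarray(design.column_centers, dtype=float),
        sign=1,
        intercept=fit.intercept,
        lam=lam_store,
        edf=fit.edf,
        scale_tag=Q_train.scale_tag,
        metadata={"n_train": M, "converged": bool(fit.converged), **lam_info},
    )
    return sign_adjust(model, Q_train)


def _select_tensor_lambda(base_fitter, X, Sp, Sq, config: IndexConfig):
    """Anisotropic smoothing search for the tensor surface.

    A single shared λ cannot smooth the q-direction strongly while leaving
    the p-direction flexible, which would force the heavily-smoothed surface
    toward a merely linear-in-p weight.  Searching a per-margin grid
    ``S(λ_p, λ_q) = λ_p S_p⊗I + λ_q I⊗S_q`` lets the additive-model space
    nest the linear index model (strong λ_q, weak λ_p gives
    ``F(p,q) = f1(p) + f2(p)·q``).  Grids are applied relative to the
    design/penalty scale; criterion ties break toward the smoother fit.
    """
    lo = np.log10(config.smoothing.lambda_grid[0])
    hi = np.log10(config.smoothing.lambda_grid[-1])
    grid = np.logspace(lo, hi, config.n_lambda_margin)
    scale = np.trace(X.T @ X)
    rho_p = scale / np.trace(Sp)
    rho_q = scale / np.trace(Sq)

    # lambda_q = infinity is handled exactly by restricting to the q-penalty
    # null space (the additive, linear-in-q surfaces), so that limit is
    # always an available and numerically clean candidate
    w, V = np.linalg.eigh(Sq)
    N = V[:, w < 1e-10 * max(w[-1], 1.0)]
    X_lim = X @ N
    Sp_lim = N.T @ Sp @ N
    n = grid.size + 1  # index n-1 encodes the infinite-lambda_q limit

    cache: dict[tuple[int, int], tuple[float, object]] = {}
    state = {"warm": None, "best": None, "best_score": np.inf, "best_pair": None}

    def _project_warm(warm):
        if warm is None:
            return None
        if warm.shape[0] == X.shape[1] + 1:  # leading intercept (GLM)
            return np.concatenate([[warm[0]], N.T @ warm[1:]])
        return N.T @ warm

    def score_at(ip, iq):
        key = (ip, iq)
        if key in cache:
            return cache[key][0]
        try:
            if iq == n - 1:
                fit = base_fitter(
                    (grid[ip] * rho_p) * Sp_lim, 1.0,
                    beta0=_project_warm(state["warm"]), design=X_lim,
                )
            else:
                S = (grid[ip] * rho_p) * Sp + (grid[iq] * rho_q) * Sq
                fit = base_fitter(S, 1.0, beta0=state["warm"])
        except np.linalg.LinAlgError:
            cache[key] = (np.inf, None)
            return np.inf
        if not fit.converged:
            cache[key] = (np.inf, None)
            return np.inf
        if iq == n - 1:  # expand back to the full coefficient space
            fit = dataclasses.replace(fit, coef=N @ fit.coef)
        state["warm"] = (
            np.concatenate([[fit.intercept], fit.coef])
            if fit.intercept is not None else fit.coef
        )
        score = models.criterion_value(fit, config.smoothing.criterion)
        cache[key] = (score, fit)
        if score <= state["best_score"]:
            state["best"], state["best_score"] = fit, score
            state["best_pair"] = key
        return score

    # coordinate descent over (lambda_p, lambda_q), started at the additive
    # limit; reversed argmin scans resolve criterion ties toward smoother fits
    ip, iq = n - 2, n - 1
    for _ in range(2):
        scores = [score_at(i, iq) for i in range(n - 1)]
        ip = (n - 2) - int(np.nanargmin(scores[::-1]))
        scores = [score_at(ip, i) for i in range(n)]
        iq = (n - 1) - int(np.nanargmin(scores[::-1]))
    if state["best"] is None:
        raise RuntimeError("no candidate smoothing parameter converged")
    bp, bq = state["best_pair"]
    # Positive-evidence rule: keep the additive linear-in-q limit unless a
    # genuinely nonlinear surface improves the criterion by more than the
    # threshold (deviance-scale criteria only).
    if (bq < n - 1 and config.evidence_threshold > 0
            and config.smoothing.criterion in ("aic", "bic")):
        limit_scores = [
            cache[(i, n - 1)][0] for i in range(n) if (i, n - 1) in cache
        ]
        limit_best = np.nanmin(limit_scores) if limit_scores else np.inf
        if state["best_score"] > limit_best - config.evidence_threshold:
            for i in range(n - 1, -1, -1):
                if (i, n - 1) in cache and cache[(i, n - 1)][0] == limit_best:
                    bp, bq = i, n - 1
                    state["best"] = cache[(i, n - 1)][1]
                    break
    lam_q = np.inf if bq == n - 1 else float(grid[bq] * rho_q)
    return (float(grid[bp] * rho_p), lam_q), state["best"]


def compute_index(
    model: FittedIndexModel,
    Q: QuantileMatrix | None = None,
    cells=None,
    log_transform: bool | None = None,
) -> BiomarkerVector:
    """Quantile indices for new subjects under a fitted model.

    ``value_i = sign · (design_i − centers) · coefficients`` — the quadrature
    of ``∫ β(p) Q_i(p) dp`` or ``∫ F(p, Q_i(p)) dp`` with the training
    centering applied.  Quantile values beyond the training q-domain are
    clamped to its boundary.  A raw cell table may be given instead of a
    quantile matrix; it is tabulated on the model's stored grid.
    """
    if Q is None:
        if cells is None:
            raise ValueError("either Q or cells must be provided")
        Q = tabulate_quantiles(
            cells, model.grid,
            log_transform=(model.scale_tag == "log") if log_transform is None
            else log_transform,
        )
    if not Q.grid.isclose(model.grid):
        raise ValueError(
            "quantile matrix grid differs from the model grid; "
            "re-tabulate on the model grid (pass the raw cell table)"
        )
    design = _build_design(Q, model.kind, model.basis_p, model.basis_q)
    X = design.matrix - model.column_centers
    values = model.sign * (X @ model.coefficients)
    name = "QI" if model.kind == "linear_QI" else "nlQI"
    return BiomarkerVector(list(Q.subject_ids), values, name=name)


def sign_adjust(model: FittedIndexModel, Q_train: QuantileMatrix) -> FittedIndexModel:
    """Orient the model so indices increase with training median CSI.

    Computes the Spearman correlation between raw training indices and the
    per-subject quantile at the grid probability nearest 0.5; if negative,
    the orientation sign is set to −1, which negates the effective weight
    function/surface.  Negating a centered (zero-mean) functional term
    preserves the identifiability constraint.
    """
    base = FittedIndexModel(**{**model.__dict__, "sign": 1})
    idx = compute_index(base, Q_train).values
    med = Q_train.median_column()
    if np.ptp(med) == 0 or np.ptp(idx) == 0:
        warnings.warn(
            "zero-variance medians or indices; sign left at +1", stacklevel=2
        )
        return base
    rho = stats.spearmanr(idx, med).statistic
    if np.isnan(rho):
        warnings.warn("undefined correlation; sign left at +1", stacklevel=2)
        return base
    if rho < 0:
        return FittedIndexModel(**{**model.__dict__, "sign": -1})
    return base


def standardize(
    v: BiomarkerVector,
    center: float | None = None,
    scale: float | None = None,
) -> BiomarkerVector:
    """Median/IQR standardization: ``(v − median) / IQR``.

    Quartiles use the linear-interpolation (type-7) convention.  ``center``
    and ``scale`` may be supplied to freeze training-set statistics;
    otherwise they are computed from ``v`` itself.
    """
    x = v.values
    if center is None:
        center = float(np.median(x))
    if scale is None:
        q1, q3 = np.percentile(x, [25, 75])
        scale = float(q3 - q1)
    if scale <= 0:
        raise ValueError("degenerate biomarker: IQR is zero")
    return BiomarkerVector(
        list(v.subject_ids), (x - center) / scale, name=v.name, standardized=True
    )


def _stratified_folds(strata: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seed-deterministic fold labels, stratified by a binary indicator."""
    rng = np.random.default_rng(seed)
    n = strata.size
    fold = np.empty(n, dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def crossfit(
    Q: QuantileMatrix,
    outcome: BinaryOutcome | SurvivalOutcome,
    k: int = 5,
    seed: int = 0,
    kind: str = "nonlinear_nlQI",
    config: IndexConfig | None = None,
) -> BiomarkerVector:
    """Out-of-fold quantile indices via k-fold cross-fitting.

    Subjects are assigned to folds stratified by outcome status (event or
    class indicator) so every training remainder keeps both classes / at
    least one event; each subject's index comes from the model trained on
    the other k−1 folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(outcome, SurvivalOutcome):
        strata = outcome.event.astype(int)
    elif isinstance(outcome, BinaryOutcome):
        strata = outcome.y.astype(int)
    else:
        strata = np.zeros(Q.n_subjects, dtype=int)
    fold = _stratified_folds(strata, k, seed)

    from .quantiles import subset as q_subset

    values = np.empty(Q.n_subjects)
    name = None
    sids = np.asarray(Q.subject_ids, dtype=object)
    for f in range(k):
        train_mask = fold != f
        if isinstance(outcome, SurvivalOutcome):
            if outcome.event[train_mask].sum() < 1:
                raise ValueError(
                    f"training remainder of fold {f} has no events; use smaller k"
                )
            sub_outcome = SurvivalOutcome(
                list(sids[train_mask]), outcome.time[train_mask],
                outcome.event[train_mask],
            )
        else:
            y_tr = outcome.y[train_mask]
            if y_tr.min() == y_tr.max():
                raise ValueError(
                    f"training remainder of fold {f} has one class; use smaller k"
                )
            sub_outcome = BinaryOutcome(list(sids[train_mask]), y_tr)
        Q_tr = q_subset(Q, list(sids[train_mask]))
        Q_te = q_subset(Q, list(sids[~train_mask]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_index_model(Q_tr, sub_outcome, kind=kind, config=config)
            vals = compute_index(model, Q_te).values
        values[~train_mask] = vals
        name = "QI" if kind == "linear_QI" else "nlQI"
    return BiomarkerVector(list(Q.subject_ids), values, name=f"{name}_crossfit")
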