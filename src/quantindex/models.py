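"""Penalized scalar-on-function model fitters.

Two estimation engines back all quantile-index biomarkers:

* a penalized exponential-family GLM (Gaussian identity, binomial logit)
  maximizing ``ℓ(θ) − (λ/2) θᵀSθ`` by iteratively reweighted least squares —
  the functional general(ized) linear/additive models FGLM and FGAM;
* a penalized Cox proportional-hazards model maximizing the Breslow partial
  log-likelihood ``ℓ_p(θ) − (λ/2) θᵀSθ`` by Newton iterations with step
  halving — the linear/additive functional Cox models LFCM and AFCM.

The intercept (GLM only) is never penalized; the Cox model has no intercept
because it is absorbed into the baseline hazard.  Smoothing parameters are
selected on a fixed grid by GCV (exponential family) or by the partial-
likelihood AIC ``−2ℓ_p + 2·edf`` (Cox), with ties broken toward the larger,
smoother λ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .splines import PenaltyMatrix

__all__ = [
    "BinaryOutcome",
    "SurvivalOutcome",
    "PenalizedFit",
    "SmoothingConfig",
    "fit_penalized_glm",
    "fit_penalized_cox",
    "select_lambda",
    "fit_unpenalized",
]

MAX_ITER = 100
REL_TOL = 1e-11
MAX_HALVINGS = 20


@dataclass
class BinaryOutcome:
    subject_ids: list
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("binary outcome must be coded 0/1")

    def check_fittable(self) -> None:
        if self.y.min() == self.y.max():
            raise ValueError("both outcome classes must be present for fitting")


@dataclass
class SurvivalOutcome:
    subject_ids: list
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.event, (0.0, 1.0))):
            raise ValueError("event indicator must be coded 0/1")

    def check_fittable(self) -> None:
        if self.event.sum() < 1:
            raise ValueError("at least one event is required for fitting")


@dataclass
class PenalizedFit:
    """Result of one penalized fit at a fixed smoothing parameter."""

    coef: np.ndarray
    intercept: float | None
    lam: float
    edf: float
    converged: bool
    loglik: float
    criterion_value: float
    family: str
    n_obs: int
    n_iter: int = 0
    message: str = ""
    cov: np.ndarray | None = None
    grad_norm: float = np.nan


@dataclass
class SmoothingConfig:
    """Grid and criterion for smoothing-parameter selection."""

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 6, 30)
    )
    criterion: str = "auto"  # gcv for exponential family, cox_aic for Cox

    def __post_init__(self) -> None:
        self.lambda_grid = np.sort(np.asarray(self.lambda_grid, dtype=float))
        if self.lambda_grid.size == 0:
            raise ValueError("lambda grid must be non-empty")
        if np.any(self.lambda_grid < 0):
            raise ValueError("lambda values must be >= 0")
        if self.criterion not in ("auto", "gcv", "aic", "bic"):
            raise ValueError("criterion must be one of auto/gcv/aic/bic")


def criterion_value(fit: PenalizedFit, criterion: str = "auto") -> float:
    """Model-selection score of a fit under the requested criterion.

    ``auto`` uses the fit's native score (GCV for exponential families,
    −2ℓ_p + 2·edf for Cox); ``aic``/``bic`` score ``−2ℓ + c·edf`` with
    c = 2 or log n (for Gaussian fits the deviance stands in for −2ℓ, so
    these are scale-dependent and GCV is preferred there).
    """
    if criterion in ("auto", "gcv"):
        return fit.criterion_value
    c = 2.0 if criterion == "aic" else float(np.log(fit.n_obs))
    return -2.0 * fit.loglik + c * fit.edf


def _penalty_matrix(penalty, k: int) -> np.ndarray:
    if penalty is None:
        return np.zeros((k, k))
    S = penalty.matrix if isinstance(penalty, PenaltyMatrix) else np.asarray(penalty)
    if S.shape != (k, k):
        raise ValueError(f"penalty shape {S.shape} does not match {k} coefficients")
    return S


def fit_penalized_glm(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltyMatrix | np.ndarray | None = None,
    lam: float = 0.0,
    family: str = "binomial",
    add_intercept: bool = True,
    beta0: np.ndarray | None = None,
) -> PenalizedFit:
    """Penalized IRLS fit of a Gaussian or binomial-logit GLM.

    ``X`` holds the (typically centered functional) covariate columns without
    an intercept; an unpenalized intercept column is prepended unless
    ``add_intercept=False``.  ``edf`` is the trace of the influence matrix
    ``(XᵀWX + λS)⁻¹ XᵀWX`` at convergence and the reported criterion value is
    the GCV score ``n·deviance / (n − edf)²``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if family not in ("gaussian", "binomial"):
        raise ValueError("family must be 'gaussian' or 'binomial'")
    S = _penalty_matrix(penalty, k)

    if add_intercept:
        Xa = np.column_stack([np.ones(n), X])
        Sa = np.zeros((k + 1, k + 1))
        Sa[1:, 1:] = S
    else:
        Xa, Sa = X, S

    def _solve(A, b):
        try:
            return np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            if lam > 0:
                # numerically singular at an intermediate lambda: tiny jitter
                jitter = 1e-8 * np.mean(np.diag(A)) * np.eye(A.shape[0])
                return np.linalg.solve(A + jitter, b)
            raise np.linalg.LinAlgError(
                "singular penalized system; use lambda > 0 or a full-rank design"
            ) from exc

    if family == "gaussian":
        A = Xa.T @ Xa + lam * Sa
        beta = _solve(A, Xa.T @ y)
        mu = Xa @ beta
        dev = float(np.sum((y - mu) ** 2))
        edf = float(np.trace(np.linalg.solve(A, Xa.T @ Xa)))
        scale = dev / max(n - edf, 1.0)
        # -2 loglik up to constants; used only for comparison across lambdas
        loglik = -0.5 * dev
        cov = np.linalg.inv(A) * scale
        grad = Xa.T @ (y - mu) - lam * (Sa @ beta)
        fit = PenalizedFit(
            coef=beta[1:] if add_intercept else beta,
            intercept=float(beta[0]) if add_intercept else None,
            lam=lam, edf=edf, converged=True, loglik=loglik,
            criterion_value=_gcv(n, dev, edf), family=family, n_obs=n,
            n_iter=1, cov=cov, grad_norm=float(np.linalg.norm(grad)),
        )
        return fit

    # binomial logit IRLS
    if beta0 is not None and beta0.shape == (Xa.shape[1],):
        beta = np.array(beta0, dtype=float)
    else:
        beta = np.zeros(Xa.shape[1])
        mu0 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        if add_intercept:
            beta[0] = np.log(mu0 / (1 - mu0))
    def _pen_dev(b):
        eta = Xa @ b
        mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700))), 1e-12,
                     1 - 1e-12)
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        return dev + lam * float(b @ Sa @ b), dev, mu

    pen_dev_old, dev, mu = _pen_dev(beta)
    converged = False
    message = ""
    for it in range(1, MAX_ITER + 1):
        eta = np.clip(Xa @ beta, -700, 700)
        w = np.maximum(mu * (1 - mu), 1e-12)
        z = eta + (y - mu) / w
        A = (Xa * w[:, None]).T @ Xa + lam * Sa
        beta_new = _solve(A, (Xa * w[:, None]).T @ z)
        # step halving keeps the penalized deviance monotone (stabilizes
        # separable configurations, where the unpenalized MLE is infinite)
        alpha = 1.0
        for _ in range(MAX_HALVINGS + 1):
            cand = beta + alpha * (beta_new - beta)
            pen_dev, dev, mu = _pen_dev(cand)
            if np.isfinite(pen_dev) and pen_dev <= pen_dev_old + 1e-12:
                break
            alpha *= 0.5
        step = np.max(np.abs(cand - beta))
        beta = cand
        if (abs(pen_dev - pen_dev_old) <= REL_TOL * (abs(pen_dev) + 1.0)
                or step <= 1e-10 * (1.0 + np.max(np.abs(beta)))):
            converged = True
            break
        pen_dev_old = pen_dev
    eta = Xa @ beta
    n_iter = it
    if np.max(np.abs(eta)) > 25 and lam * np.trace(Sa) == 0:
        converged = False
        message = "possible complete separation: fitted probabilities at 0/1"
    w = mu * (1 - mu)
    Info = (Xa * w[:, None]).T @ Xa
    A = Info + lam * Sa
    try:
        edf = float(np.trace(np.linalg.solve(A, Info)))
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.mean(np.diag(A)) * np.eye(A.shape[0])
        edf = float(np.trace(np.linalg.solve(A, Info)))
        cov = np.linalg.inv(A)
    loglik = -0.5 * dev
    grad = Xa.T @ (y - mu) - lam * (Sa @ beta)
    if not converged and not message:
        message = "IRLS did not converge"
    return PenalizedFit(
        coef=beta[1:] if add_intercept else beta,
        intercept=float(beta[0]) if add_intercept else None,
        lam=lam, edf=edf, converged=converged, loglik=loglik,
        criterion_value=_gcv(n, dev, edf), family=family, n_obs=n,
        n_iter=n_iter, message=message, cov=cov,
        grad_norm=float(np.linalg.norm(grad)),
    )


def _gcv(n: int, deviance: float, edf: float) -> float:
    return n * deviance / max(n - edf, 1e-8) ** 2


def _breslow_parts(eta, X, order, tie_last):
    """Risk-set sums S0, S1, S2 at each subject's time (descending order)."""
    e = np.exp(eta - eta.max())
    s0 = np.cumsum(e[order])
    s1 = np.cumsum(e[order, None] * X[order], axis=0)
    s2 = np.cumsum(e[order, None, None] * (X[order, :, None] * X[order, None, :]),
                   axis=0)
    # subjects tied on time share the full tied risk set
    s0 = s0[tie_last]
    s1 = s1[tie_last]
    s2 = s2[tie_last]
    return e, s0, s1, s2


def fit_penalized_cox(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    penalty: PenaltyMatrix | np.ndarray | None = None,
    lam: float = 0.0,
    beta0: np.ndarray | None = None,
) -> PenalizedFit:
    """Penalized Cox fit (Breslow ties) by Newton iterations with step halving.

    Maximizes ``ℓ_p(θ) − (λ/2) θᵀSθ``; ``edf = tr((H + λS)⁻¹ H)`` with ``H``
    the negative Hessian of the partial log-likelihood at the optimum, and the
    criterion value is ``−2ℓ_p + 2·edf``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    outcome.check_fittable()
    time, event = outcome.time, outcome.event
    n, k = X.shape
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    S = _penalty_matrix(penalty, k)

    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    Xs = X[order]
    ev_s = event[order].astype(bool)
    # first/last index (within descending order) of each tied-time group
    tie_first = np.empty(n, dtype=int)
    tie_last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        tie_first[i : j + 1] = i
        tie_last[i : j + 1] = j
        i = j + 1

    def loglik_parts(beta, need_hess=True):
        # Breslow risk-set sums via cumulative sums in descending-time order;
        # the Hessian uses the cumulative-hazard reweighting identity
        # Σ_e S2(e)/S0(e) = Xᵀ diag(w c) X, avoiding any n×K×K intermediate.
        etas = Xs @ beta
        shift = etas.max()
        es = np.exp(etas - shift)
        s0 = np.cumsum(es)[tie_last]
        ll = float(np.sum(etas[ev_s] - (np.log(s0[ev_s]) + shift)))
        if not need_hess:
            return ll, None, None
        s1 = np.cumsum(es[:, None] * Xs, axis=0)[tie_last]
        R = s1[ev_s] / s0[ev_s, None]
        grad = Xs[ev_s].sum(axis=0) - R.sum(axis=0)
        g = np.where(ev_s, 1.0 / s0, 0.0)
        c = np.cumsum(g[::-1])[::-1][tie_first]
        H = (Xs * (es * c)[:, None]).T @ Xs - R.T @ R
        return ll, grad, H

    if beta0 is not None and beta0.shape == (k,):
        beta = np.array(beta0, dtype=float)
    else:
        beta = np.zeros(k)
    ll, grad, H = loglik_parts(beta)
    pen_obj = ll - 0.5 * lam * float(beta @ S @ beta)
    converged = False
    message = ""
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        pgrad = grad - lam * (S @ beta)
        if np.linalg.norm(pgrad) <= 1e-9 * (1.0 + abs(pen_obj)):
            converged = True
            break
        pH = H + lam * S
        try:
            step = np.linalg.solve(pH, pgrad)
        except np.linalg.LinAlgError:
            pH = pH + 1e-8 * np.eye(k)
            step = np.linalg.solve(pH, pgrad)
        # step halving on the penalized objective
        alpha = 1.0
        for _ in range(MAX_HALVINGS + 1):
            beta_new = beta + alpha * step
            ll_new, _, _ = loglik_parts(beta_new, need_hess=False)
            obj_new = ll_new - 0.5 * lam * float(beta_new @ S @ beta_new)
            if np.isfinite(obj_new) and obj_new >= pen_obj - 1e-12:
                break
            alpha *= 0.5
        beta = beta_new
        improved = obj_new - pen_obj
        pen_obj = obj_new
        ll, grad, H = loglik_parts(beta)
        if abs(improved) <= REL_TOL * (abs(pen_obj) + 1.0):
            converged = True
            break
    if np.linalg.norm(beta) > 1e3:
        converged = False
        message = "monotone partial likelihood: coefficient diverging"
    pH = H + lam * S
    try:
        edf = float(np.trace(np.linalg.solve(pH, H))) if k > 0 else 0.0
        cov = np.linalg.inv(pH)
    except np.linalg.LinAlgError:
        pH_j = pH + (1e-10 * max(np.trace(pH) / max(k, 1), 1.0)) * np.eye(k)
        edf = float(np.trace(np.linalg.solve(pH_j, H)))
        cov = np.linalg.inv(pH_j)
    pgrad = grad - lam * (S @ beta)
    if not converged and not message:
        message = "Newton iterations did not converge"
    return PenalizedFit(
        coef=beta, intercept=None, lam=lam, edf=edf, converged=converged,
        loglik=ll, criterion_value=-2.0 * ll + 2.0 * edf, family="cox",
        n_obs=n, n_iter=n_iter, message=message, cov=cov,
        grad_norm=float(np.linalg.norm(pgrad)),
    )


def select_lambda(fitter, config: SmoothingConfig | None = None):
    """Pick the smoothing parameter minimizing the fitter's criterion.

    ``fitter`` maps a λ value to a :class:`PenalizedFit` (whose
    ``criterion_value`` is GCV for exponential families and −2ℓ+2edf for
    Cox).  Non-converged candidates are skipped; criterion ties are broken
    toward the larger λ.

    Returns
    -------
    (lambda_star, PenalizedFit)
    """
    if config is None:
        config = SmoothingConfig()
    best = None
    best_score = np.inf
    for lam in config.lambda_grid:
        try:
            fit = fitter(float(lam))
        except np.linalg.LinAlgError:
            continue  # singular system at this (too small) lambda
        if not fit.converged:
            continue
        score = criterion_value(fit, config.criterion)
        if best is None or score <= best_score:
            best, best_score = fit, score
    if best is None:
        raise RuntimeError("no candidate smoothing parameter converged")
    return best.lam, best


def fit_unpenalized(
    X: np.ndarray,
    outcome,
    family: str,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Unpenalized (λ=0) fit with Wald inference for 1–3 scalar covariates.

    Returns a tidy summary with one row per covariate: coefficient, standard
    error, z, p-value, and the exponentiated effect (OR for binomial, HR for
    Cox) with its 95% Wald CI.  For Gaussian outcomes the effect column is
    the raw slope.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 1 and X.shape[0] == 1:
        X = X.T
    k = X.shape[1]
    if names is None:
        names = [f"x{j+1}" for j in range(k)]
    if family == "cox":
        fit = fit_penalized_cox(X, outcome, penalty=None, lam=0.0)
        coefs = fit.coef
        cov = fit.cov
        offset = 0
    else:
        y = outcome.y if isinstance(outcome, BinaryOutcome) else np.asarray(outcome)
        fit = fit_penalized_glm(X, y, penalty=None, lam=0.0, family=family)
        coefs = fit.coef
        cov = fit.cov
        offset = 1  # skip the intercept row of the covariance
    rows = []
    for j in range(k):
        se = float(np.sqrt(cov[j + offset, j + offset]))
        b = float(coefs[j])
        z = b / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z))
        lo, hi = b - 1.959963984540054 * se, b + 1.959963984540054 * se
        expit = family in ("binomial", "cox")
        rows.append({
            "term": names[j],
            "coef": b,
            "se": se,
            "z": z,
            "p_value": p,
            "effect": np.exp(b) if expit else b,
            "ci_low": np.exp(lo) if expit else lo,
            "ci_high": np.exp(hi) if expit else hi,
            "effect_label": {"binomial": "OR", "cox": "HR", "gaussian": "slope"}[family],
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)
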