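"""B-spline bases, difference penalties and functional design matrices.

The linear quantile index uses a weight function ``β(p) = Σ_j b_j B_j(p)``;
the nonlinear index uses a bivariate surface represented as a tensor product
of univariate P-splines, ``F(p, q) = Σ_{j,l} θ_{jl} B_j^p(p) B_l^q(q)``.
Both reduce, after quadrature over the probability grid, to ordinary design
matrices whose rows are per-subject integrated basis evaluations.  Column
centering absorbs the identifiability constraint that the functional term's
training-set contributions sum to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import BSpline

from .quantiles import ProbabilityGrid, QuantileMatrix

__all__ = [
    "BasisSpec",
    "PenaltyMatrix",
    "FunctionalDesign",
    "bspline_basis",
    "difference_penalty",
    "tensor_penalty",
    "linear_functional_design",
    "tensor_functional_design",
    "center_columns",
    "q_domain_from_training",
]


@dataclass(frozen=True)
class BasisSpec:
    """A clamped, uniform-knot B-spline basis on a closed interval."""

    n_basis: int
    degree: int = 3
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_basis < self.degree + 1:
            raise ValueError("n_basis must be at least degree + 1")
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("basis domain must have positive width")

    @property
    def knots(self) -> np.ndarray:
        """Full clamped knot vector (end knots repeated degree+1 times)."""
        lo, hi = self.domain
        n_interior = self.n_basis - self.degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate(
            [np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)]
        )

    def to_dict(self) -> dict:
        return {
            "n_basis": self.n_basis,
            "degree": self.degree,
            "domain": [float(self.domain[0]), float(self.domain[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(n_basis=int(d["n_basis"]), degree=int(d["degree"]),
                   domain=(float(d["domain"][0]), float(d["domain"][1])))


@dataclass
class PenaltyMatrix:
    """Symmetric PSD quadratic-form matrix ``DᵀD`` of a difference operator."""

    matrix: np.ndarray
    order: int


@dataclass
class FunctionalDesign:
    """Discretized functional term: rows are per-subject quadratures."""

    matrix: np.ndarray
    kind: str  # {"linear", "tensor"}
    basis_p: BasisSpec
    grid: ProbabilityGrid
    basis_q: BasisSpec | None = None
    column_centers: np.ndarray | None = None  # None until centered


def bspline_basis(points, spec: BasisSpec, clamp: bool = False) -> np.ndarray:
    """Evaluate all basis functions at ``points`` (rows sum to one).

    With ``clamp=True`` points outside the domain are moved to the nearest
    boundary (used for quantile values beyond the training range).
    """
    x = np.asarray(points, dtype=float)
    shape = x.shape
    x = x.ravel()
    lo, hi = spec.domain
    if clamp:
        n_out = int(np.sum((x < lo) | (x > hi)))
        if n_out:
            warnings.warn(
                f"{n_out} evaluation point(s) outside basis domain "
                f"[{lo:g}, {hi:g}]; clamped to boundary",
                stacklevel=2,
            )
        x = np.clip(x, lo, hi)
    elif np.any(x < lo) or np.any(x > hi):
        raise ValueError("evaluation points outside basis domain")
    design = BSpline.design_matrix(x, spec.knots, spec.degree).toarray()
    return design.reshape(*shape, spec.n_basis)


def difference_penalty(n_basis: int, order: int = 2) -> PenaltyMatrix:
    """P-spline penalty ``DᵀD`` with ``D`` the order-th difference operator.

    Its null space is exactly the coefficient vectors of polynomials of
    degree < order evaluated on the basis index.
    """
    if order >= n_basis:
        raise ValueError("difference order must be smaller than n_basis")
    if order < 1:
        raise ValueError("difference order must be >= 1")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return PenaltyMatrix(matrix=D.T @ D, order=order)


def curvature_penalty(spec: BasisSpec) -> PenaltyMatrix:
    """Second-order divided-difference penalty on the Greville abscissae.

    For clamped B-splines a coefficient vector represents an exactly linear
    function of the argument iff it is linear in the Greville sites, which
    are non-uniform near the boundary.  Scaling the second differences as
    divided differences makes the penalty null space exactly {1, x}, so an
    infinitely smoothed margin degenerates to a truly linear effect.
    """
    t = spec.knots
    d = spec.degree
    K = spec.n_basis
    xi = np.array([t[j + 1 : j + d + 1].mean() for j in range(K)])  # Greville
    D = np.zeros((K - 2, K))
    for j in range(K - 2):
        x0, x1, x2 = xi[j], xi[j + 1], xi[j + 2]
        D[j, j] = 1.0 / ((x0 - x1) * (x0 - x2))
        D[j, j + 1] = 1.0 / ((x1 - x0) * (x1 - x2))
        D[j, j + 2] = 1.0 / ((x2 - x0) * (x2 - x1))
    # normalize to the plain-difference scale on a uniform interior
    h = (xi[-1] - xi[0]) / (K - 1)
    D *= h * h
    return PenaltyMatrix(matrix=D.T @ D, order=2)


def tensor_penalty(n_p: int, n_q: int, order: int = 2) -> PenaltyMatrix:
    """Isotropic tensor penalty ``S_p ⊗ I + I ⊗ S_q`` with one shared λ."""
    S_p = difference_penalty(n_p, order).matrix
    S_q = difference_penalty(n_q, order).matrix
    S = np.kron(S_p, np.eye(n_q)) + np.kron(np.eye(n_p), S_q)
    return PenaltyMatrix(matrix=S, order=order)


def linear_functional_design(Q: QuantileMatrix, basis_p: BasisSpec) -> FunctionalDesign:
    """Design for ``∫ β(p) Q_i(p) dp`` with ``β`` in the span of ``basis_p``.

    Entry ``(i, j) = Σ_p w_p B_j(p) Q_i(p)`` so that ``design @ b`` is the
    quadrature of ``β(p) Q_i(p)`` for ``β = Σ_j b_j B_j``.
    """
    B = bspline_basis(Q.grid.probabilities, basis_p)  # (P, N_p)
    X = (Q.values * Q.grid.weights) @ B  # (M, N_p)
    return FunctionalDesign(matrix=X, kind="linear", basis_p=basis_p, grid=Q.grid)


def q_domain_from_training(Q: QuantileMatrix, margin: float = 0.05) -> tuple[float, float]:
    """Training q-range extended by ``margin`` of its width on each side."""
    lo = float(Q.values.min())
    hi = float(Q.values.max())
    width = hi - lo
    if width <= 0:
        raise ValueError("degenerate functional predictor: zero q-range")
    return lo - margin * width, hi + margin * width


def tensor_functional_design(
    Q: QuantileMatrix,
    basis_p: BasisSpec,
    basis_q: BasisSpec,
    clamp_q: bool = True,
) -> FunctionalDesign:
    """Design for ``∫ F(p, Q_i(p)) dp`` with ``F`` a tensor-product surface.

    Entry ``(i, (j,l)) = Σ_p w_p B_j^p(p) B_l^q(Q_i(p))``; columns are
    ordered with the q-basis index varying fastest (row-major ``(j, l)``).
    """
    lo, hi = basis_q.domain
    if not hi > lo:
        raise ValueError("degenerate basis_q domain")
    Bp = bspline_basis(Q.grid.probabilities, basis_p)  # (P, N_p)
    Bq = bspline_basis(Q.values, basis_q, clamp=clamp_q)  # (M, P, N_q)
    X = np.einsum("pj,mpl,p->mjl", Bp, Bq, Q.grid.weights)
    X = X.reshape(Q.n_subjects, basis_p.n_basis * basis_q.n_basis)
    return FunctionalDesign(
        matrix=X, kind="tensor", basis_p=basis_p, basis_q=basis_q, grid=Q.grid
    )


def center_columns(
    design: FunctionalDesign, reference: np.ndarray | None = None
) -> FunctionalDesign:
    """Subtract column means (training) or stored centers (test).

    On training data the centered design satisfies ``Σ_i (X θ)_i = 0`` for
    every coefficient vector θ — the identifiability constraint of the
    functional term.
    """
    X = design.matrix
    if reference is None:
        centers = X.mean(axis=0)
    else:
        centers = np.asarray(reference, dtype=float)
        if centers.shape != (X.shape[1],):
            raise ValueError(
                f"reference centers have length {centers.size}, "
                f"expected {X.shape[1]}"
            )
    return replace(design, matrix=X - centers, column_centers=centers)
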