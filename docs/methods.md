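# Methods

## Empirical quantile functions

For subject *i* with CSI sample `x_{i1}, …, x_{in_i}`, the empirical
quantile at probability `p` is the *k*-th order statistic with
`k = ⌈n_i p⌉` (the classical type-1 / left-continuous generalized inverse;
a 1e-9 slack is subtracted before the ceiling to protect boundary points
`p = k/n` from binary floating-point fuzz).  Quantile functions are
tabulated on an equally spaced probability grid — 19 points 0.05…0.95 by
default, 99 points 0.01…0.99 available — with uniform weights `1/P` acting
as the Riemann measure for every `∫·dp` quadrature.  CSIs are
log-transformed by default because fluorescence intensity distributions are
right-skewed; optional symmetric trimming of the grid tails increases
robustness to outliers.  When a tissue has several regions of interest,
ROI-level quantile functions are aggregated pointwise (min / median /
mean / max, default mean — all four preserve monotonicity).

## Index models

**Linear (QI).**  `β(p)` is expanded in `N_p = 8` cubic B-splines on
[0, 1] with clamped uniform knots and a second-order difference penalty.
The functional term reduces to an ordinary design matrix with entries
`Σ_p w_p B_j(p) Q_i(p)`.

**Nonlinear (nlQI).**  `F(p, q)` is a tensor product of cubic B-splines
(`N_p = 8` on [0, 1]; `N_q = 5` on the training q-range extended by 5% per
side; test-time quantile values outside that range are clamped to the
boundary with a warning).  Three design choices matter here:

1. *Anisotropic smoothing.*  The penalty is
   `λ_p S_p ⊗ I + λ_q I ⊗ S_q`, searched on a per-margin grid by
   coordinate descent.  A single shared λ cannot smooth the q-direction
   strongly while leaving p flexible: its heavily-smoothed limit is a
   merely linear-in-p weight, which systematically handicaps the surface
   against the linear index.  With two smoothing parameters the limit
   `λ_q → ∞` is the additive family `F(p,q) = f₁(p) + f₂(p)·q`, which
   *nests* the linear index model.
2. *Exactly linear smooth limit.*  The q-margin uses a divided-difference
   (curvature) penalty on the Greville abscissae, whose null space is
   exactly `{1, q}`; the plain index-difference penalty is only
   approximately linear near clamped boundaries.  The `λ_q = ∞` candidate
   is implemented exactly by restricting the fit to that null space
   (numerically cleaner than a huge finite λ).
3. *Identifiability.*  The constant surface lies in the null space of both
   the centered design and the penalty, so it is removed by reparametrizing
   to the orthogonal complement of the constant coefficient vector; column
   centering then enforces the usual constraint that training-set
   functional contributions sum to zero, making the GLM intercept
   interpretable.

**Fitters.**  Exponential-family models (Gaussian identity, binomial
logit) are fitted by penalized IRLS with step halving on the penalized
deviance (this keeps separable configurations, whose unpenalized MLE is
infinite, stable and convergent).  Survival models maximize the penalized
Cox partial log-likelihood with Breslow tie handling by Newton iterations
with step halving; risk-set sums use cumulative sums in descending time
order and the Hessian uses the cumulative-hazard reweighting identity
`Σ_e S₂(e)/S₀(e) = Xᵀ diag(w c) X`, avoiding any `n×K×K` intermediate.
Convergence: relative objective change below 1e-11, a gradient-norm
criterion, or a vanishing step; at most 100 iterations with up to 20
halvings.  Effective degrees of freedom are the trace of the influence
matrix `(XᵀWX + λS)⁻¹XᵀWX` (GLM) or `(H + λS)⁻¹H` (Cox).

**Smoothing selection.**  The criterion is pluggable (GCV, AIC, BIC);
index training defaults to BIC, which in our simulations prevented the
surface from chasing outcome noise that GCV admitted.  λ grids are applied
*relative to the design/penalty scale* `tr(XᵀX)/tr(S)` — quadrature-scaled
functional designs have `tr(XᵀX)` orders of magnitude below `tr(S)`, so an
absolute grid would explore only the over-smoothed regime.  Both index
kinds search the same 13-point log-spaced grid (1e-4…1e6, relative);
criterion ties resolve toward the smoother fit.  A positive-evidence rule
(ΔBIC > 2, the conventional threshold) is required before the surface may
leave the additive linear-in-q limit: deviations accepted on weaker
evidence degraded held-out performance symmetrically in both directions.

**Orientation and scaling.**  After fitting, the index sign is set so that
the Spearman correlation between training indices and the per-subject
quantile nearest p = 0.5 is non-negative ("higher index ↔ higher median
expression"); negating a centered functional term preserves the centering
constraint.  Note the convention fixes interpretability, not risk
direction: a fitted index can be protective.  Indices entering association
models are standardized by subtracting the median and dividing by the IQR
(type-7 quartiles); training-set constants can be frozen and reused.

**Cross-fitting.**  k-fold cross-fitting assigns subjects to folds
stratified by event/class status (so every training remainder retains both
classes or at least one event), deterministically from a seed; each
subject's index comes from the model trained on the other folds.

## Comparators

MSI is the per-subject mean of (log) CSI.  The OQ biomarker selects, on
training data, the grid probability whose z-scored quantile column has the
largest absolute Wald z in a univariable logistic or Cox fit (ties toward
the smaller probability, non-converged columns skipped); the frozen
selection is applied to test subjects as the raw quantile value at p*.

## Synthetic studies

Each subject's log-CSI distribution is a 2-component normal mixture.
Group-level parameters define four scenarios (values on the log scale):

| scenario | low risk (π, μ₁, μ₂, σ₁, σ₂) | high risk |
|---|---|---|
| A | 0.65, 2.0, 3.0, 0.6, 0.8 | 0.65, 2.0, 4.8, 0.6, 0.6 |
| B | 0.65, 2.5, 3.0, 0.6, 0.8 | 0.65, 1.2, 3.0, 0.6, 0.8 |
| C | 0.65, 2.0, 4.0, 0.6, 0.6 | 0.65, 2.0, 5.2, 0.6, 0.6 |
| D | identical to low-risk A | identical |

A mimics a distinctive high-expression component (bimodal high-risk group),
B loss of expression, C a shifted high-expression fraction, D the null.

Subject-level random effects perturb every mixture parameter: a **shared
brightness shift** `δᵢ ~ N(0, τ²)`, τ = 0.7, added to both component means
(emulating tissue-level staining variability — the dominant technical
source of between-tissue variation in immunofluorescence), independent
per-component mean perturbations (sd 0.15), log-normal sd perturbations
(sd 0.15 on the log), and a logit-normal mixing-weight perturbation
(sd 0.3).  The shift scale was calibrated (τ ∈ {0.3, 0.5, 0.7}, frozen at
0.7) so the generator reproduces the qualitative performance structure
this class of methods is designed for: quantile-contrast indices can
cancel a shared shift, while single-location biomarkers (MSI, any single
quantile) cannot, so QI/nlQI clearly dominate MSI and OQ.  A consequence
worth stating: with the group contrasts being location shifts and the
shift noise removing usable curvature in q, the *optimal* surface is
essentially linear — the nonlinear index then matches, but does not beat,
the linear index (their AUCs tie exactly in most replicates because of the
nesting design).

Outcomes depend on the group label only.  Binary: Bernoulli with
P(event | high) = 0.61 and a group odds ratio of 2.5 (hence
P(event | low) ≈ 0.3849).  Survival: Weibull by inverse transform,
shape 1.5, rate 0.1, group log hazard ratio log 2.5, administrative
censoring at t = 3 (roughly 60–70% censoring).  All draws flow from
independent sub-streams of one seed; a study pair is bitwise reproducible
from (spec, seed).

What the generator does **not** emulate: spatial structure (cell
coordinates carry no information), batch effects beyond the scalar
brightness shift, segmentation error, and heavy-tailed contamination.
Passing benchmarks therefore demonstrate correct behaviour under the
stated mixture model, not performance on real images.

## Evaluation harness

Test-set discrimination is the Mann–Whitney AUC (pairwise U-statistic with
half credit for ties).  For each biomarker the score direction is fixed on
the *training* half (the sign making training AUC ≥ 0.5) and applied to
the test half — a biomarker that decreases with risk is scored fairly
while null biomarkers keep an unbiased test AUC around 0.5.  Benchmarks
sweep scenarios × sizes × grids × outcome kinds with per-replicate seeds
derived from one master seed; replicate studies are shared across grid
sizes so grid comparisons are paired; failed fits are recorded with their
reason and excluded from summaries, never silently dropped.

Default benchmark conditions follow the study design the simulator
emulates: 120 subjects per group (40–240 supported), 100 cells per subject
(20–200), 19 or 99 quantiles, 200 replicate pairs.  The shipped acceptance
suite runs 50 replicates per condition to keep the full test run within a
few minutes on one CPU; the problem sizes used are stated in the tests.

## Known limitations

* Smoothing selection is grid search with warm starts, not REML; extremely
  small training sets (≲ 20 subjects) trigger a warning and may select
  degenerate smoothing.
* The Cox fitter supports Breslow ties only; no stratification,
  time-varying effects, or frailty.
* The OQ comparator deliberately implements a simple max-|z| selection
  with train/test separation; published variants with multiplicity
  adjustment may differ.
* Quantile values outside the training q-range are clamped; indices for
  subjects far outside the training distribution are extrapolations of a
  boundary-constant surface.
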