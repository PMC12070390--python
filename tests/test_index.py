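"""Index training/application: closed-form limits, orientation, centering,
standardization, serialization and cross-fitting."""

import warnings

import numpy as np
import pandas as pd
import pytest

import quantindex as qi
from quantindex.index import (
    BiomarkerVector,
    FittedIndexModel,
    IndexConfig,
    compute_index,
    crossfit,
    sign_adjust,
    standardize,
    train_index_model,
)
from quantindex.models import BinaryOutcome
from quantindex.quantiles import ProbabilityGrid, QuantileMatrix
from quantindex.splines import BasisSpec


def _linear_model(grid, n_basis=1, coefficients=(1.0,), sign=1, centers=None):
    spec = BasisSpec(n_basis=n_basis, degree=0)
    k = spec.n_basis
    return FittedIndexModel(
        kind="linear_QI", outcome_family="binomial", grid=grid,
        basis_p=spec, coefficients=np.asarray(coefficients, float),
        column_centers=np.zeros(k) if centers is None else np.asarray(centers),
        sign=sign, intercept=0.0,
    )


@pytest.fixture
def outcome_for(rng):
    def make(Q, signal="mean", family="binomial"):
        x = Q.values.mean(axis=1) if signal == "mean" else rng.normal(size=Q.n_subjects)
        x = (x - x.mean()) / x.std()
        if family == "binomial":
            p = 1 / (1 + np.exp(-1.5 * x))
            return BinaryOutcome(list(Q.subject_ids), (rng.random(len(p)) < p) * 1.0)
        raise NotImplementedError
    return make


class TestComputeIndex:
    def test_unit_weight_gives_riemann_mean(self, random_quantile_matrix):
        """β ≡ 1 with no centering: QI_i is the mean of tabulated quantiles."""
        Q = random_quantile_matrix
        model = _linear_model(Q.grid)
        v = compute_index(model, Q)
        np.testing.assert_allclose(v.values, Q.values.mean(axis=1), atol=1e-12)

    def test_zero_coefficients_zero_index(self, random_quantile_matrix):
        Q = random_quantile_matrix
        model = _linear_model(Q.grid, coefficients=(0.0,))
        np.testing.assert_allclose(compute_index(model, Q).values, 0.0)

    def test_linear_in_coefficients_and_order_invariant(self, random_quantile_matrix):
        Q = random_quantile_matrix
        m1 = _linear_model(Q.grid, n_basis=4, coefficients=[1, 0, 2, -1.0])
        m2 = _linear_model(Q.grid, n_basis=4, coefficients=[2, 0, 4, -2.0])
        v1 = compute_index(m1, Q).values
        v2 = compute_index(m2, Q).values
        np.testing.assert_allclose(v2, 2 * v1, atol=1e-12)
        perm = np.random.default_rng(3).permutation(Q.n_subjects)
        Qp = QuantileMatrix(
            [Q.subject_ids[i] for i in perm], Q.grid, Q.values[perm], Q.scale_tag
        )
        vp = compute_index(m1, Qp).values
        np.testing.assert_allclose(vp, v1[perm], atol=1e-12)

    def test_grid_mismatch_rejected(self, random_quantile_matrix):
        Q = random_quantile_matrix
        model = _linear_model(ProbabilityGrid.default(9))
        with pytest.raises(ValueError, match="grid"):
            compute_index(model, Q)

    def test_cells_are_retabulated_on_model_grid(self, random_quantile_matrix):
        Q = random_quantile_matrix
        model = _linear_model(Q.grid)
        cells = pd.DataFrame({
            "subject_id": ["a"] * 7, "csi": np.exp([1, 2, 3, 4, 5, 6, 7.0]),
        })
        v = compute_index(model, cells=cells)
        Qa = qi.tabulate_quantiles(cells, Q.grid)
        assert v.values[0] == pytest.approx(Qa.values.mean())


class TestTrainedModels:
    def test_training_enforces_identifiability_and_orientation(
        self, random_quantile_matrix, outcome_for
    ):
        Q = random_quantile_matrix
        model = train_index_model(Q, outcome_for(Q), kind="nonlinear_nlQI")
        # centered training contributions sum to zero for the stored fit
        raw = FittedIndexModel(**{**model.__dict__, "sign": 1})
        contributions = compute_index(raw, Q).values
        assert np.mean(contributions) == pytest.approx(0.0, abs=1e-10)
        # orientation: positive rank correlation with the median quantile
        from scipy.stats import spearmanr

        idx = compute_index(model, Q).values
        assert spearmanr(idx, Q.median_column()).statistic >= 0

    def test_mean_signal_recovers_consistent_weight_sign(self, rng):
        """Outcome driven by the mean of Q: fitted β(p) keeps one sign."""
        frames = []
        for i in range(150):
            mu = rng.normal(2.5, 0.6)
            frames.append(pd.DataFrame({
                "subject_id": f"s{i:03d}",
                "csi": np.exp(rng.normal(mu, 0.5, size=80)),
            }))
        Q = qi.tabulate_quantiles(pd.concat(frames, ignore_index=True))
        x = Q.values.mean(axis=1)
        x = (x - x.mean()) / x.std()
        y = (rng.random(150) < 1 / (1 + np.exp(-2 * x))) * 1.0
        model = train_index_model(
            Q, BinaryOutcome(list(Q.subject_ids), y), kind="linear_QI"
        )
        # the index tracks the driver, with positive orientation after the
        # sign adjustment (the driver here IS a monotone mean functional)
        idx = compute_index(model, Q).values
        assert np.corrcoef(idx, x)[0, 1] >= 0.8

    def test_degenerate_predictor_rejected(self):
        grid = ProbabilityGrid.default(9)
        Q = QuantileMatrix([f"s{i}" for i in range(30)], grid, np.ones((30, 9)))
        y = np.r_[np.ones(15), np.zeros(15)]
        with pytest.raises(ValueError, match="degenerate"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train_index_model(Q, BinaryOutcome(list(Q.subject_ids), y))

    def test_shifted_quantiles_shift_indices_only(self, random_quantile_matrix,
                                                  outcome_for):
        """A constant added to every quantile function leaves the linear
        index fit equivalent up to re-centering (test indices shift only)."""
        Q = random_quantile_matrix
        outcome = outcome_for(Q)
        m0 = train_index_model(Q, outcome, kind="linear_QI")
        Qs = QuantileMatrix(Q.subject_ids, Q.grid, Q.values + 5.0, Q.scale_tag)
        m1 = train_index_model(Qs, outcome, kind="linear_QI")
        v0 = compute_index(m0, Q).values
        v1 = compute_index(m1, Qs).values
        assert np.corrcoef(v0, v1)[0, 1] == pytest.approx(1.0, abs=1e-6)


class TestSignAdjust:
    def test_negated_model_is_flipped(self, random_quantile_matrix, outcome_for):
        Q = random_quantile_matrix
        model = train_index_model(Q, outcome_for(Q), kind="linear_QI")
        bad = FittedIndexModel(**{
            **model.__dict__,
            "coefficients": -model.coefficients, "sign": 1,
        })
        fixed = sign_adjust(bad, Q)
        assert fixed.sign == -1
        np.testing.assert_allclose(
            compute_index(fixed, Q).values, compute_index(model, Q).values
        )

    def test_involution_and_identity(self, random_quantile_matrix, outcome_for):
        Q = random_quantile_matrix
        model = train_index_model(Q, outcome_for(Q), kind="linear_QI")
        once = sign_adjust(model, Q)
        twice = sign_adjust(once, Q)
        np.testing.assert_allclose(once.coefficients, twice.coefficients)
        assert once.sign == twice.sign

    def test_constant_medians_warn_and_keep_sign(self):
        grid = ProbabilityGrid.default(5)
        r = np.random.default_rng(0)
        lower = np.sort(r.uniform(0.0, 0.9, size=(6, 2)), axis=1)
        upper = np.sort(r.uniform(1.1, 2.0, size=(6, 2)), axis=1)
        vals = np.hstack([lower, np.ones((6, 1)), upper])  # constant medians
        Q = QuantileMatrix([f"s{i}" for i in range(6)], grid, vals)
        model = _linear_model(Q.grid, n_basis=4, coefficients=[1, 2, 3, 4.0])
        with pytest.warns(UserWarning):
            out = sign_adjust(model, Q)
        assert out.sign == 1


class TestStandardize:
    def test_known_values(self):
        v = BiomarkerVector(list("abcde"), [1, 2, 3, 4, 5.0], "QI")
        s = standardize(v)
        np.testing.assert_allclose(s.values, [-1, -0.5, 0, 0.5, 1])
        assert s.standardized

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        v1 = standardize(BiomarkerVector(list(range(50)), x, "QI"))
        v2 = standardize(BiomarkerVector(list(range(50)), 3 * x + 7, "QI"))
        np.testing.assert_allclose(v1.values, v2.values, atol=1e-12)
        assert np.median(v1.values) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_training_constants(self, rng):
        x = rng.normal(size=20)
        v = BiomarkerVector(list(range(20)), x, "QI")
        s = standardize(v, center=1.0, scale=2.0)
        np.testing.assert_allclose(s.values, (x - 1.0) / 2.0)

    def test_degenerate_iqr_rejected(self):
        v = BiomarkerVector(list("abc"), [1.0, 1.0, 1.0], "QI")
        with pytest.raises(ValueError, match="IQR"):
            standardize(v)


class TestSerialization:
    def test_round_trip_reproduces_indices_bitwise(
        self, random_quantile_matrix, outcome_for, tmp_path
    ):
        Q = random_quantile_matrix
        model = train_index_model(Q, outcome_for(Q), kind="nonlinear_nlQI")
        path = tmp_path / "model.json"
        model.save(path)
        back = FittedIndexModel.load(path)
        v0 = compute_index(model, Q).values
        v1 = compute_index(back, Q).values
        assert np.array_equal(v0, v1)

    def test_corrupt_file_raises_schema_error(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="corrupt|incompatible"):
            FittedIndexModel.load(path)
        path.write_text('{"schema_version": 99}')
        with pytest.raises(ValueError):
            FittedIndexModel.load(path)


class TestCrossfit:
    def test_leave_one_out_mechanics(self, rng):
        frames = []
        for i in range(6):
            frames.append(pd.DataFrame({
                "subject_id": f"s{i}",
                "csi": np.exp(rng.normal(2 + 0.5 * (i % 2), 0.4, 30)),
            }))
        Q = qi.tabulate_quantiles(pd.concat(frames, ignore_index=True))
        y = np.array([1.0, 0, 1, 0, 1, 0])
        outcome = BinaryOutcome(list(Q.subject_ids), y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = crossfit(Q, outcome, k=3, seed=0, kind="linear_QI")
        assert len(v.values) == 6
        assert np.all(np.isfinite(v.values))

    def test_seed_determinism(self, random_quantile_matrix, outcome_for):
        Q = random_quantile_matrix
        outcome = outcome_for(Q)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v1 = crossfit(Q, outcome, k=4, seed=7, kind="linear_QI")
            v2 = crossfit(Q, outcome, k=4, seed=7, kind="linear_QI")
        assert np.array_equal(v1.values, v2.values)

    def test_bad_fold_count_rejected(self, random_quantile_matrix, outcome_for):
        with pytest.raises(ValueError):
            crossfit(random_quantile_matrix,
                     outcome_for(random_quantile_matrix), k=1)
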