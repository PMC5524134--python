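import numpy as np
import pytest
from sklearn.linear_model import Ridge

from mhcmotif import (
    ALPHABET,
    SMMRegressor,
    ScoringMatrix,
    encode,
    encode_peptides,
    predict,
    train,
    transform_affinity,
)
from mhcmotif.smm import _ridge_sweep


def _normal_equations_oracle(H, y, lam):
    """Independent closed-form ridge solve with unpenalized intercept.

    Solves the joint stationarity system
        [H'H + lam I   H'1] [w]   [H'y]
        [1'H           n  ] [b] = [1'y]
    by a dense solve; deliberately distinct from the package's
    centered-eigendecomposition route.
    """
    n, d = H.shape
    ones = np.ones(n)
    A = np.zeros((d + 1, d + 1))
    A[:d, :d] = H.T @ H + lam * np.eye(d)
    A[:d, d] = H.T @ ones
    A[d, :d] = ones @ H
    A[d, d] = n
    rhs = np.concatenate([H.T @ y, [ones @ y]])
    sol = np.linalg.solve(A, rhs)
    return sol[:d], float(sol[d])


class TestTransformAffinity:
    def test_log10_of_nanomolar(self):
        assert transform_affinity(1000.0) == pytest.approx(3.0)

    def test_ceiling_clamp(self):
        assert transform_affinity(100000.0) == pytest.approx(np.log10(50000))

    def test_floor_clamp(self):
        assert transform_affinity(0.01) == pytest.approx(-1.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(ValueError):
            transform_affinity(bad)

    def test_vectorized_matches_scalar(self):
        vals = np.array([0.5, 70.0, 60000.0])
        np.testing.assert_allclose(
            transform_affinity(vals), [transform_affinity(v) for v in vals]
        )


class TestEncode:
    def test_poly_alanine_hits_first_column_of_each_block(self):
        H = encode_peptides(["AAAAAAAAA"])
        assert H.shape == (1, 180)
        np.testing.assert_array_equal(np.flatnonzero(H[0]), np.arange(0, 180, 20))

    def test_shape_is_n_by_20L(self, planted_dataset):
        design = encode(planted_dataset)
        assert design.H.shape == (len(planted_dataset), 180)
        assert design.length == 9

    def test_each_row_has_L_ones_one_per_block(self, planted_dataset):
        H = encode(planted_dataset).H
        assert np.all(H.sum(axis=1) == 9)
        blocks = H.reshape(len(H), 9, 20)
        assert np.all(blocks.sum(axis=2) == 1)

    def test_identical_peptides_identical_rows(self):
        H = encode_peptides(["SIINFEKLV", "SIINFEKLV"])
        np.testing.assert_array_equal(H[0], H[1])

    def test_noncanonical_residue_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            encode_peptides(["SIINFEKLX"])


class TestTrain:
    def test_huge_lambda_shrinks_matrix_to_zero(self, small_dataset):
        mat = train(small_dataset, lambdas=(1e9,), folds=3, seed=0)
        assert np.abs(mat.values).max() < 1e-4
        y = transform_affinity(small_dataset.ic50s)
        assert mat.intercept == pytest.approx(y.mean(), abs=1e-3)

    def test_tiny_lambda_matches_ols_normal_equations(self):
        # full-column-rank synthetic design (non-binary so H'H is well conditioned)
        rng = np.random.default_rng(5)
        H = rng.normal(size=(400, 60))
        y = rng.normal(size=400)
        (w, b), = _ridge_sweep(H, y, [1e-8])
        w_ols, b_ols = _normal_equations_oracle(H, y, 1e-8)
        np.testing.assert_allclose(w, w_ols, atol=1e-4)
        assert b == pytest.approx(b_ols, abs=1e-4)

    def test_fixed_lambda_agrees_with_iterated_closed_form(self, planted_dataset):
        design = encode(planted_dataset)
        for lam in (0.1, 10.0):
            (w, b), = _ridge_sweep(design.H, design.y, [lam])
            w_o, b_o = _normal_equations_oracle(design.H, design.y, lam)
            np.testing.assert_allclose(w, w_o, atol=1e-6)
            assert b == pytest.approx(b_o, abs=1e-6)

    def test_fixed_lambda_agrees_with_sklearn_ridge(self, planted_dataset):
        design = encode(planted_dataset)
        ref = Ridge(alpha=1.0, fit_intercept=True, solver="svd").fit(design.H, design.y)
        (w, b), = _ridge_sweep(design.H, design.y, [1.0])
        np.testing.assert_allclose(w, ref.coef_, atol=1e-8)
        assert b == pytest.approx(ref.intercept_, abs=1e-8)

    def test_planted_matrix_recovered_after_centering(self, planted_model, planted_dataset):
        mat = train(planted_dataset, seed=2)
        truth = planted_model.true_matrix
        fit_c = mat.values - mat.values.mean(axis=0)
        truth_c = truth - truth.mean(axis=0)
        assert np.abs(fit_c - truth_c).mean() < 0.1

    def test_training_scores_correlate_with_targets(self, planted_dataset):
        mat = train(planted_dataset, seed=2)
        y = transform_affinity(planted_dataset.ic50s)
        scores = [predict(mat, p) for p in planted_dataset.peptides]
        assert np.corrcoef(scores, y)[0, 1] > 0.9

    def test_ridge_norm_monotone_in_lambda(self, small_dataset):
        design = encode(small_dataset)
        fits = _ridge_sweep(design.H, design.y, [1e-3, 1e-1, 10.0, 1e3])
        norms = [np.linalg.norm(w) for w, _ in fits]
        assert norms == sorted(norms, reverse=True)

    def test_target_shift_moves_only_the_intercept(self, small_dataset):
        design = encode(small_dataset)
        reg1 = SMMRegressor(seed=4).fit(design.H, design.y)
        reg2 = SMMRegressor(seed=4).fit(design.H, design.y + 5.0)
        np.testing.assert_allclose(reg1.coef_, reg2.coef_, atol=1e-9)
        assert reg2.intercept_ - reg1.intercept_ == pytest.approx(5.0, abs=1e-9)

    def test_same_seed_reproduces_lambda_and_matrix(self, small_dataset):
        m1 = train(small_dataset, seed=9)
        m2 = train(small_dataset, seed=9)
        assert m1.lambda_used == m2.lambda_used
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_nonpositive_lambda_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="> 0"):
            train(small_dataset, lambdas=(0.0, 1.0))

    def test_fewer_distinct_peptides_than_folds_rejected(self):
        H = encode_peptides(["AAAAAAAAA"] * 10 + ["CCCCCCCCC"] * 10)
        with pytest.raises(ValueError, match="distinct"):
            SMMRegressor(folds=5).fit(H, np.zeros(20))

    def test_sklearn_params_roundtrip(self):
        reg = SMMRegressor(folds=7, seed=3)
        clone = SMMRegressor(**reg.get_params())
        assert clone.get_params() == reg.get_params()


class TestPredict:
    def test_zero_matrix_returns_intercept(self, zero_matrix):
        assert predict(zero_matrix, "SIINFEKLV") == 3.0

    def test_single_active_cell(self):
        values = np.zeros((20, 9))
        values[ALPHABET.index("L"), 1] = -1.0
        mat = ScoringMatrix("X", values, intercept=3.0)
        assert predict(mat, "ALAAAAAAA") == pytest.approx(2.0)
        assert predict(mat, "AAAAAAAAA") == pytest.approx(3.0)

    def test_length_mismatch_rejected(self, zero_matrix):
        with pytest.raises(ValueError, match="length"):
            predict(zero_matrix, "SIINFEKL")

    def test_estimator_predict_matches_functional_predict(self, small_dataset):
        design = encode(small_dataset)
        reg = SMMRegressor(seed=0).fit(design.H, design.y)
        got = reg.predict(small_dataset.peptides[:5])
        want = [predict(reg.matrix_, p) for p in small_dataset.peptides[:5]]
        np.testing.assert_allclose(got, want, atol=1e-12)
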