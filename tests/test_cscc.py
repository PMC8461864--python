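"""CSCCS estimator: centering algebra, lasso paths, and direction calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labcmap import cscc
from labcmap.synthetic import EHRSimConfig, TrueDrugEffects, generate_ehr
from tests.conftest import manual_dataset


def fixed_effects_ols(y, X, patient_index):
    """Brute-force oracle: least squares with one explicit intercept per
    patient, i.e. the full [Z | X] regression; returns the beta block."""
    n = len(y)
    patients = np.unique(patient_index)
    Z = np.zeros((n, len(patients)))
    for col, p in enumerate(patients):
        Z[patient_index == p, col] = 1.0
    full = np.hstack([Z, X])
    coef, *_ = np.linalg.lstsq(full, y, rcond=None)
    return coef[len(patients):]


class TestBuildDesign:
    def test_shape_contract(self):
        ds = manual_dataset(
            [
                ("p1", 0, "L", 1.0, (0,)), ("p1", 1, "L", 2.0, (1,)),
                ("p2", 0, "L", 3.0, (0,)), ("p2", 1, "L", 4.0, (1,)),
            ],
            drugs=["d"], labs=["L"],
        )
        d = cscc.build_design(ds, "L")
        assert d.y.shape == (4,)
        np.testing.assert_array_equal(d.patient_index, [0, 0, 1, 1])

    def test_patient_without_lab_contributes_no_rows(self):
        ds = manual_dataset(
            [
                ("p1", 0, "L", 1.0, (0,)),
                ("p2", 0, "K", 3.0, (0,)),
            ],
            drugs=["d"], labs=["L", "K"],
        )
        d = cscc.build_design(ds, "L")
        assert d.patients == ["p1"]
        assert len(d.y) == 1

    def test_generated_row_count(self, small_effects):
        config = EHRSimConfig(
            n_patients=4, n_drugs=3, n_labs=2,
            measurements_per_patient=(3, 3), seed=0,
        )
        ds = generate_ehr(config, small_effects)
        d = cscc.build_design(ds, "lab_00")
        assert len(d.y) == 12

    def test_empty_design_errors(self):
        ds = manual_dataset(
            [("p1", 0, "L", np.nan, (0,))], drugs=["d"], labs=["L"]
        )
        with pytest.raises(ValueError, match="empty design"):
            cscc.build_design(ds, "L")


class TestCentering:
    def test_single_patient_mean_removed(self):
        y_c, _ = cscc.center_within_patient(
            np.array([1.0, 2.0, 3.0]), np.zeros((3, 1)), np.array([0, 0, 0])
        )
        np.testing.assert_allclose(y_c, [-1.0, 0.0, 1.0])

    def test_singleton_patient_centers_to_zero(self):
        y_c, X_c = cscc.center_within_patient(
            np.array([5.0]), np.array([[1.0]]), np.array([0])
        )
        np.testing.assert_allclose(y_c, [0.0])
        np.testing.assert_allclose(X_c, [[0.0]])

    def test_two_patient_hand_example(self):
        y = np.array([1.0, 3.0, 10.0, 14.0])
        X = np.array([[0.0], [1.0], [1.0], [1.0]])
        idx = np.array([0, 0, 1, 1])
        y_c, X_c = cscc.center_within_patient(y, X, idx)
        np.testing.assert_allclose(y_c, [-1.0, 1.0, -2.0, 2.0])
        np.testing.assert_allclose(X_c[:, 0], [-0.5, 0.5, 0.0, 0.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_blocks_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        n_patients = rng.integers(1, 6)
        sizes = rng.integers(1, 5, n_patients)
        idx = np.repeat(np.arange(n_patients), sizes)
        y = rng.normal(size=idx.size)
        X = rng.integers(0, 2, (idx.size, 3)).astype(float)
        y_c, X_c = cscc.center_within_patient(y, X, idx)
        for p in range(n_patients):
            assert abs(y_c[idx == p].sum()) < 1e-10
            np.testing.assert_allclose(
                X_c[idx == p].sum(axis=0), 0.0, atol=1e-10
            )


class TestFitCSCC:
    def test_lambda_above_max_gives_exact_null(self):
        rng = np.random.default_rng(0)
        idx = np.repeat(np.arange(10), 4)
        X = rng.integers(0, 2, (40, 3)).astype(float)
        y = rng.normal(size=40)
        y_c, X_c = cscc.center_within_patient(y, X, idx)
        lam_max = np.abs(X_c.T @ y_c).max()
        beta = cscc.fit_cscc(y_c, X_c, lam_max * 1.001)
        assert (beta == 0).all()

    def test_noise_free_exact_recovery(self, noise_free_dataset, small_effects):
        d = cscc.build_design(noise_free_dataset, "lab_00")
        y_c, X_c = cscc.center_within_patient(d.y, d.X, d.patient_index)
        beta = cscc.fit_cscc(y_c, X_c, 0.0)
        np.testing.assert_allclose(beta, small_effects.matrix[:, 0], atol=1e-10)

    def test_matches_fixed_effects_ols_oracle(self):
        """Centering + lambda=0 equals the brute-force per-patient-intercept
        least squares: the algebraic core of the estimator."""
        effects = TrueDrugEffects.random_sparse(3, 1, 2, magnitude=1.5, seed=5)
        config = EHRSimConfig(
            n_patients=5, n_drugs=3, n_labs=1,
            measurements_per_patient=(4, 4), noise_sd=1.0,
            exposure_prob=0.5, seed=5,
        )
        ds = generate_ehr(config, effects)
        d = cscc.build_design(ds, "lab_00")
        y_c, X_c = cscc.center_within_patient(d.y, d.X, d.patient_index)
        beta = cscc.fit_cscc(y_c, X_c, 0.0)
        oracle = fixed_effects_ols(d.y, d.X, d.patient_index)
        np.testing.assert_allclose(beta, oracle, atol=1e-8)

    def test_shift_invariance(self):
        """Adding a per-patient constant is absorbed by the baseline."""
        rng = np.random.default_rng(3)
        idx = np.repeat(np.arange(8), 5)
        X = rng.integers(0, 2, (40, 4)).astype(float)
        y = rng.normal(size=40) + X @ np.array([1.0, 0, 0, -1.0])
        shifts = rng.normal(scale=50, size=8)
        y_shifted = y + shifts[idx]
        for lam in (0.0, 2.0):
            b1 = cscc.fit_cscc(*cscc.center_within_patient(y, X, idx), lam)
            b2 = cscc.fit_cscc(*cscc.center_within_patient(y_shifted, X, idx), lam)
            np.testing.assert_allclose(b1, b2, atol=1e-8)

    def test_monotone_sparsity_along_grid(self):
        rng = np.random.default_rng(9)
        idx = np.repeat(np.arange(30), 5)
        X = rng.integers(0, 2, (150, 10)).astype(float)
        y = rng.normal(size=150) + X[:, 0] * 2 - X[:, 5]
        y_c, X_c = cscc.center_within_patient(y, X, idx)
        grid = cscc.default_lambda_grid(y_c, X_c)
        supports = [
            int((cscc.fit_cscc(y_c, X_c, lam) != 0).sum()) for lam in grid
        ]
        # grid is descending in lambda, so support sizes must be non-decreasing
        assert all(a <= b for a, b in zip(supports, supports[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            cscc.fit_cscc(np.array([np.nan]), np.array([[1.0]]), 0.0)


class TestSelectLambda:
    def _centered(self, seed=0, beta=None, n_patients=40):
        rng = np.random.default_rng(seed)
        idx = np.repeat(np.arange(n_patients), 5)
        X = rng.integers(0, 2, (idx.size, 4)).astype(float)
        signal = X @ beta if beta is not None else 0.0
        y = rng.normal(size=idx.size) + signal
        y_c, X_c = cscc.center_within_patient(y, X, idx)
        return y_c, X_c, idx

    def test_single_value_grid(self):
        y_c, X_c, idx = self._centered()
        assert cscc.select_lambda(y_c, X_c, idx, grid=[0.7]) == 0.7

    def test_fewer_patients_than_folds(self):
        y_c, X_c, idx = self._centered(n_patients=3)
        with pytest.raises(ValueError, match="fewer than"):
            cscc.select_lambda(y_c, X_c, idx, folds=5)

    def test_null_data_selects_empty_support(self):
        empty = 0
        for seed in range(10):
            y_c, X_c, idx = self._centered(seed=seed)
            lam = cscc.select_lambda(y_c, X_c, idx, seed=seed)
            empty += (cscc.fit_cscc(y_c, X_c, lam) == 0).all()
        assert empty >= 9

    def test_strong_effect_stays_in_support(self):
        y_c, X_c, idx = self._centered(seed=1, beta=np.array([3.0, 0, 0, 0]))
        lam = cscc.select_lambda(y_c, X_c, idx, seed=1)
        beta = cscc.fit_cscc(y_c, X_c, lam)
        assert beta[0] > 0

    def test_deterministic_given_seed(self):
        y_c, X_c, idx = self._centered(seed=2)
        assert cscc.select_lambda(y_c, X_c, idx, seed=3) == cscc.select_lambda(
            y_c, X_c, idx, seed=3
        )


class TestPvaluesAndDirections:
    def test_empty_support_all_ones(self):
        p = cscc.coef_pvalues(
            np.zeros(3), np.zeros(10), np.zeros((10, 3)), np.repeat([0, 1], 5)
        )
        np.testing.assert_array_equal(p, 1.0)

    def test_strong_effect_significant(self):
        effects = TrueDrugEffects(
            np.array([[3.0], [0.0]]), ["drug_000", "drug_001"], ["lab_00"]
        )
        config = EHRSimConfig(
            n_patients=50, n_drugs=2, n_labs=1, noise_sd=0.1,
            exposure_prob=0.4, seed=2,
        )
        ds = generate_ehr(config, effects)
        d = cscc.build_design(ds, "lab_00")
        y_c, X_c = cscc.center_within_patient(d.y, d.X, d.patient_index)
        beta = cscc.fit_cscc(y_c, X_c, 0.5)
        p = cscc.coef_pvalues(beta, y_c, X_c, d.patient_index)
        assert p[0] < 0.05

    def test_df_exhausted_warns_and_returns_ones(self, caplog):
        # 2 patients x 2 rows: n - N - s = 4 - 2 - 3 < 0
        idx = np.array([0, 0, 1, 1])
        beta = np.array([0.1, -0.2, 0.3])
        y_c = np.array([1.0, -1.0, 2.0, -2.0])
        X_c = np.random.default_rng(0).normal(size=(4, 3))
        with caplog.at_level("WARNING"):
            p = cscc.coef_pvalues(beta, y_c, X_c, idx)
        np.testing.assert_array_equal(p, 1.0)
        assert "degrees of freedom" in caplog.text

    @pytest.mark.parametrize(
        "beta, p, expected",
        [(0.5, 0.01, 1.0), (-0.3, 0.2, 0.0), (0.0, 0.5, 0.0), (-0.4, 0.01, -1.0)],
    )
    def test_direction_rules(self, beta, p, expected):
        fit = cscc.CSCCSFit(
            lab_id="L", drugs=["d"],
            beta=np.array([beta]), pvalues=np.array([p]), lam=0.1,
        )
        assert cscc.call_drug_directions(fit)[0] == expected


class TestBuildDrugEffectVectors:
    def test_noise_free_sign_pattern_recovered(self):
        mat = np.array([[2.0, 0.0], [0.0, -1.5], [0.0, 0.0]])
        effects = TrueDrugEffects(
            mat, ["drug_000", "drug_001", "drug_002"], ["lab_00", "lab_01"]
        )
        config = EHRSimConfig(
            n_patients=30, n_drugs=3, n_labs=2, noise_sd=0.0,
            exposure_prob=0.4, seed=1,
        )
        ds = generate_ehr(config, effects)
        dev = cscc.build_drug_effect_vectors(ds, min_patients=1, seed=1)
        np.testing.assert_array_equal(dev.signs.to_numpy(), np.sign(mat))
        assert dev.signs.shape == (3, 2)

    def test_min_patient_threshold_excludes_all(self, noise_free_dataset):
        dev = cscc.build_drug_effect_vectors(
            noise_free_dataset, min_patients=1000, seed=0
        )
        assert (dev.signs.to_numpy() == 0).all()

    def test_empty_dataset_rejected(self, small_effects):
        config = EHRSimConfig(n_patients=0, n_drugs=3, n_labs=2, seed=0)
        ds = generate_ehr(config, small_effects)
        with pytest.raises(ValueError, match="empty"):
            cscc.build_drug_effect_vectors(ds, min_patients=1)
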