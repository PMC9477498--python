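"""Sparse varying-coefficient model: spline basis, solver exactness,
cross-validation, repetition protocol and permutation specificity."""

import numpy as np
import pandas as pd
import pytest

from netstage import (
    build_basis,
    cv_lambda,
    fit_svc,
    lambda_max,
    permutation_specificity,
    repeat_and_summarize,
    standardize_inputs,
)
from netstage.svc import _Workspace, default_lambda_grid, kkt_residuals


def _scenario(n=150, K=15, p=6, noise=0.4, seed=0, beta=None):
    """One planted predictor with a declining coefficient curve."""
    rng = np.random.default_rng(seed)
    reps = n // K
    bins = np.repeat(np.arange(1, K + 1), reps)
    X = rng.normal(size=(bins.size, p))
    if beta is None:
        beta = np.linspace(0.9, 0.3, K)
    y = beta[bins - 1] * X[:, 0] + noise * rng.normal(size=bins.size)
    y, X = standardize_inputs(y, X, np.zeros(bins.size))
    return y, X, bins, beta


# ----------------------------------------------------------------------
class TestBasis:
    @pytest.mark.parametrize("K,M", [(6, 4), (20, 6), (30, 10), (12, 12)])
    def test_partition_of_unity_and_shape(self, K, M):
        basis = build_basis(K, M)
        assert basis.B.shape == (K, M)
        np.testing.assert_allclose(basis.B.sum(axis=1), 1.0, atol=1e-12)
        # Gram is symmetric PSD
        np.testing.assert_allclose(basis.omega, basis.omega.T, atol=1e-14)
        assert np.linalg.eigvalsh(basis.omega).min() > -1e-12

    def test_minimal_basis_reproduces_cubics(self):
        K = 20
        basis = build_basis(K, 4, degree=3)
        t = np.arange(1, K + 1, dtype=float)
        target = 0.5 * t**3 - 2 * t**2 + t - 7
        coef, *_ = np.linalg.lstsq(basis.B, target, rcond=None)
        np.testing.assert_allclose(basis.B @ coef, target, rtol=1e-9)

    def test_too_many_basis_functions_rejected(self):
        with pytest.raises(ValueError):
            build_basis(4, 6)
        with pytest.raises(ValueError):
            build_basis(10, 3, degree=3)


class TestStandardize:
    def test_already_standard_is_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = rng.normal(size=40)
        y = (y - y.mean()) / y.std(ddof=1)
        y2, X2 = standardize_inputs(y, X, np.zeros(40))
        np.testing.assert_allclose(X2, X, atol=1e-12)
        np.testing.assert_allclose(y2, y, atol=1e-12)

    def test_sample_sd_convention(self):
        y = np.array([0.0, 1.0, 2.0])
        X = np.array([[1.0], [2.0], [3.0]])
        _, X2 = standardize_inputs(y, X, np.zeros(3))
        np.testing.assert_allclose(X2[:, 0], [-1.0, 0.0, 1.0])

    def test_groupwise_centering(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        g = np.repeat(["a", "b"], 15)
        y2, X2 = standardize_inputs(y, X, g)
        for grp in ("a", "b"):
            m = g == grp
            np.testing.assert_allclose(X2[m].mean(0), 0.0, atol=1e-12)
            np.testing.assert_allclose(X2[m].std(0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_named(self):
        X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize_inputs(np.arange(3.0), X, np.zeros(3))


# ----------------------------------------------------------------------
class TestSolver:
    def test_ridge_at_zero_matches_normal_equations(self):
        y, X, bins, _ = _scenario(seed=1)
        basis = build_basis(15, 5)
        fit = fit_svc(y, X, bins, basis, 0.0, penalty="ridge")
        ws = _Workspace(X, bins, basis)
        g_ref, *_ = np.linalg.lstsq(ws.Z, y, rcond=None)
        got = (fit.gamma @ basis.omega_sqrt.T).ravel()
        np.testing.assert_allclose(got, g_ref, rtol=1e-6, atol=1e-8)

    def test_all_groups_zero_at_lambda_max(self):
        y, X, bins, _ = _scenario(seed=2)
        basis = build_basis(15, 5)
        lam_hi = lambda_max(y, X, bins, basis)
        fit = fit_svc(y, X, bins, basis, lam_hi * (1 + 1e-10))
        assert fit.selected == []
        fit_below = fit_svc(y, X, bins, basis, lam_hi * 0.95)
        assert fit_below.selected != []

    @pytest.mark.parametrize("frac", [0.5, 0.1, 0.02])
    def test_kkt_conditions_at_convergence(self, frac):
        y, X, bins, _ = _scenario(seed=3)
        basis = build_basis(15, 5)
        ws = _Workspace(X, bins, basis)
        lam = lambda_max(y, X, bins, basis, _ws=ws) * frac
        fit = fit_svc(y, X, bins, basis, lam, _ws=ws)
        assert fit.converged
        g = (fit.gamma @ basis.omega_sqrt.T).ravel()
        active, zero = kkt_residuals(ws, y, g, lam)
        assert active.max() < 1e-4
        assert zero.max() < 1e-8

    def test_objective_no_worse_than_zero_solution(self):
        y, X, bins, _ = _scenario(seed=4)
        basis = build_basis(15, 5)
        lam = lambda_max(y, X, bins, basis) * 0.3
        fit = fit_svc(y, X, bins, basis, lam)
        obj_at_zero = 0.5 * float(y @ y) / y.size
        assert fit.objective <= obj_at_zero + 1e-12

    def test_moderate_lambda_selects_only_planted_group(self):
        y, X, bins, _ = _scenario(n=300, K=15, p=8, noise=0.4, seed=5)
        basis = build_basis(15, 5)
        lam = lambda_max(y, X, bins, basis) * 0.5
        fit = fit_svc(y, X, bins, basis, lam)
        assert fit.selected == [0]

    def test_active_sets_nest_along_the_path(self):
        y, X, bins, _ = _scenario(n=200, K=10, p=8, noise=0.8, seed=6)
        basis = build_basis(10, 5)
        lam_hi = lambda_max(y, X, bins, basis)
        grid = default_lambda_grid(lam_hi, 12, 1e-3)
        prev: set = set()
        warm = None
        ws = _Workspace(X, bins, basis)
        for lam in grid:  # descending
            fit = fit_svc(y, X, bins, basis, lam, warm_start=warm, _ws=ws)
            warm = (fit.gamma @ basis.omega_sqrt.T).ravel()
            assert prev <= set(fit.selected)
            prev = set(fit.selected)

    def test_ridge_and_group_lasso_agree_on_kept_predictor(self):
        y, X, bins, beta = _scenario(n=300, K=15, p=8, noise=0.4, seed=7)
        basis = build_basis(15, 5)
        lam = lambda_max(y, X, bins, basis) * 0.3
        gl = fit_svc(y, X, bins, basis, lam, penalty="group_lasso")
        rd = fit_svc(y, X, bins, basis, lam, penalty="ridge")
        # ridge cannot zero groups; compare the dominant coefficient curve
        norms = np.linalg.norm(rd.beta_curves, axis=1)
        assert int(np.argmax(norms)) == 0
        assert gl.selected == [0]
        r = np.corrcoef(gl.beta_curves[0], rd.beta_curves[0])[0, 1]
        assert r > 0.95


# ----------------------------------------------------------------------
class TestCrossValidation:
    def test_singleton_grid_is_returned(self):
        y, X, bins, _ = _scenario(seed=8)
        basis = build_basis(15, 5)
        lam, curve = cv_lambda(y, X, bins, basis, grid=np.array([0.3]), rng=0)
        assert lam == 0.3 and len(curve) == 1

    def test_min_rule_is_argmin_of_curve(self):
        y, X, bins, _ = _scenario(seed=9)
        basis = build_basis(15, 5)
        lam, curve = cv_lambda(y, X, bins, basis, n_lambda=12, rng=1,
                               rule="min")
        sel = curve.loc[curve["lam"] == lam, "cv_error"].iloc[0]
        assert sel <= curve["cv_error"].min() + 1e-12

    def test_one_se_rule_never_below_min_lambda(self):
        y, X, bins, _ = _scenario(seed=10)
        basis = build_basis(15, 5)
        lam_min, _ = cv_lambda(y, X, bins, basis, n_lambda=12, rng=2,
                               rule="min")
        lam_1se, _ = cv_lambda(y, X, bins, basis, n_lambda=12, rng=2,
                               rule="1se")
        assert lam_1se >= lam_min

    def test_selected_lambda_retains_planted_predictor(self):
        y, X, bins, _ = _scenario(n=300, K=15, p=8, noise=0.4, seed=11)
        basis = build_basis(15, 5)
        lam, _ = cv_lambda(y, X, bins, basis, n_lambda=12, rng=3, rule="1se")
        fit = fit_svc(y, X, bins, basis, lam)
        assert 0 in fit.selected


class TestRepetitions:
    def test_noiseless_truth_selected_always(self):
        y, X, bins, _ = _scenario(n=100, K=10, p=5, noise=1e-8, seed=12)
        basis = build_basis(10, 5)
        s = repeat_and_summarize(y, X, bins, basis, n_rep=5, threshold=4,
                                 n_lambda=10)
        assert s.frequency.iloc[0] == 5
        assert (s.frequency.iloc[1:] == 0).all()
        assert s.kept == ["x0"]
        assert ((s.frequency >= 0) & (s.frequency <= 5)).all()

    def test_identity_permutation_reproduces_summary(self):
        y, X, bins, _ = _scenario(n=100, K=10, p=4, seed=13)
        basis = build_basis(10, 4)
        ref = repeat_and_summarize(y, X, bins, basis, n_rep=3, threshold=2,
                                   n_lambda=8, base_seed=7)
        null = permutation_specificity(
            y, X, bins, basis, n_perm_datasets=1, n_rep=3, threshold=2,
            n_lambda=8, base_seed=7, permutations=[np.arange(y.size)],
        )
        pd.testing.assert_series_equal(
            null.iloc[0], ref.frequency, check_names=False
        )

    @pytest.mark.parametrize("M", [4, 6, 8, 10])
    def test_selection_stable_across_basis_sizes(self, M):
        y, X, bins, _ = _scenario(n=300, K=15, p=6, noise=0.4, seed=14)
        basis = build_basis(15, M)
        lam, _ = cv_lambda(y, X, bins, basis, n_lambda=10, rng=4, rule="1se")
        fit = fit_svc(y, X, bins, basis, lam)
        assert 0 in fit.selected
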