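"""LASSO solver oracles (soft-thresholding, exhaustive active-set search,
KKT conditions), check-mark validity, consensus selection, and post-OLS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methylgrowth import (InsufficientValidRunsError, checkmark_valid,
                          consensus_select, cv_lasso, post_selection_ols,
                          screen_covariates, site_level_reanalysis)
from methylgrowth.selection import LassoFit


# ---------------------------------------------------------------------------
# independent verifiers (no reliance on the solver's internals)


def kkt_violation(Xs: np.ndarray, yc: np.ndarray, lam: float,
                  coef: np.ndarray) -> float:
    """Max violation of the L1 subgradient conditions at (lam, coef).

    For the objective (1/2n)||yc - Xs b||^2 + lam ||b||_1 the gradient of the
    smooth part is g = -Xs'(yc - Xs b)/n; optimality requires g_j = -lam *
    sign(b_j) on the active set and |g_j| <= lam elsewhere.
    """
    n = len(yc)
    g = Xs.T @ (yc - Xs @ coef) / n
    active = coef != 0
    v_active = np.abs(g[active] - lam * np.sign(coef[active]))
    v_inactive = np.maximum(np.abs(g[~active]) - lam, 0.0)
    return max(v_active.max() if active.any() else 0.0,
               v_inactive.max() if (~active).any() else 0.0)


def exhaustive_lasso(Xc: np.ndarray, yc: np.ndarray, lam: float):
    """Global lasso minimizer by enumeration over active sets and signs.

    For every support S and sign vector s the stationary candidate solves
    (X_S'X_S) b = X_S'y - n*lam*s; a candidate is admissible when its signs
    match s.  Returns (coef, objective) of the best admissible candidate.
    """
    n, p = Xc.shape

    def objective(b):
        r = yc - Xc @ b
        return (r @ r) / (2 * n) + lam * np.abs(b).sum()

    best = np.zeros(p)
    best_obj = objective(best)
    for k in range(1, p + 1):
        for S in itertools.combinations(range(p), k):
            XS = Xc[:, S]
            G = XS.T @ XS
            for signs in itertools.product([-1.0, 1.0], repeat=k):
                s = np.asarray(signs)
                try:
                    b_S = np.linalg.solve(G, XS.T @ yc - n * lam * s)
                except np.linalg.LinAlgError:
                    continue
                if not np.all(np.sign(b_S) == s):
                    continue
                b = np.zeros(p)
                b[list(S)] = b_S
                obj = objective(b)
                if obj < best_obj:
                    best, best_obj = b, obj
    return best, best_obj


def _orthonormal_design(n, p, seed=0):
    """Centered X with X'X = n I."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    return Q * np.sqrt(n)


# ---------------------------------------------------------------------------


class TestCvLasso:
    def test_orthonormal_equals_soft_thresholding(self):
        n, p = 60, 5
        X = _orthonormal_design(n, p, seed=1)
        rng = np.random.default_rng(2)
        y = X @ np.array([2.0, -1.5, 0.0, 0.5, 0.0]) + 0.1 * rng.normal(size=n)
        fit = cv_lasso(pd.DataFrame(X), pd.Series(y), k_folds=5,
                       standardize=False, solver_tol=1e-12, seed=0)
        ols = X.T @ (y - y.mean()) / n
        for i in range(len(fit.lambdas)):
            lam = fit.lambdas[i]
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            np.testing.assert_allclose(fit.coef_path[:, i], expected,
                                       atol=1e-8)

    def test_matches_exhaustive_active_set_search(self):
        n, p = 40, 6
        rng = np.random.default_rng(3)
        X = rng.normal(size=(n, p))
        y = X[:, 0] * 1.5 - X[:, 3] * 0.8 + rng.normal(size=n) * 0.5
        fit = cv_lasso(pd.DataFrame(X), pd.Series(y), k_folds=5,
                       standardize=False, solver_tol=1e-12, seed=0)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        for i in (5, 30, 60, 90):
            lam = fit.lambdas[i]
            b_star, obj_star = exhaustive_lasso(Xc, yc, lam)
            b_fit = fit.coef_path[:, i]
            r = yc - Xc @ b_fit
            obj_fit = (r @ r) / (2 * n) + lam * np.abs(b_fit).sum()
            assert obj_fit <= obj_star + 1e-8
            np.testing.assert_allclose(b_fit, b_star, atol=1e-6)

    def test_kkt_conditions_along_reported_path(self, small_cohort):
        from methylgrowth import aggregate, map_probes_to_genes, derive_outcomes
        models = map_probes_to_genes(small_cohort.probe_annotation,
                                     small_cohort.gene_intervals)
        table = aggregate(small_cohort.betas, models)
        X = table.values.T
        y = derive_outcomes(small_cohort.phenotypes)["cwg_z"]
        fit = cv_lasso(X, y, solver_tol=1e-10, seed=0)
        Xs = (X[fit.feature_names].values - fit.x_mean) / fit.x_scale
        yc = y.values - y.values.mean()
        for i in range(0, len(fit.lambdas), 7):
            v = kkt_violation(Xs, yc, fit.lambdas[i], fit.coef_path_std[:, i])
            assert v < 1e-6

    def test_unpenalized_limit_matches_ols(self):
        n, p = 50, 4
        rng = np.random.default_rng(4)
        X = rng.normal(size=(n, p))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.2 * rng.normal(size=n)
        fit = cv_lasso(pd.DataFrame(X), pd.Series(y), k_folds=5,
                       lambda_min_ratio=1e-8, solver_tol=1e-14, seed=0)
        ols = np.linalg.lstsq(np.c_[np.ones(n), X], y, rcond=None)[0][1:]
        np.testing.assert_allclose(fit.coef_path[:, -1], ols, atol=1e-6)

    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 8)))
        y = pd.Series(rng.normal(size=30))
        fit = cv_lasso(X, y, k_folds=5, seed=0)
        assert np.all(fit.coef_path[:, 0] == 0.0)

    def test_zero_variance_outcome_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="zero-variance outcome"):
            cv_lasso(X, pd.Series(np.ones(20)), k_folds=5)

    def test_selected_bounded_by_sample_count(self, small_cohort):
        from methylgrowth import aggregate, map_probes_to_genes, derive_outcomes
        models = map_probes_to_genes(small_cohort.probe_annotation,
                                     small_cohort.gene_intervals)
        table = aggregate(small_cohort.betas, models)
        y = derive_outcomes(small_cohort.phenotypes)["cwg_z"]
        fit = cv_lasso(table.values.T, y, seed=0)
        assert len(fit.selected) <= len(y)


class TestCheckmark:
    def _fake_fit(self, cv_mse, idx_min, n_selected):
        L = len(cv_mse)
        coef = np.zeros((3, L))
        coef[:n_selected, idx_min] = 1.0
        return LassoFit(lambdas=np.geomspace(1, 1e-3, L), coef_path=coef,
                        intercept_path=np.zeros(L), coef_path_std=coef,
                        cv_mse=np.asarray(cv_mse, dtype=float),
                        cv_se=np.full(L, 0.01), idx_min=idx_min,
                        feature_names=["a", "b", "c"], seed=0,
                        standardized=True, x_mean=np.zeros(3),
                        x_scale=np.ones(3))

    def test_interior_minimum_with_selection_is_valid(self):
        cv = np.r_[np.linspace(1.0, 0.4, 10), np.linspace(0.42, 0.9, 10)]
        assert checkmark_valid(self._fake_fit(cv, 9, 2))

    def test_endpoint_minimum_invalid(self):
        cv = np.linspace(1.0, 0.2, 20)  # minimum at the last grid point
        assert not checkmark_valid(self._fake_fit(cv, 19, 2))

    def test_empty_selection_invalid(self):
        cv = np.r_[np.linspace(1.0, 0.4, 10), np.linspace(0.42, 0.9, 10)]
        assert not checkmark_valid(self._fake_fit(cv, 9, 0))

    def test_shallow_minimum_invalid(self):
        cv = np.full(20, 0.5)
        cv[9] = 0.499  # improvement below one CV standard error (0.01)
        assert not checkmark_valid(self._fake_fit(cv, 9, 2))

    def test_pure_noise_cv_curve_invalid(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(80, 30)))
        y = pd.Series(rng.normal(size=80))
        fit = cv_lasso(X, y, seed=1)
        assert not checkmark_valid(fit)


class TestConsensus:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(80, 20)),
                         columns=[f"G{i}" for i in range(20)])
        y = pd.Series(X.values[:, :3] @ np.array([1.0, -1.0, 0.8]),
                      index=X.index)  # noiseless
        return X, y

    def test_noiseless_signal_unanimous_consensus(self, planted):
        X, y = planted
        cons = consensus_select(X, y, base_seed=0)
        assert cons.n_valid_runs == 10
        sets = [frozenset(r.selected) for r in cons.runs]
        assert len(set(sets)) == 1
        assert (cons.frequencies == 10).all()
        assert set(cons.consensus) == {"G0", "G1", "G2"}

    def test_tie_broken_by_cv_mse(self, planted):
        X, y = planted
        cons = consensus_select(X, y, base_seed=0)
        # every run selects the identical set, so all tie on overlap
        chosen = cons.runs[cons.chosen_run]
        assert chosen.cv_mse_min == min(r.cv_mse_min for r in cons.runs)

    def test_pure_noise_raises_insufficient_valid(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(50, 40)))
        y = pd.Series(rng.normal(size=50))
        with pytest.raises(InsufficientValidRunsError, match="insufficient"):
            consensus_select(X, y, base_seed=0, max_attempts=12)

    def test_reproducible_given_base_seed(self, planted):
        X, y = planted
        a = consensus_select(X, y, base_seed=3)
        b = consensus_select(X, y, base_seed=3)
        assert a.consensus == b.consensus
        assert [r.seed for r in a.runs] == [r.seed for r in b.runs]
        assert a.chosen_run == b.chosen_run

    def test_max_attempts_validation(self, planted):
        X, y = planted
        with pytest.raises(ValueError):
            consensus_select(X, y, max_attempts=5, n_target_valid=10)


class TestPostSelectionOls:
    def test_identity_predictor(self):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=25))
        X = pd.DataFrame({"g": y.values}, index=y.index)
        res = post_selection_ols(X, y, ["g"])
        assert res.coefficients["g"] == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients["const"] == pytest.approx(0.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        beta = np.array([0.5, -1.2, 2.0])
        y = pd.Series(3.0 + X.values @ beta)  # noiseless
        res = post_selection_ols(X, y, list("abc"))
        D = np.c_[np.ones(20), X.values]
        expected = np.linalg.solve(D.T @ D, D.T @ y.values)
        np.testing.assert_allclose(res.coefficients.values, expected,
                                   atol=1e-10)

    def test_orthogonal_predictors_give_nonpositive_adj_r2(self):
        rng = np.random.default_rng(11)
        n = 40
        X = pd.DataFrame(_orthonormal_design(n, 3, seed=12), columns=list("abc"))
        y = pd.Series(rng.normal(size=n))
        y = y - pd.Series(X.values @ (X.values.T @ y.values) / n)  # orthogonalize
        res = post_selection_ols(X, y, list("abc"))
        assert res.adj_r2 <= 0

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=30)})
        y = pd.Series(a + rng.normal(size=30))
        with pytest.warns(UserWarning, match="collinear"):
            res = post_selection_ols(X, y, ["a", "b", "c"])
        assert len(res.dropped_collinear) == 1

    def test_empty_selection_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="empty"):
            post_selection_ols(X, pd.Series(np.arange(10.0)), [])

    def test_marginal_regressions_reported(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = pd.Series(X["a"] * 2 + rng.normal(size=30) * 0.1)
        res = post_selection_ols(X, y, ["a", "b"])
        assert set(res.marginal.index) == {"a", "b"}
        assert res.marginal.loc["a", "p_value"] < 1e-6
        assert {"coef", "p_value", "r2", "p_value_bh"} <= set(res.marginal)


class TestScreenCovariates:
    def test_covariate_equal_to_outcome_selected(self):
        rng = np.random.default_rng(15)
        cov = pd.DataFrame({"x": rng.normal(size=40),
                            "z": rng.normal(size=40)})
        y = pd.Series(cov["x"].values, index=cov.index)
        res = screen_covariates(cov, y, seed=0)
        assert "x" in res["selected"]

    def test_near_constant_covariate_dropped(self):
        rng = np.random.default_rng(16)
        cov = pd.DataFrame({"x": rng.normal(size=48),
                            "smoking": [1] + [0] * 47})
        y = pd.Series(rng.normal(size=48), index=cov.index)
        res = screen_covariates(cov, y, seed=0)
        assert res["dropped_near_constant"] == ["smoking"]


class TestSiteLevelReanalysis:
    def test_single_cpg_gene_duplicates_gene_result(self):
        rng = np.random.default_rng(17)
        n = 60
        betas = pd.DataFrame(rng.uniform(0.1, 0.9, size=(8, n)),
                             index=[f"cg{i}" for i in range(8)],
                             columns=[f"S{j}" for j in range(n)])
        membership = {f"G{i}": [f"cg{i}"] for i in range(8)}
        y = pd.Series(2.0 * betas.loc["cg2"].values, index=betas.columns)
        genes = pd.DataFrame({g: betas.loc[m].mean(axis=0)
                              for g, m in membership.items()}).T
        cons = consensus_select(genes.T, y, base_seed=0)
        res = site_level_reanalysis(betas, membership, cons.consensus, y,
                                    base_seed=0)
        assert set(res["consensus_sites"]) == {
            m[0] for g, m in membership.items() if g in cons.consensus}
        assert res["genes_without_sites"] == []
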