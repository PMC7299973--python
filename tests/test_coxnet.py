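"""Elastic-net Cox path: lambda grid, KKT conditions, CV behaviour."""

import numpy as np
import pytest

from snpsurv.coxnet import (
    coxnet_path,
    cv_coxnet,
    kkt_check,
    lambda_grid,
    _loglik,
)
from snpsurv.simulate import EffectSpec, SNPSpec, simulate_cohort
from snpsurv.survival import cox_fit


@pytest.fixture(scope="module")
def problem():
    """Non-degenerate N=60, P=5 problem with one real effect."""
    specs = [SNPSpec(f"s{j}", 0.3) for j in range(5)]
    gm, ct = simulate_cohort(60, specs, [EffectSpec("s0", "dominant", np.log(2.5))],
                             seed=3)
    t, e = ct.endpoint("pfs")
    return gm.codes.copy(), t, e


class TestLambdaGrid:
    def test_all_zero_at_and_above_lambda_max(self, problem):
        X, t, e = problem
        lams = lambda_grid(X, t, e, alpha=0.5)
        path = coxnet_path(X, t, e, 0.5, lambdas=np.array([lams[0] * 2, lams[0]]))
        assert (path.coefs == 0).all()
        assert kkt_check(X, t, e, path, 0) == 0.0
        assert kkt_check(X, t, e, path, 1) == 0.0

    def test_lambda_max_is_tight(self, problem):
        # just below lambda_max at least one coefficient activates
        X, t, e = problem
        lam_max = lambda_grid(X, t, e, 0.5)[0]
        path = coxnet_path(X, t, e, 0.5, lambdas=np.array([lam_max, lam_max * 0.98]))
        assert path.n_nonzero[1] >= 1

    def test_matches_bisection_oracle_single_predictor(self, problem):
        X, t, e = problem
        x = X[:, :1]
        alpha = 0.7
        lam_max = lambda_grid(x, t, e, alpha)[0]
        # bisection on "is the solution all-zero at lambda?"
        lo, hi = lam_max / 4, lam_max * 4

        def all_zero(lam):
            p = coxnet_path(x, t, e, alpha, lambdas=np.array([lam]))
            return p.n_nonzero[0] == 0

        for _ in range(40):
            mid = np.sqrt(lo * hi)
            if all_zero(mid):
                hi = mid
            else:
                lo = mid
        assert lam_max == pytest.approx(hi, rel=1e-3)

    def test_halving_alpha_doubles_lambda_max(self, problem):
        X, t, e = problem
        a = lambda_grid(X, t, e, 1.0)[0]
        b = lambda_grid(X, t, e, 0.5)[0]
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_ridge_unsupported(self, problem):
        X, t, e = problem
        with pytest.raises(ValueError, match="alpha"):
            lambda_grid(X, t, e, 0.0)


class TestPath:
    def test_lambda_to_zero_matches_unpenalized(self, problem):
        X, t, e = problem
        lam_max = lambda_grid(X, t, e, 0.5)[0]
        path = coxnet_path(
            X, t, e, 0.5, lambdas=np.array([lam_max, lam_max * 1e-8]),
            cd_tol=1e-9, outer_tol=1e-9,
        )
        ref = cox_fit(X, t, e, ties="breslow")
        np.testing.assert_allclose(path.coefs[:, 1], ref.beta, atol=1e-4)

    def test_kkt_audit_along_path(self, problem):
        X, t, e = problem
        path = coxnet_path(X, t, e, 0.5, n_lambda=40, cd_tol=1e-9, outer_tol=1e-8)
        for li in range(path.lambdas.size):
            assert kkt_check(X, t, e, path, li) < 1e-6

    def test_warm_start_objective_never_worse(self, problem):
        # the solution at each lambda must score at least as well as its
        # warm start (previous lambda's solution) under the same penalty
        X, t, e = problem
        path = coxnet_path(X, t, e, 0.5, n_lambda=40)
        n = X.shape[0]
        sd = X.std(axis=0)

        def objective(beta_std, lam):
            beta = beta_std / sd
            pen = lam * (0.5 * np.abs(beta_std).sum()
                         + 0.25 * (beta_std**2).sum())
            return -_loglik(X, t, e, beta) / n + pen

        for li in range(1, path.lambdas.size):
            lam = path.lambdas[li]
            own = objective(path.coefs_std[:, li], lam)
            warm = objective(path.coefs_std[:, li - 1], lam)
            assert own <= warm + 1e-10

    def test_path_continuity(self, problem):
        X, t, e = problem
        path = coxnet_path(X, t, e, 0.5, n_lambda=60)
        jumps = np.abs(np.diff(path.coefs_std, axis=1)).max(axis=0)
        assert jumps.max() < 0.25

    def test_missing_values_rejected(self, problem):
        X, t, e = problem
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            coxnet_path(X, t, e, 0.5)


class TestCrossValidation:
    def test_deterministic_given_fold_seed(self, problem):
        X, t, e = problem
        a = cv_coxnet(X, t, e, 0.5, fold_seed=11)
        b = cv_coxnet(X, t, e, 0.5, fold_seed=11)
        np.testing.assert_array_equal(a.folds, b.folds)
        np.testing.assert_array_equal(a.mean_deviance, b.mean_deviance)
        np.testing.assert_array_equal(a.nonzero_idx, b.nonzero_idx)
        assert a.lambda_min == b.lambda_min

    def test_fold_sizes_differ_by_at_most_one(self, problem):
        X, t, e = problem
        cv = cv_coxnet(X, t, e, 0.5, k=3, fold_seed=0)
        sizes = np.bincount(cv.folds)
        assert sizes.max() - sizes.min() <= 1

    def test_lambda_min_attains_minimum(self, problem):
        X, t, e = problem
        cv = cv_coxnet(X, t, e, 0.5, fold_seed=2)
        assert cv.mean_deviance[cv.lambda_min_idx] == cv.mean_deviance.min()

    def test_null_problem_selects_nothing_much(self):
        # pure-noise designs: the lambda_min nonzero set is empty or tiny
        sizes = []
        for rep in range(12):
            specs = [SNPSpec(f"s{j}", 0.3) for j in range(30)]
            gm, ct = simulate_cohort(80, specs, [], seed=500 + rep)
            t, e = ct.endpoint("pfs")
            cv = cv_coxnet(gm.codes, t, e, 0.5, fold_seed=rep)
            sizes.append(cv.nonzero_idx.size)
        assert np.median(sizes) <= 2

    def test_planted_strong_effect_selected(self):
        # HR 3 at MAF 0.3, n=300: planted SNP in the lambda_min set in the
        # large majority of replicates
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            specs = [SNPSpec(f"s{j}", 0.3) for j in range(20)]
            gm, ct = simulate_cohort(
                300, specs, [EffectSpec("s0", "additive", np.log(3))],
                seed=900 + rep,
            )
            t, e = ct.endpoint("pfs")
            cv = cv_coxnet(gm.codes, t, e, 0.5, fold_seed=rep)
            hits += int(0 in cv.nonzero_idx)
        assert hits >= 9
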