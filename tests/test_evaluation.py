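import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_design
from gwpred import (
    EvaluationReport,
    decompose,
    estimate_error_variance,
    evaluate_path,
    fit_ols,
    fit_path,
    lambda_grid,
    mse,
    r2_determination,
    r2_pearson,
    rank_agreement,
    rank_individuals,
    ridge_cp_criterion,
    ridge_df,
    select_model,
    write_table1,
    write_table2,
)
from gwpred.evaluation import read_table1, read_table2
from gwpred.solvers import FitResult, LambdaGrid, PathResult


class TestMSE:
    def test_exact_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mse(y, y) == 0.0

    def test_direct_arithmetic(self):
        assert mse(np.array([0.0, 0.0]), np.array([1.0, -1.0])) == 1.0

    def test_joint_permutation_invariance(self, rng):
        y, yhat = rng.normal(size=(2, 30))
        perm = rng.permutation(30)
        assert np.isclose(mse(y, yhat), mse(y[perm], yhat[perm]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros(3), np.zeros(4))


class TestPearsonR2:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 2.0])
        assert np.isclose(r2_pearson(y, y), 1.0)

    def test_affine_invariance(self, rng):
        """The blind spot: a*yhat + b scores identically under r^2."""
        y = rng.normal(size=50)
        yhat = 0.6 * y + rng.normal(scale=0.5, size=50)
        base = r2_pearson(y, yhat)
        for a, b in [(2.0, 7.0), (0.1, -3.0), (5.0, 0.0)]:
            assert np.isclose(r2_pearson(y, a * yhat + b), base, atol=1e-12)
            # ...while MSE and R^2 both move
            assert not np.isclose(mse(y, a * yhat + b), mse(y, yhat))
            assert not np.isclose(
                r2_determination(y, a * yhat + b), r2_determination(y, yhat)
            )

    def test_scaled_prediction_still_one(self):
        y = np.array([0.0, 1.0, 2.0])
        assert np.isclose(r2_pearson(y, np.array([0.0, 2.0, 4.0])), 1.0)

    def test_constant_predictor_is_zero_with_warning(self):
        y = np.array([0.0, 1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="constant"):
            assert r2_pearson(y, np.ones(3)) == 0.0

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="var\\(y\\)"):
            r2_pearson(np.ones(3), np.array([0.0, 1.0, 2.0]))


class TestDeterminationR2:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 2.0])
        assert np.isclose(r2_determination(y, y), 1.0)

    def test_mean_predictor_scores_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        assert np.isclose(r2_determination(y, np.full(3, y.mean())), 0.0)

    def test_can_be_negative(self):
        # 1 - 5/2 = -1.5 for yhat = 2y on y = [0,1,2]
        y = np.array([0.0, 1.0, 2.0])
        assert np.isclose(r2_determination(y, np.array([0.0, 2.0, 4.0])), -1.5)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant y"):
            r2_determination(np.ones(4), np.zeros(4))


class TestDecompose:
    def test_perfect_fit_degenerates(self):
        y = np.array([1.0, -1.0, 2.0, 0.0])
        rep = decompose(y, y)
        assert rep.mse == 0.0
        assert np.isclose(rep.r2_pearson, 1.0) and np.isclose(rep.r2_determination, 1.0)
        assert np.isclose(rep.cov_y_yhat, rep.var_y)
        assert np.isclose(rep.var_yhat, rep.var_y)

    def test_scaling_moves_cov_and_var_but_not_r2(self, rng):
        y = rng.normal(size=40)
        yhat = 0.5 * y + rng.normal(scale=0.3, size=40)
        base = decompose(y, yhat)
        c = 3.0
        scaled = decompose(y, c * yhat)
        assert np.isclose(scaled.var_yhat, c**2 * base.var_yhat)
        assert np.isclose(scaled.cov_y_yhat, c * base.cov_y_yhat)
        assert np.isclose(scaled.r2_pearson, base.r2_pearson)

    def test_matches_two_pass_moment_oracle(self):
        """100 random instances against definition-based moments, 1e-10."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            rep = decompose(y, yhat)
            vy = np.sum((y - y.mean()) ** 2) / n
            vh = np.sum((yhat - yhat.mean()) ** 2) / n
            cov = np.sum((y - y.mean()) * (yhat - yhat.mean())) / n
            assert abs(rep.var_y - vy) < 1e-10
            assert abs(rep.var_yhat - vh) < 1e-10
            assert abs(rep.cov_y_yhat - cov) < 1e-10
            assert abs(rep.mse - np.mean((y - yhat) ** 2)) < 1e-10
            # identity invariants
            assert abs(rep.r2_pearson - cov**2 / (vy * vh)) < 1e-10
            assert abs(
                rep.r2_determination - (1 - rep.n_test * rep.mse / (n * vy))
            ) < 1e-10


_vec = arrays(
    np.float64,
    st.shared(st.integers(3, 25), key="n"),
    elements=st.floats(-50, 50, allow_nan=False, width=64),
)


class TestMetricProperties:
    @settings(derandomize=True, max_examples=60)
    @given(y=_vec, yhat=_vec, a=st.floats(0.1, 5), b=st.floats(-10, 10))
    def test_identities_hold_for_arbitrary_vectors(self, y, yhat, a, b):
        """r^2 is affine-invariant in yhat and R^2 = 1 - n*MSE/TSS,
        whenever both statistics are defined."""
        if np.var(y) < 1e-8 or np.var(yhat) < 1e-8:
            return
        assert np.isclose(
            r2_pearson(y, a * yhat + b), r2_pearson(y, yhat), atol=1e-8
        )
        n = y.size
        tss = np.sum((y - y.mean()) ** 2)
        assert np.isclose(
            r2_determination(y, yhat), 1 - n * mse(y, yhat) / tss, atol=1e-9
        )


class TestRidgeCp:
    def test_df_limits(self, rng):
        X, _, _ = make_design(rng, 10, 4)
        assert ridge_df(X, 1e14) < 1e-6
        assert np.isclose(ridge_df(X, 1e-12), 4, atol=1e-6)

    def test_df_matches_brute_force_trace(self, rng):
        X = rng.normal(size=(6, 3))
        lam = 1.7
        brute = np.trace(X.T @ X @ np.linalg.inv(X.T @ X + lam * np.eye(3)))
        assert np.isclose(ridge_df(X, lam), brute, atol=1e-8)

    def test_criterion_requires_error_variance(self, rng):
        X, y, _ = make_design(rng, 12, 4)
        with pytest.raises(ValueError, match="error-variance"):
            ridge_cp_criterion(X, y, 1.0, None)

    def test_criterion_value(self, rng):
        X, y, _ = make_design(rng, 15, 4)
        s2 = estimate_error_variance(fit_ols(X, y), X, y)
        from gwpred import fit_ridge

        lam = 2.0
        beta = fit_ridge(X, y, lam).beta
        rss = np.sum((y - X @ beta) ** 2)
        expect = rss - 15 * s2.sigma2_e + 2 * s2.sigma2_e * ridge_df(X, lam)
        assert np.isclose(ridge_cp_criterion(X, y, lam, s2), expect)


def _manual_path(y_test, yhats, lams):
    """Path over an identity test design: each beta IS the prediction."""
    n = y_test.size
    fits = [FitResult(beta=b, lam=lam, method="LASSO") for b, lam in zip(yhats, lams)]
    path = PathResult(method="LASSO", grid=LambdaGrid(values=np.array(lams)), fits=fits)
    return evaluate_path(path, np.eye(n), y_test)


class TestSelectModel:
    def test_single_lambda_path(self, rng):
        y = rng.normal(size=5)
        path = _manual_path(y, [rng.normal(size=5)], [1.0])
        for crit in ("min_mse", "max_r2", "max_R2"):
            sel = select_model(path, crit)
            assert sel.best_lambda == 1.0 and sel.best_index == 0

    def test_exact_fit_wins_under_every_criterion(self, rng):
        y = rng.normal(size=6)
        path = _manual_path(y, [np.zeros(6) + 0.1, y.copy(), -y], [3.0, 2.0, 1.0])
        for crit in ("min_mse", "max_r2", "max_R2"):
            assert select_model(path, crit).best_index == 1

    def test_criteria_can_disagree_under_affine_distortion(self, rng):
        """The core failure mode: a shrunk-but-perfectly-correlated
        prediction wins r^2 while losing MSE (and hence R^2)."""
        y = rng.normal(size=40)
        noisy = y + rng.normal(scale=0.4, size=40)  # good MSE, imperfect r
        shrunk = 0.2 * y  # perfect correlation, terrible MSE
        path = _manual_path(y, [shrunk, noisy], [2.0, 1.0])
        assert select_model(path, "max_r2").best_index == 0
        assert select_model(path, "min_mse").best_index == 1
        assert select_model(path, "max_R2").best_index == 1

    def test_min_mse_and_max_R2_always_agree(self, rng):
        """Theorem check: R^2 is a monotone transform of MSE for fixed y."""
        y = rng.normal(size=25)
        yhats = [rng.normal(size=25) for _ in range(8)]
        path = _manual_path(y, yhats, list(np.geomspace(8, 1, 8)))
        assert (
            select_model(path, "min_mse").best_index
            == select_model(path, "max_R2").best_index
        )

    def test_ties_break_toward_larger_lambda(self, rng):
        y = rng.normal(size=5)
        same = rng.normal(size=5)
        path = _manual_path(y, [same.copy(), same.copy()], [2.0, 1.0])
        assert select_model(path, "min_mse").best_lambda == 2.0

    def test_cp_variant_matches_brute_force(self, rng):
        X, y, _ = make_design(rng, 30, 5)
        s2 = estimate_error_variance(fit_ols(X, y), X, y)
        grid = lambda_grid(X, y, n_lambda=10, min_ratio=0.01)
        path = fit_path(X, y, "RR", grid)
        sel = select_model(path, "cp_variant", X_train=X, y_train=y, sigma2_e=s2)
        brute = [ridge_cp_criterion(X, y, 30 * lam, s2) for lam in grid.values]
        assert sel.best_index == int(np.argmin(brute))
        assert sel.best_lambda in grid.values


class TestRanking:
    def test_top_k_descending(self):
        t = rank_individuals(np.array([1.0, 3.0, 2.0]), ["a", "b", "c"], 2)
        assert t.top_ids == ["b", "c"]
        assert np.allclose(t.predicted_values, [3.0, 2.0])

    def test_all_equal_ties_by_id(self):
        t = rank_individuals(np.ones(3), ["c", "a", "b"], 3)
        assert t.top_ids == ["a", "b", "c"]

    def test_full_ranking_is_permutation(self, rng):
        ids = [f"i{k}" for k in range(10)]
        t = rank_individuals(rng.normal(size=10), ids, 10)
        assert sorted(t.top_ids) == sorted(ids)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            rank_individuals(np.ones(3), ["a", "b", "c"], 4)


class TestRankAgreement:
    def test_identical_orderings(self):
        r = rank_agreement(list("abcde"), list("abcde"))
        assert np.isclose(r["spearman"], 1.0) and np.isclose(r["kendall"], 1.0)
        assert r["topk_overlap"] == 1.0

    def test_reversed_orderings(self):
        r = rank_agreement(list("abcde"), list("edcba"))
        assert np.isclose(r["spearman"], -1.0) and np.isclose(r["kendall"], -1.0)

    def test_adjacent_swap_tau(self):
        # one discordant pair out of C(5,2)=10 -> tau = 1 - 2/10 = 0.8
        r = rank_agreement(list("abcde"), list("abdce"))
        assert np.isclose(r["kendall"], 0.8)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            rank_agreement(list("abc"), list("abd"))

    def test_topk_overlap(self):
        r = rank_agreement(list("abcde"), list("baedc"), k=2)
        assert r["topk_overlap"] == 1.0  # {a,b} vs {b,a}


class TestTableIO:
    def test_table1_roundtrip_and_conventions(self, tmp_path):
        rep = EvaluationReport(
            mse=64.52, r2_pearson=0.455, r2_determination=0.449,
            cov_y_yhat=50.68, var_y=117.2, var_yhat=48.17, n_test=900,
        )
        f = tmp_path / "t1.csv"
        write_table1({"ALASSO": rep}, f, header_lines=["seed 1"])
        df = read_table1(f)
        assert df.loc[0, "method"] == "ALASSO"
        assert np.isclose(df.loc[0, "MSE"], 64.52)
        assert np.isclose(df.loc[0, "VAR_y"], 117.2)
        write_table1({"ALASSO": rep}, f, moment_convention="sample")
        df2 = read_table1(f)
        assert np.isclose(df2.loc[0, "VAR_y"], 117.2 * 900 / 899)
        assert np.isclose(df2.loc[0, "MSE"], 64.52)  # MSE untouched

    def test_table2_roundtrip(self, tmp_path):
        t = rank_individuals(np.array([3.0, 1.0, 2.0]), ["x", "y", "z"], 3)
        f = tmp_path / "t2.csv"
        write_table2({"RR/min_mse": t}, f)
        df = read_table2(f)
        assert df.loc[0, "selection"] == "RR/min_mse"
        assert list(df.loc[0, ["rank1", "rank2", "rank3"]]) == ["x", "z", "y"]
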