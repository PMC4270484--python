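"""Quantile normalization, lasso CV, consensus/difference models and
expression summaries."""

import numpy as np
import pandas as pd
import pytest

from orthopeaks import expression_model as em
from orthopeaks import synthetic_data as sd
from orthopeaks.genome_model import ExpressionTable


def expr_table(values: dict, stages=("ProE",), reps=(1,)):
    """values: gene -> fpkm (same at each stage/replicate unless callable)."""
    rows = []
    for g, v in values.items():
        for s in stages:
            for r in reps:
                rows.append({"gene_id": g, "stage": s, "replicate": r, "fpkm": v})
    return ExpressionTable(pd.DataFrame(rows))


class TestQuantileNormalize:
    def test_identical_matrices_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [0.0, 1.0, 2.0]})
        out = em.quantile_normalize([m.copy(), m.copy()])
        for o in out:
            pd.testing.assert_frame_equal(o, m)

    def test_mean_of_order_statistics(self):
        m1 = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        m2 = pd.DataFrame({"a": [10.0, 20.0, 30.0]})
        o1, o2 = em.quantile_normalize([m1, m2])
        np.testing.assert_allclose(o1["a"], [5.5, 11.0, 16.5])
        np.testing.assert_allclose(o2["a"], [5.5, 11.0, 16.5])

    def test_sorted_columns_identical_after(self, rng):
        m1 = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        m2 = pd.DataFrame(rng.gamma(2, 2, size=(50, 3)), columns=list("abc"))
        o1, o2 = em.quantile_normalize([m1, m2])
        for c in "abc":
            np.testing.assert_allclose(np.sort(o1[c]), np.sort(o2[c]))

    def test_ties_share_block_mean_rank_oracle(self):
        m1 = pd.DataFrame({"a": [1.0, 1.0, 5.0, 9.0]})
        m2 = pd.DataFrame({"a": [2.0, 4.0, 6.0, 8.0]})
        o1, _ = em.quantile_normalize([m1, m2])
        target = (np.sort(m1["a"]) + np.sort(m2["a"])) / 2  # [1.5,2.5,5.5,8.5]
        # tied inputs 1.0,1.0 share mean of the first two targets
        assert o1["a"][0] == o1["a"][1] == pytest.approx((1.5 + 2.5) / 2)
        assert o1["a"][2] == pytest.approx(5.5)

    def test_idempotent(self, rng):
        m1 = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        m2 = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        once = em.quantile_normalize([m1, m2])
        twice = em.quantile_normalize(once)
        for a, b in zip(once, twice):
            pd.testing.assert_frame_equal(a, b)

    def test_mismatched_columns_error(self):
        with pytest.raises(ValueError, match="columns"):
            em.quantile_normalize(
                [pd.DataFrame({"a": [1.0]}), pd.DataFrame({"b": [1.0]})]
            )


class TestFitLassoCV:
    def test_noiseless_single_predictor(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=200)})
        y = 2.0 * X["x1"].to_numpy()
        m = em.fit_lasso_cv(X, y, n_folds=5, one_se=False, seed=0)
        assert m.beta[0] == pytest.approx(2.0, abs=0.01)
        assert m.r_squared == pytest.approx(1.0, abs=1e-3)

    def test_lambda_max_all_zero(self, rng):
        X, y, _, _ = sd.make_regression_fixture(n=300, seed=1)
        m = em.fit_lasso_cv(X, y, n_folds=5, seed=1)
        from sklearn.linear_model import Lasso

        Xs = (X - X.mean()) / X.std(ddof=0)
        big = Lasso(alpha=m.lambda_grid[0] * 1.001).fit(Xs, y - np.mean(y))
        assert np.all(big.coef_ == 0)

    def test_one_se_lambda_not_below_best(self, rng):
        X, y, _, _ = sd.make_regression_fixture(n=500, seed=2)
        m = em.fit_lasso_cv(X, y, seed=2)
        assert m.lambda_1se >= m.lambda_best

    def test_path_monotone_in_lambda(self, rng):
        """Training RSS is non-increasing as lambda decreases."""
        from sklearn.linear_model import lasso_path

        X, y, _, _ = sd.make_regression_fixture(n=400, seed=3)
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        yc = y - y.mean()
        grid = np.geomspace(1.0, 1e-3, 30) * np.max(np.abs(Xs.T @ yc)) / len(y)
        _, coefs, _ = lasso_path(Xs, yc, alphas=grid)
        rss = [np.sum((yc - Xs @ coefs[:, i]) ** 2) for i in range(len(grid))]
        assert all(a >= b - 1e-8 for a, b in zip(rss, rss[1:]))
        # beta -> 0 entrywise at lambda_max
        assert np.allclose(coefs[:, 0], 0.0)

    def test_ols_limit_matches_closed_form(self):
        X, y, _, _ = sd.make_regression_fixture(n=800, seed=4)
        beta, intercept = em.fit_lasso_at(X, y, lam=1e-10)
        design = np.column_stack([np.ones(len(y)), X.to_numpy()])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        rel = np.abs(np.concatenate([[intercept], beta]) - ols) / np.abs(ols)
        assert rel.max() < 1e-6

    def test_constant_response_errors(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            em.fit_lasso_cv(X, np.ones(3), n_folds=3, seed=0)
        with pytest.raises(ValueError):
            em.fit_lasso_cv(X, np.arange(3.0), n_folds=5, seed=0)


class TestConsensusAndDifference:
    def test_consensus_close_to_species_fits(self):
        Xh, yh, beta, _ = sd.make_regression_fixture(n=800, seed=5)
        Xm, ym, _, _ = sd.make_regression_fixture(n=800, seed=6)
        fit = em.fit_consensus(Xh, yh, Xm, ym, seed=5)
        sep = em.fit_lasso_cv(Xh, yh, seed=5)
        bc = pd.Series(fit.model.beta, index=fit.model.marks)
        bs = pd.Series(sep.beta, index=sep.marks)
        assert np.abs(bc - bs).max() < 0.25
        for r2 in fit.r2_per_species.values():
            assert 0.45 < r2 < 0.75

    def test_one_species_empty_reduces_to_single_fit(self):
        Xh, yh, _, _ = sd.make_regression_fixture(n=400, seed=7)
        empty = Xh.iloc[:0]
        fit = em.fit_consensus(Xh, yh, empty, [], seed=7)
        only = em.fit_lasso_cv(Xh, yh, seed=7)
        np.testing.assert_allclose(fit.model.beta, only.beta)

    def test_scale_invariance_after_quantile_normalization(self):
        Xh, yh, _, _ = sd.make_regression_fixture(n=500, seed=8)
        Xm = Xh * 3.0 + 1.0  # disjoint scale, same ranks
        Xh_n, Xm_n = em.quantile_normalize([Xh, Xm])
        pd.testing.assert_frame_equal(Xh_n, Xm_n)

    def test_equal_marks_zero_difference_prediction(self):
        Xh, yh, _, _ = sd.make_regression_fixture(n=100, seed=9)
        model = em.fit_lasso_cv(Xh, yh, n_folds=5, seed=9)
        ys = pd.Series(yh, index=Xh.index)
        diff = em.predict_difference(model, Xh, Xh.copy(), ys, ys)
        np.testing.assert_allclose(diff.delta_pred, 0.0)

    def test_difference_r2_matches_closed_form(self):
        """Shared beta, independent noise: R2 of the difference model
        approaches Var(X_delta beta) / (Var(X_delta beta) + 2 sigma^2)."""
        rng = np.random.default_rng(10)
        Xh, _, beta, sigma = sd.make_regression_fixture(n=3000, seed=10)
        Xm = Xh + rng.normal(0, 0.8, Xh.shape)
        bvec = beta.to_numpy()
        yh = pd.Series(Xh.to_numpy() @ bvec + rng.normal(0, sigma, len(Xh)),
                       index=Xh.index)
        ym = pd.Series(Xm.to_numpy() @ bvec + rng.normal(0, sigma, len(Xh)),
                       index=Xh.index)
        model = em.LassoModel(
            marks=list(Xh.columns), beta=bvec, intercept=0.0,
            lambda_grid=np.array([0.0]), lambda_best=0.0, lambda_1se=0.0,
            cv_mean=np.array([0.0]), cv_se=np.array([0.0]), r_squared=1.0,
            cv_r_squared=1.0, x_mean=np.zeros(len(bvec)), x_scale=np.ones(len(bvec)),
        )
        diff = em.predict_difference(model, Xh, Xm, yh, ym)
        xd = (Xh.to_numpy() - Xm.to_numpy()) @ bvec
        closed = np.var(xd) / (np.var(xd) + 2 * sigma**2)
        assert diff.r_squared_all == pytest.approx(closed, abs=0.05)


class TestSpeciesSpecificGenes:
    def _tables(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        fh = {f"h{i:03d}": float(v) for i, v in enumerate(rng.gamma(2, 20, n))}
        fm = {f"m{i:03d}": float(v) for i, v in enumerate(rng.gamma(2, 20, n))}
        pairs = [(f"h{i:03d}", f"m{i:03d}") for i in range(n)]
        return expr_table(fh), expr_table(fm), pairs

    def test_decile_sizes(self):
        th, tm, pairs = self._tables(100)
        sets = em.define_species_specific_genes(th, tm, pairs, fraction=0.10)
        assert len(sets.human_specific) == 10
        assert len(sets.mouse_specific) == 10
        assert len(sets.rest) == 80
        assert not (set(sets.human_specific) & set(sets.mouse_specific))

    def test_ranking_is_signed_log_ratio(self):
        th = expr_table({"h1": 100.0, "h2": 1.0})
        tm = expr_table({"m1": 1.0, "m2": 100.0})
        sets = em.define_species_specific_genes(
            th, tm, [("h1", "m1"), ("h2", "m2")], fraction=0.5
        )
        assert sets.human_specific == ["h1"]
        assert sets.mouse_specific == ["h2"]
        assert sets.ranking["h1"] == pytest.approx(np.log2(101 / 2))

    def test_planted_mixture_recovered(self):
        rng = np.random.default_rng(3)
        n = 300
        fh, fm, pairs = {}, {}, []
        truth_h, truth_m = set(), set()
        for i in range(n):
            h, m = f"h{i:03d}", f"m{i:03d}"
            base = float(rng.gamma(2, 10))
            if i < 30:
                fh[h], fm[m] = base * 200, base
                truth_h.add(h)
            elif i < 60:
                fh[h], fm[m] = base, base * 200
                truth_m.add(h)
            else:
                fh[h] = fm[m] = base
            pairs.append((h, m))
        sets = em.define_species_specific_genes(
            expr_table(fh), expr_table(fm), pairs, fraction=0.10
        )
        agree_h = len(set(sets.human_specific) & truth_h) / 30
        agree_m = len(set(sets.mouse_specific) & truth_m) / 30
        assert agree_h >= 0.95 and agree_m >= 0.95

    def test_bad_fraction_errors(self):
        th, tm, pairs = self._tables(10)
        with pytest.raises(ValueError):
            em.define_species_specific_genes(th, tm, pairs, fraction=0.6)


class TestExpressionSummaries:
    def test_constant_expression_median(self):
        t = expr_table({"g1": 7.0, "g2": 7.0}, stages=("ProE", "OrthoE"))
        out = em.expression_by_category(t, {"g1": "conserved", "g2": "conserved"})
        np.testing.assert_allclose(out["median"], np.log2(8.0))
        assert set(out["stage"]) == {"ProE", "OrthoE"}

    def test_replicates_averaged_before_median(self):
        rows = []
        for rep, v in ((1, 0.0), (2, 30.0)):
            rows.append({"gene_id": "g", "stage": "ProE", "replicate": rep, "fpkm": v})
        t = ExpressionTable(pd.DataFrame(rows))
        out = em.expression_by_category(t, {"g": "x"})
        assert out["median"].iloc[0] == pytest.approx(np.log2(16.0))

    def test_planted_category_ordering_recovered(self):
        rng = np.random.default_rng(8)
        offsets = {"conserved": 4.0, "strongly_gained": 3.0, "compensatory": 2.0,
                   "gained": 1.0, "lost": 0.0}
        values, cats = {}, {}
        for cat, off in offsets.items():
            for i in range(40):
                g = f"{cat}{i}"
                values[g] = float(2 ** (3 + off + rng.normal(0, 0.4)) - 1)
                cats[g] = cat
        out = em.expression_by_category(expr_table(values), cats)
        med = out.set_index("category")["median"]
        order = ["conserved", "strongly_gained", "compensatory", "gained", "lost"]
        meds = [med[c] for c in order]
        assert all(a > b for a, b in zip(meds, meds[1:]))

    def test_stage_correlation_matrix(self):
        rng = np.random.default_rng(4)
        genes = {f"h{i}": float(v) for i, v in enumerate(rng.gamma(2, 10, 30))}
        th = expr_table(genes, stages=("ProE", "OrthoE"))
        corr = em.expression_correlation({"human": th})
        assert corr.loc["human:ProE", "human:ProE"] == pytest.approx(1.0)
        assert corr.loc["human:ProE", "human:OrthoE"] == pytest.approx(1.0)

    def test_cross_species_correlation_pairs_by_id(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2, 10, 20)
        th = expr_table({f"h{i}": float(v) for i, v in enumerate(vals)})
        tm = expr_table({f"m{i}": float(v) for i, v in enumerate(vals)})
        pairs = [(f"h{i}", f"m{i}") for i in range(20)]
        corr = em.expression_correlation({"human": th, "mouse": tm}, pairs=pairs)
        assert corr.loc["human:ProE", "mouse:ProE"] == pytest.approx(1.0)
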