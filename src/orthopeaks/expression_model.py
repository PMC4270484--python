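"""Penalized models of gene expression from promoter epigenomic marks.

Expression (log2(1 + FPKM), replicate-averaged) is regressed on the
promoter mark matrix with an L1 penalty (lasso).  The penalty is chosen by
K-fold cross-validation with the one-standard-error rule: the largest
lambda whose CV error is within one SE of the minimum, favoring the
sparser model.  A consensus model is fit on both species' rows pooled
after per-mark quantile normalization; applying the consensus
coefficients to the between-species difference of marks predicts
between-species expression differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path

from .genome_model import ExpressionTable

log = logging.getLogger(__name__)

__all__ = [
    "LassoModel",
    "SpeciesGeneSets",
    "quantile_normalize",
    "fit_lasso_cv",
    "fit_lasso_at",
    "fit_consensus",
    "predict_difference",
    "define_species_specific_genes",
    "expression_by_category",
    "expression_difference_by_category",
    "expression_correlation",
    "log_fpkm_response",
]


@dataclass
class LassoModel:
    """A fitted lasso regression on standardized predictors.

    ``beta`` is on the original predictor scale; ``beta_std`` on the
    standardized (unit-variance) scale used for the penalty path.
    """

    marks: list[str]
    beta: np.ndarray
    intercept: float
    lambda_grid: np.ndarray
    lambda_best: float
    lambda_1se: float
    cv_mean: np.ndarray
    cv_se: np.ndarray
    r_squared: float
    cv_r_squared: float
    x_mean: np.ndarray
    x_scale: np.ndarray

    @property
    def beta_std(self) -> np.ndarray:
        return self.beta * self.x_scale

    @property
    def support(self) -> list[str]:
        return [m for m, b in zip(self.marks, self.beta) if b != 0.0]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xv = X[self.marks].to_numpy(float)
        return self.intercept + Xv @ self.beta

    def predict_delta(self, X_delta: pd.DataFrame) -> np.ndarray:
        """Prediction for a between-species mark difference (no intercept:
        intercepts cancel in differences)."""
        return X_delta[self.marks].to_numpy(float) @ self.beta

    def to_dict(self) -> dict:
        return {
            "marks": self.marks,
            "beta": dict(zip(self.marks, map(float, self.beta))),
            "intercept": self.intercept,
            "lambda_best": self.lambda_best,
            "lambda_1se": self.lambda_1se,
            "r_squared": self.r_squared,
            "cv_r_squared": self.cv_r_squared,
            "support": self.support,
        }


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return math.nan
    return 1.0 - float(((y - y_hat) ** 2).sum()) / tss


def quantile_normalize(matrices: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    """Per-mark quantile normalization across species.

    For each shared mark column, the value vectors from all matrices are
    forced onto the mean-of-order-statistics distribution, so the sorted
    values of every species' column become identical.  Tied input values
    share the mean of their quantile block.
    """
    cols = set(matrices[0].columns)
    for m in matrices[1:]:
        if set(m.columns) != cols:
            raise ValueError("matrices must share the same mark columns")
    n = len(matrices[0])
    for m in matrices[1:]:
        if len(m) != n:
            raise ValueError("matrices must have equal row counts (paired genes)")
    out = [m.copy() for m in matrices]
    for col in matrices[0].columns:
        stacked = np.column_stack([m[col].to_numpy(float) for m in matrices])
        order = np.sort(stacked, axis=0)
        target = order.mean(axis=1)
        for k in range(stacked.shape[1]):
            v = stacked[:, k]
            idx = np.argsort(v, kind="stable")
            assigned = np.empty(n)
            assigned[idx] = target
            # ties share their block mean
            s = pd.Series(assigned)
            assigned = s.groupby(v).transform("mean").to_numpy()
            out[k][col] = assigned
    return out


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by response decile for stable CV curves."""
    n = len(y)
    deciles = np.minimum((stats.rankdata(y, method="ordinal") - 1) * 10 // n, 9)
    folds = np.empty(n, dtype=int)
    for d in np.unique(deciles):
        idx = np.flatnonzero(deciles == d)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def fit_lasso_cv(
    X: pd.DataFrame,
    y: Sequence[float],
    n_folds: int = 10,
    one_se: bool = True,
    seed: int | np.random.Generator = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> LassoModel:
    """Cross-validated lasso of a response on promoter marks.

    Predictors are standardized internally; the lambda grid is log-spaced
    from the smallest all-zero penalty down three decades.  With
    ``one_se`` the chosen lambda is the largest one within one standard
    error of the CV minimum, else the CV minimum itself.  The model is
    refit on the full data at the chosen lambda; ``r_squared`` is the
    in-sample coefficient of determination and ``cv_r_squared`` the
    cross-validated one at that lambda.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X rows and y length differ")
    if n_folds > n:
        raise ValueError("more folds than samples")
    if np.std(y) == 0:
        raise ValueError("constant response")

    marks = list(X.columns)
    Xv = X.to_numpy(float)
    x_mean = Xv.mean(axis=0)
    x_scale = Xv.std(axis=0)
    if (x_scale == 0).any():
        x_scale = np.where(x_scale == 0, 1.0, x_scale)
    Xs = (Xv - x_mean) / x_scale
    yc = y - y.mean()

    lambda_max = np.max(np.abs(Xs.T @ yc)) / n
    grid = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)

    folds = _stratified_folds(y, n_folds, rng)
    fold_mse = np.empty((n_folds, n_lambda))
    fold_sse = np.empty((n_folds, n_lambda))
    for k in range(n_folds):
        tr = folds != k
        te = ~tr
        Xtr, ytr = Xs[tr], y[tr]
        mu = ytr.mean()
        _, coefs, _ = lasso_path(Xtr, ytr - mu, alphas=grid, max_iter=5000)
        pred = mu + Xs[te] @ coefs  # (n_te, n_lambda)
        err = (y[te][:, None] - pred) ** 2
        fold_mse[k] = err.mean(axis=0)
        fold_sse[k] = err.sum(axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / math.sqrt(n_folds)

    i_best = int(np.argmin(cv_mean))
    lambda_best = float(grid[i_best])
    threshold = cv_mean[i_best] + cv_se[i_best]
    ok = np.flatnonzero(cv_mean <= threshold)
    i_1se = int(ok[0])  # grid is decreasing, first ok index = largest lambda
    lambda_1se = float(grid[i_1se])
    i_chosen = i_1se if one_se else i_best
    lam = float(grid[i_chosen])

    model = Lasso(alpha=lam, max_iter=50000)
    model.fit(Xs, yc)
    beta_std = model.coef_
    beta = beta_std / x_scale
    intercept = float(y.mean() - x_mean @ beta)
    yhat = intercept + Xv @ beta
    r2 = r_squared(y, yhat)
    cv_r2 = 1.0 - float(fold_sse[:, i_chosen].sum()) / float(((y - y.mean()) ** 2).sum())

    return LassoModel(
        marks=marks,
        beta=beta,
        intercept=intercept,
        lambda_grid=grid,
        lambda_best=lambda_best,
        lambda_1se=lambda_1se,
        cv_mean=cv_mean,
        cv_se=cv_se,
        r_squared=r2,
        cv_r_squared=cv_r2,
        x_mean=x_mean,
        x_scale=x_scale,
    )


def fit_lasso_at(
    X: pd.DataFrame, y: Sequence[float], lam: float, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Lasso solution at one penalty on the standardized design.

    Returns (beta on the original scale, intercept).  At penalties
    approaching zero this converges to the ordinary least-squares fit;
    the tight tolerance exists for that limit.
    """
    y = np.asarray(y, float)
    Xv = X.to_numpy(float)
    x_mean = Xv.mean(axis=0)
    x_scale = np.where(Xv.std(axis=0) == 0, 1.0, Xv.std(axis=0))
    Xs = (Xv - x_mean) / x_scale
    model = Lasso(alpha=lam, max_iter=2_000_000, tol=tol)
    model.fit(Xs, y - y.mean())
    beta = model.coef_ / x_scale
    intercept = float(y.mean() - x_mean @ beta)
    return beta, intercept


@dataclass
class ConsensusFit:
    model: LassoModel
    r2_per_species: dict[str, float]


def fit_consensus(
    Xh: pd.DataFrame,
    yh: Sequence[float],
    Xm: pd.DataFrame,
    ym: Sequence[float],
    species_names: tuple[str, str] = ("human", "mouse"),
    **fit_kwargs,
) -> ConsensusFit:
    """One model fit on both species' rows pooled; per-species R2 reported.

    Inputs are expected to be quantile-normalized with aligned mark
    columns.  Either species may be empty, reducing to a single-species
    fit.
    """
    if list(Xh.columns) and list(Xm.columns) and set(Xh.columns) != set(Xm.columns):
        raise ValueError("mark columns differ between species")
    cols = list(Xh.columns) if len(Xh.columns) else list(Xm.columns)
    Xm = Xm[cols] if len(Xm) else Xm
    X = pd.concat([Xh[cols] if len(Xh) else Xh, Xm], axis=0, ignore_index=True)
    y = np.concatenate([np.asarray(yh, float), np.asarray(ym, float)])
    model = fit_lasso_cv(X, y, **fit_kwargs)
    per_species = {}
    for name, Xi, yi in zip(species_names, (Xh, Xm), (yh, ym)):
        if len(Xi):
            per_species[name] = r_squared(np.asarray(yi, float), model.predict(Xi[cols]))
    return ConsensusFit(model, per_species)


@dataclass
class DifferencePrediction:
    delta_pred: np.ndarray
    delta_obs: np.ndarray
    r_squared_all: float
    r_squared_subset: float | None
    n_dropped: int


def predict_difference(
    model: LassoModel,
    Xh: pd.DataFrame,
    Xm: pd.DataFrame,
    yh: pd.Series,
    ym: pd.Series,
    subset: Sequence[str] | None = None,
) -> DifferencePrediction:
    """Predict between-species expression differences from mark differences.

    Rows are paired by index (ortholog pairing); unpaired genes are
    dropped with their count recorded.  The prediction is the consensus
    coefficients applied to ``Xh - Xm`` with no intercept term, scored by
    the coefficient of determination against ``yh - ym``, optionally also
    on a gene subset (e.g. species-specific genes).
    """
    shared = Xh.index.intersection(Xm.index).intersection(yh.index).intersection(ym.index)
    n_dropped = max(len(Xh), len(Xm)) - len(shared)
    if n_dropped:
        log.info("%d unpaired genes dropped from the difference model", n_dropped)
    Xd = Xh.loc[shared, model.marks] - Xm.loc[shared, model.marks]
    yd = (yh.loc[shared] - ym.loc[shared]).to_numpy(float)
    pred = model.predict_delta(Xd)
    r2_all = r_squared(yd, pred)
    r2_sub = None
    if subset is not None:
        keep = shared.intersection(pd.Index(list(subset)))
        pos = shared.get_indexer(keep)
        r2_sub = r_squared(yd[pos], pred[pos])
    return DifferencePrediction(pred, yd, r2_all, r2_sub, n_dropped)


@dataclass
class SpeciesGeneSets:
    human_specific: list[str]
    mouse_specific: list[str]
    rest: list[str]
    ranking: pd.Series  # signed log2 expression ratio per gene (human/mouse)

    def to_dict(self) -> dict:
        return {
            "n_human_specific": len(self.human_specific),
            "n_mouse_specific": len(self.mouse_specific),
            "n_rest": len(self.rest),
        }


def log_fpkm_response(expr: ExpressionTable, stage: str) -> pd.Series:
    """log2(1 + FPKM) averaged over replicates at one stage."""
    df = expr.df[expr.df["stage"] == stage]
    if df.empty:
        raise ValueError(f"stage {stage!r} absent from expression table")
    mean_fpkm = df.groupby("gene_id")["fpkm"].mean()
    return np.log2(1.0 + mean_fpkm)


def define_species_specific_genes(
    expr_h: ExpressionTable,
    expr_m: ExpressionTable,
    pairs: Sequence[tuple[str, str]],
    stage: str = "ProE",
    fraction: float = 0.10,
) -> SpeciesGeneSets:
    """Top/bottom deciles of between-species differential expression.

    Ortholog pairs are ranked by signed ``log2((FPKM_h + 1)/(FPKM_m + 1))``
    at one stage (replicate-averaged); the top ``fraction`` are
    human-specific, the bottom ``fraction`` mouse-specific.  Gene ids in
    the output refer to the first (human) species.  Ties order by gene_id
    so the split is deterministic.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    fh = expr_h.df[expr_h.df["stage"] == stage].groupby("gene_id")["fpkm"].mean()
    fm = expr_m.df[expr_m.df["stage"] == stage].groupby("gene_id")["fpkm"].mean()
    rows = []
    for gid_h, gid_m in pairs:
        if gid_h in fh.index and gid_m in fm.index:
            rows.append((gid_h, math.log2((fh[gid_h] + 1.0) / (fm[gid_m] + 1.0))))
    if not rows:
        raise ValueError("no ortholog pairs present in both expression tables")
    ranking = pd.Series(dict(rows)).sort_index()
    order = ranking.sort_values(ascending=False, kind="stable")
    if ranking.nunique() == 1:
        log.warning("degenerate ranking: all expression ratios identical")
    k = int(len(order) * fraction)
    human_specific = list(order.index[:k])
    mouse_specific = list(order.index[len(order) - k :])
    rest = list(order.index[k : len(order) - k])
    return SpeciesGeneSets(human_specific, mouse_specific, rest, ranking)


def expression_by_category(
    expr: ExpressionTable, gene_category: dict[str, str]
) -> pd.DataFrame:
    """Median and quartiles of log2(1 + FPKM) per conservation category and
    stage (replicates averaged first).  Empty categories are omitted."""
    wide = expr.stage_means(log2=True)
    rows = []
    for cat in sorted(set(gene_category.values())):
        genes = [g for g, c in gene_category.items() if c == cat and g in wide.index]
        if not genes:
            log.warning("category %r has no genes with expression; omitted", cat)
            continue
        sub = wide.loc[genes]
        for stage in wide.columns:
            v = sub[stage]
            rows.append(
                {
                    "category": cat,
                    "stage": stage,
                    "n_genes": len(genes),
                    "median": float(v.median()),
                    "q1": float(v.quantile(0.25)),
                    "q3": float(v.quantile(0.75)),
                }
            )
    return pd.DataFrame(rows)


def expression_difference_by_category(
    expr_h: ExpressionTable,
    expr_m: ExpressionTable,
    pairs: Sequence[tuple[str, str]],
    gene_category: dict[str, str],
) -> pd.DataFrame:
    """Between-species expression difference (human minus mouse,
    log2(1+FPKM)) summarized per category at each shared stage."""
    wh = expr_h.stage_means(log2=True)
    wm = expr_m.stage_means(log2=True)
    shared_stages = [s for s in wh.columns if s in wm.columns]
    rows = []
    diffs = {}
    for gid_h, gid_m in pairs:
        if gid_h in wh.index and gid_m in wm.index:
            diffs[gid_h] = wh.loc[gid_h, shared_stages].to_numpy() - wm.loc[
                gid_m, shared_stages
            ].to_numpy()
    for cat in sorted(set(gene_category.values())):
        genes = [g for g, c in gene_category.items() if c == cat and g in diffs]
        if not genes:
            continue
        arr = np.array([diffs[g] for g in genes])
        for j, stage in enumerate(shared_stages):
            v = arr[:, j]
            rows.append(
                {
                    "category": cat,
                    "stage": stage,
                    "n_genes": len(genes),
                    "median": float(np.median(v)),
                    "q1": float(np.quantile(v, 0.25)),
                    "q3": float(np.quantile(v, 0.75)),
                }
            )
    return pd.DataFrame(rows)


def expression_correlation(
    tables: dict[str, ExpressionTable],
    pairs: Sequence[tuple[str, str]] | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Stage x stage correlation matrix of log2(1+FPKM) profiles.

    ``tables`` maps a species label to its expression table; columns of the
    result are ``species:stage``.  When two species are given, genes are
    paired by the ortholog ``pairs`` (first species' ids index the rows).
    """
    labels = list(tables)
    wides = {lab: tables[lab].stage_means(log2=True) for lab in labels}
    if len(labels) == 1:
        mat = wides[labels[0]]
        mat.columns = [f"{labels[0]}:{s}" for s in mat.columns]
    else:
        if pairs is None:
            raise ValueError("ortholog pairs required for cross-species correlation")
        a, b = labels[0], labels[1]
        ida = [p[0] for p in pairs if p[0] in wides[a].index and p[1] in wides[b].index]
        idb = [p[1] for p in pairs if p[0] in wides[a].index and p[1] in wides[b].index]
        wa = wides[a].loc[ida].reset_index(drop=True)
        wb = wides[b].loc[idb].reset_index(drop=True)
        wa.columns = [f"{a}:{s}" for s in wa.columns]
        wb.columns = [f"{b}:{s}" for s in wb.columns]
        mat = pd.concat([wa, wb], axis=1)
    return mat.corr(method=method)
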