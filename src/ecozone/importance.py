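"""Random-forest attribution of per-site richness to environmental and
niche features.

A regression forest is grown on bootstrap resamples of the site x feature
matrix (default feature set: the 11 physicochemical gradients plus the two
site-level niche features), with Margalef richness as the target.  Variable
importance is the classical permutation importance on out-of-bag (OOB)
samples, reported as %IncMSE:

    %IncMSE(f) = 100 * mean_t[ MSE_t(f permuted among tree t's OOB sites)
                               - MSE_t(original) ] / mean_t[ MSE_t(original) ]

averaged over ``n_rep`` independent permutation passes to suppress
Monte-Carlo noise.  The raw percentage increase is reported (no division by
its standard error); the SE-normalized variant is available via
``scale=True``.

Significance of each feature's importance is assessed with a permutation
test: the feature's column is globally reshuffled ``n_perm`` times (breaking
any association with the target while preserving the marginal), the same
OOB importance statistic is recomputed on the fitted forest for each
reshuffled copy, and

    p = (1 + #{null importance >= observed}) / (n_perm + 1).

Because the null copies replace the feature column by an exchangeable draw
and the statistic is evaluated identically, the test is calibrated under
the null hypothesis that the feature is independent of the target.

Key-factor selection drops features with non-positive %IncMSE and keeps the
``top_k`` (default 7) largest; ties at the cut are all retained and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

DEFAULT_N_TREE = 10_000
DEFAULT_N_REP = 500
MIN_SAMPLES_LEAF = 5  # regression-forest node-size convention


# ---------------------------------------------------------------------------
# forest fitting with explicit bootstrap / OOB bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class OOBForest:
    """A bag of regression trees with per-tree out-of-bag index sets."""

    trees: list = field(repr=False)
    oob_indices: list = field(repr=False)   # per tree, array of OOB row indices
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def n_tree(self) -> int:
        return len(self.trees)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_tree: int,
    seed: int,
    feature_names: list[str] | None = None,
    max_features: int | None = None,
    min_samples_leaf: int = MIN_SAMPLES_LEAF,
) -> OOBForest:
    """Grow ``n_tree`` bootstrap trees, recording each tree's OOB rows.

    ``max_features`` defaults to ceil(p/3), the regression-forest convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_tree < 1:
        raise ValueError(f"n_tree must be >= 1, got {n_tree}")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; a regression forest cannot be fit")
    if max_features is None:
        max_features = max(1, math.ceil(p / 3))
    rng = np.random.default_rng(seed)
    trees, oob_indices = [], []
    all_rows = np.arange(n)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for _ in range(n_tree):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_rows, boot)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2**31)),
        )
        # inputs are pre-validated float32; skipping sklearn's per-call checks
        tree.fit(X32[boot], y[boot], check_input=False)
        trees.append(tree)
        oob_indices.append(oob)
    return OOBForest(
        trees=trees, oob_indices=oob_indices, X=X, y=y,
        feature_names=list(feature_names) if feature_names is not None
        else [f"x{i}" for i in range(p)],
        seed=seed,
    )


def _tree_predict(tree, X32: np.ndarray) -> np.ndarray:
    """Raw Cython predict on pre-cast float32 rows (no sklearn validation)."""
    return tree.tree_.predict(X32).reshape(len(X32))


def oob_r2(forest: OOBForest) -> float:
    """Out-of-bag coefficient of determination of the aggregated forest."""
    n = len(forest.y)
    X32 = np.ascontiguousarray(forest.X, dtype=np.float32)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if len(oob) == 0:
            continue
        pred_sum[oob] += _tree_predict(tree, X32[oob])
        pred_cnt[oob] += 1
    seen = pred_cnt > 0
    resid = forest.y[seen] - pred_sum[seen] / pred_cnt[seen]
    mse = float(np.mean(resid**2))
    var = float(np.var(forest.y[seen]))
    return 1.0 - mse / var


def _permutation_matrix(rng: np.random.Generator, n_perm: int, m: int) -> np.ndarray:
    """``n_perm`` independent permutations of ``range(m)`` as an array."""
    return np.argsort(rng.random((n_perm, m)), axis=1)


def _oob_increase(
    forest: OOBForest,
    X: np.ndarray,
    n_rep: int,
    rng: np.random.Generator,
    features: np.ndarray | None = None,
    scale: bool = False,
) -> np.ndarray:
    """%IncMSE of the given features, evaluating the fitted forest on ``X``.

    For every tree, each feature's values are permuted among the tree's OOB
    rows ``n_rep`` times; all permuted copies are stacked so each tree is
    queried once per feature.  Returns the percent increase in mean OOB MSE
    (per-feature), optionally divided by its standard error over trees.
    """
    n, p = X.shape
    if features is None:
        features = np.arange(p)
    nf = len(features)
    delta_sum = np.zeros(nf)            # sum over trees of mean-over-reps MSE increase
    delta_sq = np.zeros(nf)
    mse0_sum = 0.0
    used = 0
    y = forest.y
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for tree, oob in zip(forest.trees, forest.oob_indices):
        m = len(oob)
        if m == 0:
            continue
        Xo = X32[oob]
        yo = y[oob]
        base = _tree_predict(tree, Xo)
        mse0 = float(np.mean((yo - base) ** 2))
        perms = _permutation_matrix(rng, nf * n_rep, m)
        big = np.broadcast_to(Xo, (nf * n_rep, m, p)).copy()
        for fi, f in enumerate(features):
            block = slice(fi * n_rep, (fi + 1) * n_rep)
            big[block, :, f] = Xo[:, f][perms[block]]
        preds = _tree_predict(tree, big.reshape(-1, p)).reshape(nf * n_rep, m)
        mse = ((yo[None, :] - preds) ** 2).mean(axis=1).reshape(nf, n_rep)
        d = mse.mean(axis=1) - mse0
        delta_sum += d
        delta_sq += d**2
        mse0_sum += mse0
        used += 1
    if used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    mean_delta = delta_sum / used
    mean_mse0 = mse0_sum / used
    inc = 100.0 * mean_delta / mean_mse0
    if scale:
        se = np.sqrt(np.maximum(delta_sq / used - mean_delta**2, 0.0) / used)
        inc = np.where(se > 0, mean_delta / se, 0.0)
    return inc


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    """Per-feature %IncMSE with permutation p-values and selection flags."""

    table: pd.DataFrame            # feature-indexed: inc_mse, p_perm, flags, rank
    model_r2: float                # out-of-bag R^2
    n_tree: int
    n_rep: int
    seed: int
    n_perm: int | None = None
    forest: OOBForest | None = field(default=None, repr=False)

    @property
    def inc_mse(self) -> pd.Series:
        return self.table["inc_mse"]

    @property
    def selected(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return list(sel.sort_values("inc_mse", ascending=False).index)


def validate_features(features: pd.DataFrame, target: pd.Series) -> None:
    if features.isna().any().any() or target.isna().any():
        raise ValueError("feature matrix / target contain missing values")
    if len(features) < 5:
        raise ValueError(f"need at least 5 sites, got {len(features)}")
    if not np.isfinite(target.to_numpy(dtype=float)).all():
        raise ValueError("target contains non-finite values")
    if not features.index.equals(target.index):
        raise ValueError("feature matrix and target cover different sites")


def rf_importance(
    features: pd.DataFrame,
    target: pd.Series,
    n_tree: int = DEFAULT_N_TREE,
    n_rep: int = DEFAULT_N_REP,
    seed: int = 0,
    scale: bool = False,
) -> ImportanceResult:
    """Fit the richness forest and compute OOB permutation importance.

    Identical inputs and seed give identical output.  The returned result
    keeps the fitted forest so the permutation significance test can reuse
    it without refitting.
    """
    validate_features(features, target)
    X = features.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    rng = np.random.default_rng([seed, 1])
    forest = fit_forest(X, y, n_tree=n_tree, seed=int(np.random.default_rng([seed, 0]).integers(2**31)),
                        feature_names=list(features.columns))
    inc = _oob_increase(forest, X, n_rep=n_rep, rng=rng, scale=scale)
    table = pd.DataFrame({"inc_mse": inc}, index=list(features.columns))
    table.index.name = "feature"
    table["p_perm"] = np.nan
    table["significant_05"] = False
    table["significant_01"] = False
    table["selected"] = False
    table["rank"] = table["inc_mse"].rank(method="min", ascending=False).astype(int)
    return ImportanceResult(
        table=table, model_r2=oob_r2(forest),
        n_tree=n_tree, n_rep=n_rep, seed=seed, forest=forest,
    )


def permutation_significance(
    features: pd.DataFrame,
    observed: ImportanceResult,
    n_perm: int = 99,
    seed: int = 0,
    n_rep_null: int | None = None,
) -> pd.Series:
    """Permutation p-value per feature; also written into ``observed.table``.

    Each feature column is globally reshuffled ``n_perm`` times and the OOB
    importance statistic is recomputed on the fitted forest for every
    reshuffled copy.  Null and observed statistics are both evaluated with
    ``n_rep_null`` permutation passes (default: ``observed.n_rep`` capped at
    20; the observed statistic is re-evaluated at that count internally so
    the comparison stays exchangeable under feature-target independence,
    while ``observed.inc_mse`` keeps its full-precision value).
    """
    if n_perm < 19:
        raise ValueError(f"n_perm must be >= 19 for a usable resolution, got {n_perm}")
    if observed.forest is None:
        raise ValueError("observed ImportanceResult carries no fitted forest")
    forest = observed.forest
    X = features.to_numpy(dtype=float)
    y = forest.y
    n, p = X.shape
    n_rep = min(observed.n_rep, 20) if n_rep_null is None else n_rep_null
    rng = np.random.default_rng([seed, 2])
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    # global reshuffles of each feature column: the null datasets, fixed across trees
    null_full = np.stack(
        [X32[:, f][_permutation_matrix(rng, n_perm, n)] for f in range(p)]
    )  # (p, n_perm, n)
    delta_sum = np.zeros((p, n_perm))
    base_sum = np.zeros((p, n_perm))
    used = 0
    nv = n_perm * (n_rep + 1)          # variants per feature: baselines + re-permutations
    for tree, oob in zip(forest.trees, forest.oob_indices):
        m = len(oob)
        if m == 0:
            continue
        Xo = X32[oob]
        yo = y[oob]
        big = np.broadcast_to(Xo, (p * nv, m, p)).copy()
        reperm = _permutation_matrix(rng, p * n_perm * n_rep, m).reshape(
            p, n_perm, n_rep, m
        )
        for f in range(p):
            null_cols = null_full[f][:, oob]                    # (n_perm, m)
            block = big[f * nv : (f + 1) * nv].reshape(n_perm, n_rep + 1, m, p)
            block[:, 0, :, f] = null_cols
            block[:, 1:, :, f] = np.take_along_axis(
                np.repeat(null_cols[:, None, :], n_rep, axis=1), reperm[f], axis=2
            )
        preds = _tree_predict(tree, big.reshape(-1, p)).reshape(p, n_perm, n_rep + 1, m)
        mse = ((yo[None, None, None, :] - preds) ** 2).mean(axis=3)
        base_sum += mse[:, :, 0]
        delta_sum += mse[:, :, 1:].mean(axis=2) - mse[:, :, 0]
        used += 1
    null_imp = 100.0 * (delta_sum / used) / (base_sum / used)
    obs = _oob_increase(forest, X, n_rep=n_rep, rng=rng)
    pvals = (1.0 + (null_imp >= obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    pser = pd.Series(pvals, index=observed.table.index, name="p_perm")
    observed.table["p_perm"] = pser
    observed.table["significant_05"] = pser <= 0.05
    observed.table["significant_01"] = pser <= 0.01
    observed.n_perm = n_perm
    return pser


def select_features(result: ImportanceResult, top_k: int = 7) -> list[str]:
    """Keep the ``top_k`` features by %IncMSE after dropping non-positive ones.

    Ties at the k-th rank are all retained (and logged).  Selection flags are
    written back into ``result.table``; the selected names are returned in
    decreasing importance order.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    inc = result.inc_mse
    positive = inc[inc > 0].sort_values(ascending=False, kind="mergesort")
    if len(positive) <= top_k:
        chosen = list(positive.index)
    else:
        cutoff = positive.iloc[top_k - 1]
        chosen = list(positive[positive >= cutoff].index)
        if len(chosen) > top_k:
            logger.info(
                "importance tie at rank %d: keeping %d features", top_k, len(chosen)
            )
    result.table["selected"] = result.table.index.isin(chosen)
    return chosen
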