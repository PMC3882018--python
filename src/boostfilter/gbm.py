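"""Stochastic gradient boosting over genotype features with split-improvement
variable importance.

``BoostedTreeRegressor`` fits an additive ensemble of small regression trees
to a continuous phenotype: F_0 = mean(y); at each iteration a bag of subjects
is drawn without replacement, one tree of at most ``interaction_depth``
splits is grown best-first on the current residuals, and the model is updated
by ``shrinkage`` times the tree's prediction.  Each SNP's variable importance
(VIM) is the sum, over every split that uses it, of the split's squared-error
improvement; trees grown to k splits can capture k-order interactions, which
is what lets the importance ranking surface SNPs whose only contribution is
epistatic.

Genotypes enter the trees as the three dosage classes 0/1/2, so each SNP has
exactly two candidate split points (0.5 and 1.5) and the split search runs on
per-node class histograms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import _boost_kernel as _K
from .io import GenotypeMatrix, Phenotype, dosage_classes

__all__ = ["BoostedTreeRegressor", "GbmConfig", "best_split", "fit_tree",
           "fit_gbm", "gbm_rank", "importance_table"]


def _classes(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return np.ascontiguousarray(dosage_classes(X.dosages))
    X = np.asarray(X)
    return np.ascontiguousarray(dosage_classes(X.astype(np.float64)))


def _values(y) -> np.ndarray:
    if isinstance(y, Phenotype):
        return y.values
    return np.asarray(y, dtype=np.float64)


class BoostedTreeRegressor(RegressorMixin, BaseEstimator):
    """Squared-error stochastic gradient boosting on 0/1/2 dosages.

    Parameters
    ----------
    n_trees : number of boosting iterations (weak learners).
    interaction_depth : splits per tree; depth k admits k-order interactions.
    shrinkage : learning rate applied to every tree's contribution.
    bag_fraction : fraction of subjects drawn (without replacement) per tree.
    min_node : minimum subjects in a daughter node for a split to be eligible.
    random_state : seed for the bagging stream.

    Fitted attributes
    -----------------
    feature_importances_ : raw VIM per SNP (cumulative split improvement).
    normalized_importances_ : VIM rescaled to sum to 100 (zeros if no split).
    train_mean_ : F_0, the phenotype mean.
    n_splits_ : total number of splits across all trees.
    """

    def __init__(self, n_trees: int = 3000, interaction_depth: int = 5,
                 shrinkage: float = 1e-4, bag_fraction: float = 0.5,
                 min_node: int = 10, random_state=None):
        self.n_trees = n_trees
        self.interaction_depth = interaction_depth
        self.shrinkage = shrinkage
        self.bag_fraction = bag_fraction
        self.min_node = min_node
        self.random_state = random_state

    def _check_config(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.interaction_depth < 1:
            raise ValueError("interaction_depth must be >= 1")
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in (0, 1]")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")

    def fit(self, X, y):
        self._check_config()
        G = _classes(X)
        yv = _values(y)
        Xv, yv = validate_data(self, G, yv)
        G = np.ascontiguousarray(Xv.astype(np.int8))
        n, P = G.shape
        M = int(self.n_trees)
        k = int(self.interaction_depth)
        bag_n = max(int(np.ceil(self.bag_fraction * n)), 1)
        rng = np.random.default_rng(self.random_state)
        bags = np.empty((M, bag_n), dtype=np.int64)
        for m in range(M):
            bags[m] = rng.choice(n, size=bag_n, replace=False)
        max_nodes = 2 * k + 1
        self._node_feat = np.full((M, max_nodes), -1, dtype=np.int32)
        self._node_thresh = np.zeros((M, max_nodes), dtype=np.float32)
        self._node_left = np.zeros((M, max_nodes), dtype=np.int16)
        self._node_right = np.zeros((M, max_nodes), dtype=np.int16)
        self._node_value = np.zeros((M, max_nodes))
        self._node_imp = np.zeros((M, max_nodes))
        self._n_nodes = np.zeros(M, dtype=np.int32)
        vim = np.zeros(P)
        F = np.zeros(n)
        resid = np.zeros(n)
        _K.fit_boosted_trees(G, yv, bags, k, float(self.shrinkage),
                             int(self.min_node),
                             self._node_feat, self._node_thresh,
                             self._node_left, self._node_right,
                             self._node_value, self._node_imp,
                             self._n_nodes, vim, F, resid)
        self.feature_importances_ = vim
        tot = vim.sum()
        self.normalized_importances_ = (100.0 * vim / tot if tot > 0
                                        else np.zeros_like(vim))
        self.train_mean_ = float(yv.mean())
        self.train_predictions_ = F
        self.n_splits_ = int((self._n_nodes - 1).sum() // 2)
        return self

    def predict(self, X):
        check_is_fitted(self)
        G = _classes(X)
        G = validate_data(self, G, reset=False).astype(np.int8)
        out = np.empty(G.shape[0])
        _K.predict_trees(np.ascontiguousarray(G), self._node_feat,
                         self._node_thresh, self._node_left,
                         self._node_right, self._node_value,
                         float(self.shrinkage), self.train_mean_, out)
        return out

    def split_improvements(self) -> pd.DataFrame:
        """One row per split: tree, SNP index, threshold, improvement."""
        check_is_fitted(self)
        trees, feats, ths, imps = [], [], [], []
        for m in range(self._node_feat.shape[0]):
            for nd in range(self._n_nodes[m]):
                if self._node_feat[m, nd] >= 0:
                    trees.append(m)
                    feats.append(int(self._node_feat[m, nd]))
                    ths.append(float(self._node_thresh[m, nd]))
                    imps.append(float(self._node_imp[m, nd]))
        return pd.DataFrame({"tree": trees, "snp": feats,
                             "threshold": ths, "improvement": imps})


# GbmConfig mirrors the estimator's constructor for config-file / CLI use.
class GbmConfig(dict):
    """Plain mapping of BoostedTreeRegressor parameters."""

    def __init__(self, n_trees=3000, interaction_depth=5, shrinkage=1e-4,
                 bag_fraction=0.5, min_node=10, random_state=None):
        super().__init__(n_trees=n_trees, interaction_depth=interaction_depth,
                         shrinkage=shrinkage, bag_fraction=bag_fraction,
                         min_node=min_node, random_state=random_state)


# ---------------------------------------------------------------------------
# functional surface


def best_split(residuals: np.ndarray, node_members: np.ndarray,
               g, min_node: int = 1) -> tuple[int, float, float]:
    """Exhaustive best split for one node over all SNPs x {0.5, 1.5}.

    Returns (variable index, split point, improvement); variable -1 when no
    eligible split exists (node too small or residuals constant).
    """
    G = _classes(g)
    residuals = np.asarray(residuals, dtype=np.float64)
    idx = np.asarray(node_members, dtype=np.int64)
    P = G.shape[1]
    s = np.zeros((P, 3))
    c = np.zeros((P, 3))
    ss = _K._node_hist(G, idx, 0, len(idx), residuals, s, c)
    j, t, imp = _K._best_split_from_hist(s, c, ss, int(min_node))
    return j, (0.5 if t == 0 else 1.5) if j >= 0 else float("nan"), imp


def fit_tree(residuals: np.ndarray, bag: np.ndarray, g,
             k: int = 5, min_node: int = 10) -> dict:
    """Grow one best-first regression tree on the given residuals.

    Returns a dict of node arrays: feature (-1 = terminal), threshold,
    left, right, value (terminal mean residual), improvement, n_nodes,
    plus a ``predict`` callable over dosage matrices.
    """
    G = _classes(g)
    residuals = np.asarray(residuals, dtype=np.float64)
    idx = np.asarray(bag, dtype=np.int64).copy()
    P = G.shape[1]
    max_nodes = 2 * k + 1
    node_feat = np.full(max_nodes, -1, dtype=np.int32)
    node_thresh = np.zeros(max_nodes, dtype=np.float32)
    node_left = np.zeros(max_nodes, dtype=np.int16)
    node_right = np.zeros(max_nodes, dtype=np.int16)
    node_value = np.zeros(max_nodes)
    node_imp = np.zeros(max_nodes)
    S = np.zeros((k + 1, P, 3))
    C = np.zeros((k + 1, P, 3))
    buf = np.empty(len(idx), dtype=np.int64)
    ln = np.empty(k + 1, dtype=np.int32)
    ls = np.empty(k + 1, dtype=np.int64)
    le = np.empty(k + 1, dtype=np.int64)
    lj = np.empty(k + 1, dtype=np.int32)
    lt = np.empty(k + 1, dtype=np.int32)
    li = np.empty(k + 1, dtype=np.float64)
    n_nodes = _K.grow_tree(G, residuals, idx, int(k), int(min_node),
                           node_feat, node_thresh, node_left, node_right,
                           node_value, node_imp, buf, S, C,
                           ln, ls, le, lj, lt, li)

    def predict(Xnew):
        Gn = _classes(Xnew)
        out = np.empty(Gn.shape[0])
        for i in range(Gn.shape[0]):
            nd = 0
            while node_feat[nd] >= 0:
                nd = (node_left[nd] if Gn[i, node_feat[nd]] < node_thresh[nd]
                      else node_right[nd])
            out[i] = node_value[nd]
        return out

    return {"feature": node_feat, "threshold": node_thresh,
            "left": node_left, "right": node_right, "value": node_value,
            "improvement": node_imp, "n_nodes": int(n_nodes),
            "predict": predict}


def fit_gbm(g, y, **config) -> tuple[BoostedTreeRegressor, pd.DataFrame]:
    """Fit the boosting model; returns (model, importance table)."""
    model = BoostedTreeRegressor(**config).fit(g, y)
    return model, importance_table(model, g if isinstance(g, GenotypeMatrix)
                                   else None)


def importance_table(model: BoostedTreeRegressor,
                     g: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Per-SNP VIM table with average-tie ranks (rank 1 = highest VIM)."""
    vim = model.feature_importances_
    d = {"vim": vim, "normalized_vim": model.normalized_importances_,
         "score": vim, "rank": rankdata(-vim, method="average")}
    if g is not None:
        d = {"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos, **d}
    else:
        d = {"snp_id": [f"snp{j + 1}" for j in range(len(vim))],
             "chrom": "0", "pos": np.arange(1, len(vim) + 1), **d}
    return pd.DataFrame(d)


def gbm_rank(g, y, **config) -> pd.DataFrame:
    """Importance table sorted by VIM (descending); ties share average rank."""
    _, table = fit_gbm(g, y, **config)
    return table.sort_values("rank", kind="stable").reset_index(drop=True)
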