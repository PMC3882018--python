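"""Single-marker association scans.

``AdditiveScan`` regresses the phenotype on each SNP's 0/1/2 dosage by OLS
and reports slope, standard error, t and two-sided p (N-2 df).
``RobustScan`` computes the same t statistic under additive (0,1,2),
dominant (0,1,1) and recessive (0,0,1) codings and scores each SNP by the
maximum absolute statistic (a MAX3-type robust test); an optional permutation
p-value is available.  Both follow the sklearn estimator protocol: ``fit(X,
y)`` populates trailing-underscore attributes; ranking scores are oriented so
larger is better.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import GenotypeMatrix, Phenotype, mean_impute

__all__ = ["AdditiveScan", "RobustScan", "additive_scan", "robust_scan"]


def _ols_scan(X: np.ndarray, y: np.ndarray):
    """Vectorized per-column simple linear regression with intercept.

    Returns (beta, se, t, p, monomorphic mask).  Monomorphic columns get
    beta=0, t=0, p=1."""
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    xm = X.mean(axis=0)
    ym = y.mean()
    xc = X - xm
    yc = y - ym
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    syy = float(yc @ yc)
    mono = sxx <= 0.0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    sse = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = sse / (n - 2)
    se = np.sqrt(np.where(sigma2 <= 0.0, 0.0, sigma2) / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0.0, beta / se, np.where(beta != 0.0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    beta = np.where(mono, 0.0, beta)
    t = np.where(mono, 0.0, t)
    p = np.where(mono, 1.0, p)
    p = np.maximum(p, np.nextafter(0.0, 1.0))  # p in (0, 1]
    return beta, se, t, p, mono


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return mean_impute(X.dosages)
    return np.asarray(X, dtype=np.float64)


def _as_values(y) -> np.ndarray:
    if isinstance(y, Phenotype):
        return y.values
    return np.asarray(y, dtype=np.float64)


class AdditiveScan(BaseEstimator):
    """Per-SNP OLS of a continuous phenotype on additive dosage.

    Fitted attributes
    -----------------
    beta_, se_, t_, pvalues_ : per-SNP regression results
    scores_ : \\|t\\|, the ranking score (larger = stronger association)
    ranks_ : average-tie rank of each SNP, 1 = best
    monomorphic_ : mask of SNPs with zero genotype variance (p set to 1)
    """

    def fit(self, X, y):
        Xd = _as_matrix(X)
        yv = _as_values(y)
        Xd, yv = validate_data(self, Xd, yv)
        beta, se, t, p, mono = _ols_scan(Xd, yv)
        self.beta_, self.se_, self.t_, self.pvalues_ = beta, se, t, p
        self.monomorphic_ = mono
        self.scores_ = np.abs(t)
        self.ranks_ = rankdata(p, method="average")
        return self

    def table(self, g: GenotypeMatrix | None = None) -> pd.DataFrame:
        check_is_fitted(self)
        d = {"beta": self.beta_, "se": self.se_, "t": self.t_,
             "p": self.pvalues_, "score": self.scores_, "rank": self.ranks_,
             "coding": "additive"}
        if g is not None:
            d = {"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos, **d}
        else:
            d = {"snp_id": [f"snp{j + 1}" for j in range(len(self.beta_))],
                 "chrom": "0", "pos": np.arange(1, len(self.beta_) + 1), **d}
        return pd.DataFrame(d)


_CODINGS = ("add", "dom", "rec")


def _max3(X: np.ndarray, y: np.ndarray):
    """t statistics under additive/dominant/recessive codings and their max.

    A coding whose recoded genotype is constant is skipped for that SNP."""
    Z = np.empty((3, X.shape[1]))
    for i, recode in enumerate((lambda g: g,
                                lambda g: (g >= 0.5).astype(float),
                                lambda g: (g >= 1.5).astype(float))):
        _, _, t, _, mono = _ols_scan(recode(X), y)
        Z[i] = np.where(mono, np.nan, t)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column
        zmax = np.nanmax(np.abs(Z), axis=0)
    zmax = np.where(np.isnan(zmax), 0.0, zmax)  # all codings collapsed
    return Z, zmax


class RobustScan(BaseEstimator):
    """MAX3-type robust scan over additive, dominant and recessive codings.

    Ranks SNPs by Z_max = max(|t_add|, |t_dom|, |t_rec|), which is sensitive
    to associations that an additive-only scan would shrink.  ``n_permutations
    > 0`` additionally computes a label-permutation p-value per SNP,
    p = (1 + #{Z*_max >= Z_max}) / (B + 1).
    """

    def __init__(self, n_permutations: int = 0, random_state=None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        Xd = _as_matrix(X)
        yv = _as_values(y)
        Xd, yv = validate_data(self, Xd, yv)
        Z, zmax = _max3(Xd, yv)
        self.z_add_, self.z_dom_, self.z_rec_ = Z
        self.z_max_ = zmax
        self.scores_ = zmax
        self.ranks_ = rankdata(-zmax, method="average")
        if self.n_permutations:
            rng = np.random.default_rng(self.random_state)
            B = int(self.n_permutations)
            exceed = np.zeros(Xd.shape[1])
            for _ in range(B):
                _, zperm = _max3(Xd, rng.permutation(yv))
                exceed += zperm >= zmax
            self.perm_pvalues_ = (1.0 + exceed) / (B + 1.0)
        return self

    def table(self, g: GenotypeMatrix | None = None) -> pd.DataFrame:
        check_is_fitted(self)
        d = {"z_add": self.z_add_, "z_dom": self.z_dom_,
             "z_rec": self.z_rec_, "z_max": self.z_max_,
             "score": self.scores_, "rank": self.ranks_, "coding": "max3"}
        if hasattr(self, "perm_pvalues_"):
            d["perm_p"] = self.perm_pvalues_
        if g is not None:
            d = {"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos, **d}
        else:
            d = {"snp_id": [f"snp{j + 1}" for j in range(len(self.z_max_))],
                 "chrom": "0", "pos": np.arange(1, len(self.z_max_) + 1), **d}
        return pd.DataFrame(d)


def additive_scan(g: GenotypeMatrix, y: Phenotype) -> pd.DataFrame:
    """Additive GWA scan; returns the per-SNP association table."""
    return AdditiveScan().fit(g, y).table(g)


def robust_scan(g: GenotypeMatrix, y: Phenotype,
                n_permutations: int = 0, random_state=None) -> pd.DataFrame:
    """Robust (MAX3) scan; returns the per-SNP association table."""
    est = RobustScan(n_permutations=n_permutations, random_state=random_state)
    return est.fit(g, y).table(g)
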