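"""Correlation-constrained overlapping SNP subsets and importance aggregation.

Large panels are divided into overlapping subsets in which no SNP pair
correlates beyond a ceiling (|Pearson r| on dosages, 0.1 by default), so SNPs
in high LD are analyzed in different subsets and cannot share or split
variable importance.  Several passes with randomized window phase give each
SNP multiple subset memberships; per-subset importances (normalized to sum
100 within each subset) are then aggregated per SNP across its subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .gbm import BoostedTreeRegressor, importance_table
from .io import GenotypeMatrix, mean_impute

__all__ = ["SubsetPlan", "build_subsets", "aggregate_importance",
           "gbm_on_subsets"]


@dataclass
class SubsetPlan:
    subsets: list            # list of np.ndarray of global SNP indices
    membership_count: np.ndarray
    max_abs_corr: float
    n_snps: int

    def validate(self, g: GenotypeMatrix) -> None:
        """Brute-force check of the within-subset correlation ceiling."""
        Z = _standardize(g)
        for s, members in enumerate(self.subsets):
            sub = Z[:, members]
            r = (sub.T @ sub) / Z.shape[0]
            np.fill_diagonal(r, 0.0)
            worst = float(np.abs(r).max()) if len(members) > 1 else 0.0
            if worst > self.max_abs_corr + 1e-9:
                raise AssertionError(
                    f"subset {s} violates |r| <= {self.max_abs_corr}: {worst}")


def _standardize(g: GenotypeMatrix) -> np.ndarray:
    X = mean_impute(g.dosages).astype(np.float32)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0
    return X / sd


def build_subsets(g: GenotypeMatrix, max_abs_corr: float = 0.1,
                  copies: int = 5, window: int = 500,
                  seed=None) -> SubsetPlan:
    """Sliding-window subset construction with randomized phase.

    Each of ``copies`` passes walks the position-ordered SNPs and assigns
    each SNP to the first open subset in which it (a) fits under the
    correlation ceiling against every member and (b) leaves the subset at or
    below ``window`` SNPs; otherwise a new subset is opened, so no SNP is
    ever dropped.  The first window of each pass has a random length, which
    shifts window boundaries between passes and creates overlap.  On an
    LD-free panel each pass yields contiguous windows and every SNP ends up
    in exactly ``copies`` subsets.
    """
    if not 0.0 < max_abs_corr < 1.0:
        raise ValueError("max_abs_corr must be in (0,1)")
    if copies < 1 or window < 2:
        raise ValueError("copies >= 1 and window >= 2 required")
    rng = np.random.default_rng(seed)
    Z = _standardize(g)
    n = Z.shape[0]
    P = g.n_snps
    subsets: list[np.ndarray] = []
    for _ in range(copies):
        phase = int(rng.integers(1, window + 1))
        open_members: list[list[int]] = []
        open_cap: list[int] = []
        closed: list[list[int]] = []
        opened_any = False
        for j in range(P):
            placed = False
            for s in range(len(open_members)):
                mem = open_members[s]
                r = np.abs(Z[:, mem].T @ Z[:, j]) / n
                if np.all(r <= max_abs_corr):
                    mem.append(j)
                    placed = True
                    if len(mem) >= open_cap[s]:
                        closed.append(mem)
                        del open_members[s], open_cap[s]
                    break
            if not placed:
                # candidate conflicts with every open subset (or none is
                # open): it gets a fresh subset, never dropped.  The first
                # subset of a pass is truncated at the random phase.
                cap = window if opened_any else phase
                opened_any = True
                if cap <= 1:
                    closed.append([j])
                else:
                    open_members.append([j])
                    open_cap.append(cap)
        closed.extend(open_members)
        subsets.extend(np.asarray(m, dtype=np.int64) for m in closed if m)
    membership = np.zeros(P, dtype=np.int64)
    for mem in subsets:
        membership[mem] += 1
    assert membership.min() >= 1
    return SubsetPlan(subsets=subsets, membership_count=membership,
                      max_abs_corr=max_abs_corr, n_snps=P)


def aggregate_importance(plan: SubsetPlan, per_subset: list,
                         stat: str = "mean",
                         norm: str = "share") -> pd.DataFrame:
    """Combine within-subset importances into one per-SNP score.

    ``per_subset`` holds one importance table (with a ``vim`` column, rows in
    the subset's SNP order) per subset of the plan.  Within each subset the
    VIM is normalized to a per-SNP mean of one (each SNP's share of the
    subset's total importance, on a scale comparable across subsets of
    different sizes); a SNP's aggregated score is the mean (or median) of its
    normalized VIMs over the subsets containing it.  ``norm="raw"`` skips
    the normalization and averages absolute improvements (comparable across
    subsets because every subset models the same phenotype).
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    if norm not in ("share", "raw"):
        raise ValueError("norm must be 'share' or 'raw'")
    if len(per_subset) != len(plan.subsets):
        raise ValueError(
            f"got {len(per_subset)} importance tables for "
            f"{len(plan.subsets)} subsets")
    per_snp: list[list[float]] = [[] for _ in range(plan.n_snps)]
    for s, (members, table) in enumerate(zip(plan.subsets, per_subset)):
        if table is None or len(table) != len(members):
            raise ValueError(f"missing or misaligned importance table for "
                             f"subset {s}")
        vim = np.asarray(table["vim"], dtype=np.float64)
        tot = vim.sum()
        if norm == "share":
            vals = (len(vim) * vim / tot) if tot > 0 else np.zeros_like(vim)
        else:
            vals = vim
        for j, v in zip(members, vals):
            per_snp[j].append(v)
    agg = np.array([np.mean(v) if stat == "mean" else np.median(v)
                    for v in per_snp])
    return pd.DataFrame({
        "snp_index": np.arange(plan.n_snps),
        "score": agg,
        "membership_count": plan.membership_count,
        "rank": rankdata(-agg, method="average"),
    })


def gbm_on_subsets(g: GenotypeMatrix, y, plan: SubsetPlan,
                   stat: str = "mean", norm: str = "share",
                   **config) -> pd.DataFrame:
    """Fit the boosting model within every subset and aggregate importances."""
    tables = []
    for members in plan.subsets:
        sub = g.take_snps(members)
        model = BoostedTreeRegressor(**config).fit(sub, y)
        tables.append(importance_table(model, sub))
    out = aggregate_importance(plan, tables, stat=stat, norm=norm)
    out.insert(1, "snp_id", g.snp_ids)
    return out
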