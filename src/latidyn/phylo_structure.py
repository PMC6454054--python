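"""Null-model community phylogenetics: MNTD, ses.MNTD, and variance tests.

MNTD is the mean, over taxa present in a community, of the patristic
distance to the nearest other co-occurring taxon (presence-based).  The
standardized effect size compares the observed MNTD with null communities
obtained by shuffling tip labels on the patristic distance matrix while
preserving each sample's richness; negative ses.MNTD with a low quantile
indicates phylogenetic clustering, positive with a high quantile
overdispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import OtuTable, PhyloTree

__all__ = ["mntd", "ses_mntd", "SesMntdResult", "variance_ratio_test"]


def _nearest_taxon_mean(d_sub: np.ndarray) -> float:
    d = d_sub.copy()
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


class _NearestTaxonPool:
    """Nearest-in-subset distances on a fixed pool.

    Pre-sorts each tip's neighbours once; for a subset the nearest
    co-occurring tip is almost always within the first few sorted
    neighbours, turning each null draw from O(r^2) into ~O(r).
    """

    def __init__(self, d_pool: np.ndarray, window: int = 32):
        self.d = d_pool
        self.n = d_pool.shape[0]
        self.window = min(window, self.n - 1)
        self.nb_order = np.argsort(d_pool, axis=1)[:, 1:]  # drop self
        self.nb_dist = np.take_along_axis(d_pool, self.nb_order, axis=1)

    def mntd(self, subset: np.ndarray) -> float:
        member = np.zeros(self.n, dtype=bool)
        member[subset] = True
        cand = self.nb_order[subset, : self.window]
        hit = member[cand]
        found = hit.any(axis=1)
        first = hit.argmax(axis=1)
        nearest = np.take_along_axis(
            self.nb_dist[subset, : self.window], first[:, None], axis=1
        )[:, 0]
        if not found.all():
            # sparse subsets: fall back to a full scan for the misses
            for row in np.flatnonzero(~found):
                i = subset[row]
                others = subset[subset != i]
                nearest[row] = self.d[i, others].min()
        return float(nearest.mean())


def mntd(tip_set, tree: PhyloTree) -> float:
    """Mean nearest-taxon distance of a presence set on a tree."""
    tips = list(dict.fromkeys(tip_set))
    if len(tips) < len(list(tip_set)):
        warnings.warn("duplicate tips in community collapsed")
    missing = set(tips) - set(tree.tip_names)
    if missing:
        raise ValueError(f"tips not on tree: {sorted(missing)[:10]}")
    if len(tips) < 2:
        raise ValueError("MNTD requires at least 2 tips")
    d = tree.patristic_matrix().loc[tips, tips].to_numpy()
    return _nearest_taxon_mean(d)


@dataclass
class SesMntdResult:
    sample_id: str
    mntd_obs: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when null_sd == 0
    quantile: float
    n_null: int
    note: str = ""


def ses_mntd(
    table: OtuTable,
    tree: PhyloTree,
    n_null: int = 999,
    null_model: str = "taxa_labels",
    seed: int = 0,
    pool: str = "table",
) -> list[SesMntdResult]:
    """Standardized effect size of MNTD per sample against label-shuffle nulls.

    The species pool is the set of tree tips present (count > 0) anywhere in
    ``table`` (``pool='table'``; pass the per-site table for a per-site
    pool) or all tree tips (``pool='tree'``).  Null communities preserve
    each sample's richness.  Null draws are cached per distinct richness, so
    samples of equal richness share one null distribution.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if null_model != "taxa_labels":
        raise ValueError(f"unknown null model: {null_model}")
    counts = table.counts()
    if pool == "table":
        pool_ids = [
            o
            for o, tot in zip(table.otu_ids, counts.sum(axis=0))
            if tot > 0 and o in set(tree.tip_names)
        ]
    elif pool == "tree":
        pool_ids = list(tree.tip_names)
    else:
        raise ValueError(f"unknown pool: {pool}")
    if len(pool_ids) < 3:
        raise ValueError("species pool too small for null model")
    d_pool = tree.patristic_matrix().loc[pool_ids, pool_ids].to_numpy()
    helper = _NearestTaxonPool(d_pool)
    pos = {o: k for k, o in enumerate(pool_ids)}
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    results: list[SesMntdResult] = []
    for i, sid in enumerate(table.sample_ids):
        present = [o for o, c in zip(table.otu_ids, counts[i]) if c > 0 and o in pos]
        if len(present) < 2:
            results.append(
                SesMntdResult(sid, np.nan, np.nan, np.nan, np.nan, np.nan, n_null,
                              note="fewer than 2 pool taxa present")
            )
            continue
        idx = np.array([pos[o] for o in present])
        obs = helper.mntd(idx)
        r = len(idx)
        if r not in null_cache:
            nulls = np.empty(n_null)
            n_pool = len(pool_ids)
            for k in range(n_null):
                nulls[k] = helper.mntd(rng.choice(n_pool, size=r, replace=False))
            null_cache[r] = nulls
        nulls = null_cache[r]
        mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
        if sd <= 1e-12 * max(1.0, abs(mu)):  # degenerate null (e.g. full pool)
            sd = 0.0
        rank = int((nulls < obs).sum()) + 1  # rank of observed among nulls
        quant = rank / (n_null + 1)
        if sd > 0:
            results.append(SesMntdResult(sid, obs, mu, sd, (obs - mu) / sd, quant, n_null))
        else:
            results.append(
                SesMntdResult(sid, obs, mu, sd, np.nan, quant, n_null,
                              note="null_sd is zero; ses undefined")
            )
    return results


def ses_mntd_frame(results: list[SesMntdResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "mntd_obs": [r.mntd_obs for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "ses": [r.ses for r in results],
            "quantile": [r.quantile for r in results],
            "n_null": [r.n_null for r in results],
        }
    ).set_index("sample_id")


def variance_ratio_test(ses_values_a, ses_values_b) -> tuple[float, float]:
    """Two-tailed F test comparing variances of two ses.MNTD collections.

    Returns (F, p) with F = var_A / var_B on (nA-1, nB-1) degrees of freedom.
    """
    a = np.asarray(ses_values_a, dtype=float)
    b = np.asarray(ses_values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both collections need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator collection")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))
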