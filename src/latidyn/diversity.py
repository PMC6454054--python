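"""Alpha and phylogenetic beta diversity, ordination and PERMANOVA.

Weighted UniFrac sums branch lengths weighted by the absolute difference in
the fraction of each sample's reads descending from the branch; the
normalized variant divides by the abundance-weighted total branch length so
distances lie in [0, 1] and similarity = 1 - distance.  PERMANOVA supports
two crossed factors with sequential sums of squares so that site and season
variance fractions can be reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix

from .core_io import OtuTable, PhyloTree

__all__ = [
    "chao1",
    "rarefaction_curve",
    "weighted_unifrac",
    "pcoa",
    "Ordination",
    "permanova",
    "PermanovaResult",
]


def chao1(sample_counts) -> float:
    """Bias-corrected Chao1 richness estimate for one sample.

    S_obs + F1 (F1 - 1) / (2 (F2 + 1)), with F1/F2 the number of OTUs seen
    exactly once/twice in the sample.  Always >= observed richness.
    """
    c = np.asarray(sample_counts)
    if c.ndim != 1:
        raise ValueError("chao1 expects a 1-D count vector")
    if np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("counts must be non-negative integers")
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        raise ValueError("chao1 undefined for an all-zero sample")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def rarefaction_curve(
    table: OtuTable, depths, n_reps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth.

    Depths must be ascending; depths above a sample's total are reported as
    NaN for that sample.  Returns a DataFrame indexed by sample id with one
    column per depth.
    """
    depths = list(depths)
    if not depths:
        raise ValueError("empty depth list")
    if sorted(depths) != depths:
        raise ValueError("depths must be ascending")
    rng = np.random.default_rng(seed)
    counts = table.counts()
    out = np.full((table.n_samples, len(depths)), np.nan)
    for i in range(table.n_samples):
        c = counts[i]
        total = int(c.sum())
        for j, d in enumerate(depths):
            if d > total:
                continue
            if d == total:
                out[i, j] = float((c > 0).sum())
                continue
            rich = [
                int((rng.multivariate_hypergeometric(c, d) > 0).sum())
                for _ in range(n_reps)
            ]
            out[i, j] = float(np.mean(rich))
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)


def _branch_profiles(table: OtuTable, tree: PhyloTree) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample fraction of reads descending from each branch.

    Returns (branch_lengths, profiles) with profiles of shape
    (n_samples, n_branches).
    """
    counts = table.counts().astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total samples: {bad}")
    present = set(np.array(table.otu_ids)[counts.sum(axis=0) > 0])
    missing = present - set(tree.tip_names)
    if missing:
        raise ValueError(
            f"OTUs with nonzero counts missing from tree: {sorted(missing)[:10]}"
        )
    lengths, member = tree.branch_arrays()
    # align table columns to tree tip order; absent tips get zero counts
    tip_pos = {t: k for k, t in enumerate(tree.tip_names)}
    aligned = np.zeros((table.n_samples, tree.n_tips))
    for j, otu in enumerate(table.otu_ids):
        k = tip_pos.get(otu)
        if k is not None:
            aligned[:, k] = counts[:, j]
    rel = aligned / aligned.sum(axis=1, keepdims=True)
    profiles = rel @ member.T.astype(float)  # samples x branches
    return lengths, profiles


def weighted_unifrac(
    table: OtuTable, tree: PhyloTree, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise weighted UniFrac distances between all samples.

    Raw: sum_e b_e |p_Ae - p_Be|; normalized divides by
    sum_e b_e (p_Ae + p_Be), bounding distances by 1.
    """
    lengths, profiles = _branch_profiles(table, tree)
    n = profiles.shape[0]
    weighted = profiles * lengths  # samples x branches
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(weighted[i] - weighted[i + 1 :]).sum(axis=1)
        if normalized:
            denom = (weighted[i] + weighted[i + 1 :]).sum(axis=1)
            diff = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class Ordination:
    """Classical-scaling (PCoA) result with axes in descending eigenvalue order."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis


def pcoa(dist: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis by double-centering squared distances.

    Axes with negative eigenvalues are reported in ``eigenvalues`` but their
    coordinates are dropped.  For a Euclidean input matrix the pairwise
    distances among coordinates reproduce the input.
    """
    d = dist.data
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2.0
    vals, vecs = eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(vals[0]), 1.0)) if n else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    total = vals[vals > 0].sum()
    prop = vals[pos] / total if total > 0 else np.zeros(pos.sum())
    frame = pd.DataFrame(
        coords,
        index=list(dist.ids),
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return Ordination(frame, vals, prop)


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared_by_term: dict[str, float]
    p_value: float
    n_permutations: int
    f_by_term: dict[str, float]
    p_by_term: dict[str, float]


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto the column space of x
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10)
    q = q[:, :rank]
    return q @ q.T


def _design(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels])


def permanova(
    dist: DistanceMatrix,
    grouping: pd.DataFrame | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix (adonis).

    ``grouping`` may be a Series (one factor) or a DataFrame whose column
    order fixes the sequential sums of squares for crossed factors.  The
    permutation p-value is (1 + #{F* >= F}) / (n_perm + 1) under free label
    shuffles; per-term sequential F and p are also returned.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_frame()
    ids = list(dist.ids)
    if not set(ids) <= set(grouping.index):
        raise ValueError("distance matrix ids missing from grouping")
    grouping = grouping.loc[ids]
    for col in grouping.columns:
        sizes = grouping[col].value_counts()
        if len(sizes) < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
        if sizes.min() < 2:
            raise ValueError(f"factor {col!r} has a singleton level")
    n = len(ids)
    g = _gower_center(dist.data)
    sst = np.trace(g)

    factors = [np.asarray(grouping[c]) for c in grouping.columns]

    # the design is fixed; only the response (rows/cols of G) is permuted, so
    # the cumulative hat matrices can be precomputed once
    hats = []
    x = np.ones((n, 1))
    for f in factors:
        x = np.column_stack([x, _design(f)])
        hats.append(_hat(x))

    def sequential_ss(perm: np.ndarray) -> tuple[list[float], float]:
        """Sequential (type I) SS per term and residual SS for a permutation
        of the response (rows/cols of G)."""
        gp = g[np.ix_(perm, perm)]
        ss_terms = []
        prev = 0.0
        for h in hats:
            explained = float((h * gp).sum())  # trace(H @ Gp), H symmetric
            ss_terms.append(explained - prev)
            prev = explained
        return ss_terms, sst - prev

    identity = np.arange(n)
    ss_obs, ss_res = sequential_ss(identity)
    df_terms = [len(pd.unique(f)) - 1 for f in factors]
    df_res = n - 1 - sum(df_terms)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    f_terms = [
        (ss / df) / (ss_res / df_res) for ss, df in zip(ss_obs, df_terms)
    ]
    # overall model pseudo-F
    df_model = sum(df_terms)
    f_model = (sum(ss_obs) / df_model) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    ge_model = 1
    ge_terms = [1] * len(factors)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_p, ss_res_p = sequential_ss(perm)
        f_model_p = (sum(ss_p) / df_model) / (ss_res_p / df_res)
        if f_model_p >= f_model:
            ge_model += 1
        for k, (ss, df) in enumerate(zip(ss_p, df_terms)):
            if (ss / df) / (ss_res_p / df_res) >= f_terms[k]:
                ge_terms[k] += 1
    p_model = ge_model / (n_perm + 1)
    names = list(grouping.columns)
    return PermanovaResult(
        pseudo_F=f_model,
        r_squared_by_term={nm: ss / sst for nm, ss in zip(names, ss_obs)},
        p_value=p_model,
        n_permutations=n_perm,
        f_by_term=dict(zip(names, f_terms)),
        p_by_term={nm: ge / (n_perm + 1) for nm, ge in zip(names, ge_terms)},
    )
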