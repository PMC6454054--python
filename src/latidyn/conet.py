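"""Co-occurrence networks over core OTUs and their topology.

Networks are built by thresholding a correlation matrix of per-OTU relative
abundances; edges keep their sign.  Topological features are computed on
the unweighted, unsigned skeleton: node degree, betweenness (fractional
geodesic counting), stress (integer geodesic counting), clustering
coefficient; network-level average clustering coefficient, average path
distance over connected pairs, greedy-agglomeration Newman modularity, and
Freeman centralization of betweenness and stress normalized to the star
graph maximum.

The threshold can be chosen automatically with a random-matrix-theory
style criterion: scanning candidates, the nearest-neighbour spacing
distribution of the unfolded eigenvalues of the thresholded correlation
matrix is tested against the Poisson form, and the smallest candidate
where a chi-square test no longer rejects Poisson is selected (the
transition away from Gaussian-orthogonal-ensemble statistics).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import OtuTable

__all__ = [
    "core_otus",
    "correlation_matrix",
    "select_threshold",
    "build_network",
    "CoNetwork",
    "node_topology",
    "network_topology",
    "NetworkTopology",
]


def core_otus(table: OtuTable, prevalence_threshold: float = 0.5) -> OtuTable:
    """Keep OTUs present in strictly more than the given fraction of samples."""
    if not 0 <= prevalence_threshold < 1:
        raise ValueError("prevalence_threshold must be in [0, 1)")
    counts = table.counts()
    prevalence = (counts > 0).mean(axis=0)
    keep = [o for o, p in zip(table.otu_ids, prevalence) if p > prevalence_threshold]
    if not keep:
        raise ValueError(
            "no core OTUs at this prevalence threshold; lower the threshold"
        )
    return table.select_otus(keep)


def correlation_matrix(
    table: OtuTable, method: str = "pearson", transform: str = "none"
) -> pd.DataFrame:
    """Pairwise correlations of per-OTU relative abundances across samples."""
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for correlations")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method}")
    rel = table.relative_abundance().to_numpy()
    if transform == "log10_rel":
        positive = rel[rel > 0]
        floor = positive.min() / 2.0 if positive.size else 1.0
        rel = np.log10(np.where(rel > 0, rel, floor))
    elif transform != "none":
        raise ValueError(f"unknown transform: {transform}")
    x = pd.DataFrame(rel, columns=table.otu_ids)
    zero_var = x.std(ddof=0) == 0
    corr = x.corr(method=method)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance OTUs; their correlations set to 0"
        )
        for o in x.columns[zero_var]:
            corr.loc[o, :] = 0.0
            corr.loc[:, o] = 0.0
            corr.loc[o, o] = 1.0
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _unfold(eigs: np.ndarray, n_knots: int = 15) -> np.ndarray:
    """Unfold a sorted eigenvalue sequence via a coarse-grained empirical
    cumulative spectral function, so mean spacing is ~1."""
    n = len(eigs)
    # knots on the sorted spectrum; linear interpolation of the smoothed CDF
    knot_idx = np.unique(np.linspace(0, n - 1, n_knots).astype(int))
    knot_x = eigs[knot_idx]
    knot_y = (knot_idx + 1).astype(float)
    # guard against duplicate knot positions in degenerate spectra
    keep = np.concatenate([[True], np.diff(knot_x) > 0])
    return np.interp(eigs, knot_x[keep], knot_y[keep])


def nnsd_poisson_chi2(
    corr_t: np.ndarray, n_bins: int = 10
) -> tuple[float, float, float]:
    """Nearest-neighbour spacing statistics of a thresholded correlation
    matrix: chi-square and p-value against the Poisson (exponential) form,
    plus the chi-square against the Gaussian-orthogonal-ensemble Wigner
    surmise for comparison."""
    eigs = np.sort(np.linalg.eigvalsh(corr_t))
    unfolded = _unfold(eigs)
    s = np.diff(unfolded)
    s = s[np.isfinite(s)]
    if len(s) < 20:
        return np.inf, 0.0, np.inf
    s = s / s.mean()
    bin_edges = np.concatenate([np.linspace(0.0, 3.0, n_bins), [np.inf]])
    counts, _ = np.histogram(s, bins=bin_edges)

    def chi2_against(cdf_values):
        expected = len(s) * np.diff(cdf_values)
        mask = expected > 1e-12
        stat = float(((counts[mask] - expected[mask]) ** 2 / expected[mask]).sum())
        return stat, int(mask.sum()) - 1

    poisson_cdf = 1.0 - np.exp(-bin_edges)
    goe_cdf = 1.0 - np.exp(-np.pi * bin_edges**2 / 4.0)  # Wigner surmise
    chi2_p, dof = chi2_against(poisson_cdf)
    chi2_g, _ = chi2_against(goe_cdf)
    return chi2_p, float(stats.chi2.sf(chi2_p, dof)), chi2_g


def select_threshold(
    corr: pd.DataFrame,
    method: str = "rmt",
    grid=None,
    alpha: float = 0.05,
    fixed_value: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the correlation threshold for network construction.

    method 'rmt': scan the grid ascending and pick the smallest candidate
    whose thresholded matrix has Poisson-like eigenvalue spacings (chi-square
    p > alpha); the per-candidate statistics are returned for audit.
    method 'fixed': return ``fixed_value`` unchanged.
    """
    if method == "fixed":
        if fixed_value is None or not 0 < fixed_value < 1:
            raise ValueError("fixed method requires fixed_value in (0, 1)")
        return float(fixed_value), pd.DataFrame()
    if method != "rmt":
        raise ValueError(f"unknown method: {method}")
    if grid is None:
        grid = np.arange(0.30, 0.96, 0.05)
    grid = np.asarray(sorted(grid), dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid values must be in (0, 1)")
    c = corr.to_numpy(dtype=float).copy()
    records = []
    chosen = None
    for t in grid:
        ct = np.where(np.abs(c) >= t, c, 0.0)
        np.fill_diagonal(ct, 1.0)
        connected = (np.abs(ct) > 0).sum(axis=1) > 1  # beyond the diagonal
        ct = ct[np.ix_(connected, connected)]
        if ct.shape[0] < 25:
            records.append({"threshold": t, "n_nodes": ct.shape[0],
                            "chi2": np.nan, "p": np.nan, "chi2_goe": np.nan})
            continue
        chi2, p, chi2_goe = nnsd_poisson_chi2(ct)
        records.append({"threshold": t, "n_nodes": ct.shape[0], "chi2": chi2,
                        "p": p, "chi2_goe": chi2_goe})
        # accept where Poisson spacing is both unrejected and a better fit
        # than the GOE alternative (the transition away from GOE statistics)
        if chosen is None and p > alpha and chi2 < chi2_goe:
            chosen = float(t)
    report = pd.DataFrame(records)
    if chosen is None:
        warnings.warn(
            "no grid threshold reached Poisson spacing statistics; "
            "returning the highest candidate"
        )
        chosen = float(grid[-1])
    return chosen, report


@dataclass
class CoNetwork:
    """Signed, weighted, undirected co-occurrence network (i < j canonical)."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (i, j, signed correlation)
    threshold: float
    correlation_method: str = "pearson"
    n_isolated_dropped: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_negative_edges(self) -> int:
        return sum(1 for _, _, w in self.edges if w < 0)

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {v: [] for v in self.nodes}
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": i, "target": j, "weight": w,
                 "sign": "+" if w >= 0 else "-"}
                for i, j, w in self.edges
            ]
        )

    def write_graphml(self, path) -> None:
        """Minimal GraphML export for external network viewers."""
        from xml.sax.saxutils import escape

        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
            '  <key id="w" for="edge" attr.name="weight" attr.type="double"/>',
            '  <graph edgedefault="undirected">',
        ]
        for v in self.nodes:
            lines.append(f'    <node id="{escape(v)}"/>')
        for i, j, w in self.edges:
            lines.append(
                f'    <edge source="{escape(i)}" target="{escape(j)}">'
                f'<data key="w">{w}</data></edge>'
            )
        lines += ["  </graph>", "</graphml>", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))


def build_network(
    corr: pd.DataFrame, threshold: float, correlation_method: str = "pearson"
) -> CoNetwork:
    """Edges where |correlation| >= threshold; isolated nodes are dropped
    from the network but counted."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ids = list(corr.index)
    c = corr.to_numpy(dtype=float)
    edges = []
    connected = set()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if abs(c[a, b]) >= threshold:
                edges.append((ids[a], ids[b], float(c[a, b])))
                connected.add(ids[a])
                connected.add(ids[b])
    nodes = [v for v in ids if v in connected]
    return CoNetwork(
        nodes=nodes,
        edges=edges,
        threshold=float(threshold),
        correlation_method=correlation_method,
        n_isolated_dropped=len(ids) - len(nodes),
    )


def _brandes(adj: dict[str, list[str]]):
    """Single-source shortest-path accumulation of betweenness (fractional)
    and stress (integer geodesic counts), plus pairwise distances.

    Returns (betweenness, stress, distance_sum, connected_pairs) where the
    centrality dicts already account for undirected double counting.
    """
    nodes = list(adj)
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    dist_sum = 0
    pair_count = 0
    for s in nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = {v: 0.0 for v in nodes}
        dist = {v: -1 for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        for v in nodes:
            if v != s and dist[v] > 0:
                dist_sum += dist[v]
                pair_count += 1
        delta = {v: 0.0 for v in nodes}
        delta_s = {v: 0.0 for v in nodes}
        for w in reversed(stack):
            for v in pred[w]:
                frac = sigma[v] / sigma[w]
                delta[v] += frac * (1.0 + delta[w])
                delta_s[v] += sigma[v] * (1.0 + delta_s[w] / sigma[w])
            if w != s:
                betweenness[w] += delta[w]
                stress[w] += delta_s[w]
    for v in nodes:
        betweenness[v] /= 2.0
        stress[v] = round(stress[v] / 2.0)
    return betweenness, stress, dist_sum, pair_count


def node_topology(net: CoNetwork) -> pd.DataFrame:
    """Degree, betweenness, stress, and clustering coefficient per node,
    computed on the unweighted unsigned skeleton."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    adj = {v: set(ws) for v, ws in net.adjacency().items()}
    adj_lists = {v: sorted(ws) for v, ws in adj.items()}
    betweenness, stress, _, _ = _brandes(adj_lists)
    rows = []
    for v in net.nodes:
        k = len(adj[v])
        if k < 2:
            cc = 0.0
        else:
            links = sum(
                1
                for a in adj[v]
                for b in adj[v]
                if a < b and b in adj[a]
            )
            cc = 2.0 * links / (k * (k - 1))
        rows.append(
            {
                "node": v,
                "degree": k,
                "betweenness": betweenness[v],
                "stress": int(stress[v]),
                "clustering_coefficient": cc,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def _greedy_modularity(nodes: list[str], edges: list[tuple[str, str]]) -> float:
    """Deterministic greedy agglomerative Newman modularity.

    Starts from singleton communities and repeatedly merges the connected
    community pair with the largest positive modularity gain
    dQ = l_ij/m - d_i d_j / (2 m^2), ties broken by the smallest community
    index pair.  Returns the modularity of the final partition (a
    reproducible lower bound on the optimum).
    """
    m = len(edges)
    if m == 0:
        return 0.0
    index = {v: i for i, v in enumerate(nodes)}
    within = {i: 0.0 for i in range(len(nodes))}  # intra-community edges
    degree = {i: 0.0 for i in range(len(nodes))}
    between: dict[tuple[int, int], float] = {}
    for a, b, *_ in edges:
        ia, ib = index[a], index[b]
        degree[ia] += 1
        degree[ib] += 1
        key = (min(ia, ib), max(ia, ib))
        between[key] = between.get(key, 0.0) + 1.0
    while True:
        best_gain, best_pair = 0.0, None
        for (ci, cj), l_ij in sorted(between.items()):
            gain = l_ij / m - degree[ci] * degree[cj] / (2.0 * m * m)
            if gain > best_gain + 1e-12:
                best_gain, best_pair = gain, (ci, cj)
        if best_pair is None:
            break
        ci, cj = best_pair  # merge cj into ci
        within[ci] += within.pop(cj) + between.pop((ci, cj))
        degree[ci] += degree.pop(cj)
        merged: dict[tuple[int, int], float] = {}
        for (a, b), l in between.items():
            a2 = ci if a == cj else a
            b2 = ci if b == cj else b
            key = (min(a2, b2), max(a2, b2))
            merged[key] = merged.get(key, 0.0) + l
        between = merged
    q = sum(
        within[c] / m - (degree[c] / (2.0 * m)) ** 2 for c in within
    )
    return float(q)


@dataclass
class NetworkTopology:
    nodes_n: int
    links_n: int
    negative_links_n: int
    avgCC: float
    GD: float
    M: float
    CB: float
    CS: float


def network_topology(net: CoNetwork) -> NetworkTopology:
    """Network-level topology summary.

    GD is the mean geodesic length over connected pairs only; CB/CS are
    Freeman centralizations of betweenness/stress normalized to the star
    graph maximum for the same node count.
    """
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    node_df = node_topology(net)
    adj = {v: sorted(set(ws)) for v, ws in net.adjacency().items()}
    _, _, dist_sum, pair_count = _brandes(adj)
    gd = dist_sum / pair_count if pair_count else float("nan")
    n = net.n_nodes
    if n > 2:
        star_max = (n - 1) * (n - 2) / 2.0  # center of a star, both metrics
        denom = (n - 1) * star_max
        cb = float((node_df["betweenness"].max() - node_df["betweenness"]).sum() / denom)
        cs = float((node_df["stress"].max() - node_df["stress"]).sum() / denom)
    else:
        cb = cs = 0.0
    m = _greedy_modularity(net.nodes, [(i, j) for i, j, _ in net.edges])
    return NetworkTopology(
        nodes_n=n,
        links_n=net.n_edges,
        negative_links_n=net.n_negative_edges,
        avgCC=float(node_df["clustering_coefficient"].mean()),
        GD=float(gd),
        M=m,
        CB=cb,
        CS=cs,
    )
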