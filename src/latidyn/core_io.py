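"""Readers, writers and count-level preprocessing for community tables.

The unit of all downstream analyses is the :class:`OtuTable`, an integer
count matrix of samples by OTUs.  Phylogenies are rooted Newick trees whose
tips are OTU ids, wrapped in :class:`PhyloTree` which caches the structures
(branch lengths, per-branch descendant tip sets, patristic distances) that
the diversity and phylogenetic-structure modules need.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "PhyloTree",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "read_metadata",
    "remove_singletons",
    "rarefy",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the expected format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


@dataclass
class OtuTable:
    """Integer OTU count matrix, samples as rows.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative integer counts, index = sample ids, columns = OTU ids.
    taxonomy : dict, optional
        Map from OTU id to a semicolon-separated ranked lineage string
        (domain;phylum;class;...;genus).  Unassigned ranks are empty.
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)):
                raise ValidationError("counts must be finite")
            if np.any(values != np.round(values)):
                raise ValidationError("counts must be integers")
            self.data = df = df.astype(np.int64)
            values = df.to_numpy()
        if values.size and values.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(df.columns)
            if unknown:
                raise ValidationError(
                    f"taxonomy keys are not OTU ids: {sorted(unknown)[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.data.sum(axis=1)
        return self.data.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    def select_otus(self, otu_ids) -> "OtuTable":
        otu_ids = [o for o in otu_ids if o in self.data.columns]
        tax = (
            {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
            if self.taxonomy
            else None
        )
        return OtuTable(self.data.loc[:, otu_ids].copy(), taxonomy=tax)

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)].copy(), taxonomy=self.taxonomy)


class PhyloTree:
    """Rooted phylogeny with branch lengths over OTU tips.

    Wraps a :class:`skbio.TreeNode` and caches the flat branch arrays used
    by weighted UniFrac (per-branch descendant tip membership) and the
    patristic distance matrix used by MNTD.
    """

    def __init__(self, tree: TreeNode):
        tips = [t.name for t in tree.tips()]
        if not tips and tree.is_tip():  # degenerate single-tip tree
            tips = [tree.name]
        if len(tips) != len(set(tips)):
            seen, dups = set(), set()
            for t in tips:
                (dups if t in seen else seen).add(t)
            raise ValidationError(f"duplicate tip names: {sorted(dups)}")
        if any(t is None for t in tips):
            raise ValidationError("unnamed tips in tree")
        for node in tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValidationError("negative branch length")
        self.tree = tree
        self.tip_names: list[str] = tips
        self._branch_cache: tuple[np.ndarray, np.ndarray] | None = None
        self._patristic: pd.DataFrame | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def total_branch_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.tree.traverse(include_self=False)
        )

    def branch_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (branch_lengths, membership) where membership[e, i] is True
        iff tip i descends from branch e.  One row per non-root edge."""
        if self._branch_cache is None:
            tip_index = {name: i for i, name in enumerate(self.tip_names)}
            lengths: list[float] = []
            rows: list[np.ndarray] = []
            masks: dict[int, np.ndarray] = {}
            for node in self.tree.postorder(include_self=True):
                if node.is_tip():
                    mask = np.zeros(self.n_tips, dtype=bool)
                    mask[tip_index[node.name]] = True
                else:
                    mask = np.zeros(self.n_tips, dtype=bool)
                    for child in node.children:
                        mask |= masks[id(child)]
                masks[id(node)] = mask
                if node.parent is not None:
                    lengths.append(node.length or 0.0)
                    rows.append(mask)
            self._branch_cache = (np.asarray(lengths, dtype=float), np.array(rows))
        return self._branch_cache

    def patristic_matrix(self) -> pd.DataFrame:
        """All-pairs tip-to-tip branch-length path distances (cached)."""
        if self._patristic is None:
            lengths, member = self.branch_arrays()
            # path(i,j) = sum of branch lengths where exactly one of i,j descends
            m = member.astype(float)
            # d_ij = sum_e b_e * (m_ei + m_ej - 2 m_ei m_ej)
            bm = lengths[:, None] * m  # edges x tips
            col = bm.sum(axis=0)  # sum_e b_e m_ei, per tip
            cross = m.T @ bm  # tips x tips: sum_e b_e m_ei m_ej
            d = col[:, None] + col[None, :] - 2.0 * cross
            np.fill_diagonal(d, 0.0)
            self._patristic = pd.DataFrame(
                d, index=self.tip_names, columns=self.tip_names
            )
        return self._patristic

    def prune_to(self, tip_names) -> "PhyloTree":
        """Subtree induced by the given tips (shear); branch lengths kept."""
        keep = [t for t in tip_names if t in set(self.tip_names)]
        if len(keep) < 2:
            raise ValidationError("pruning requires at least 2 retained tips")
        sub = self.tree.copy().shear(keep)
        sub.prune()
        return PhyloTree(sub)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def read_otu_table(
    path, dialect: str = "tsv_samples_as_rows", taxonomy_path=None
) -> OtuTable:
    """Read a TSV OTU table.

    ``dialect`` selects the orientation: ``tsv_samples_as_rows`` (samples in
    rows) or ``tsv_otus_as_rows`` (OTUs in rows, QIIME classic layout).
    """
    if dialect not in ("tsv_samples_as_rows", "tsv_otus_as_rows"):
        raise ValueError(f"unknown dialect: {dialect}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty or unparseable OTU table: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"OTU table has no data rows/columns: {path}")
    if dialect == "tsv_otus_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    taxonomy = None
    if taxonomy_path is not None:
        tx = pd.read_csv(taxonomy_path, sep="\t", index_col=0, header=None)
        taxonomy = {str(k): str(v) for k, v in tx.iloc[:, 0].items()}
    return OtuTable(df, taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path, dialect: str = "tsv_samples_as_rows"):
    df = table.data if dialect == "tsv_samples_as_rows" else table.data.T
    df.to_csv(path, sep="\t")


def read_tree(path, missing_length: str = "error") -> PhyloTree:
    """Read a rooted Newick tree.

    ``missing_length`` controls edges without a branch length: ``error``
    (default) or ``zero`` (treat as length 0).
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    missing = [
        n for n in tree.traverse(include_self=False) if n.length is None
    ]
    if missing:
        if missing_length == "error":
            raise FormatError(
                f"{len(missing)} edges lack branch lengths (pass "
                "missing_length='zero' to accept)"
            )
        for n in missing:
            n.length = 0.0
    return PhyloTree(tree)


REQUIRED_META_COLUMNS = ("site", "plot", "season", "year", "date", "latitude", "longitude")
SEASONS = ("Sp", "Su", "A")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata CSV (index = sample id).

    Requires columns site, plot, season, year, date, latitude, longitude;
    dates are parsed as ISO-8601.  (site, plot, season, year) must be unique.
    """
    meta = pd.read_csv(path, index_col=0)
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    meta["date"] = pd.to_datetime(meta["date"], format="ISO8601")
    bad = set(meta["season"].unique()) - set(SEASONS)
    if bad:
        raise ValidationError(f"unknown season codes: {sorted(bad)}")
    key = meta[["site", "plot", "season", "year"]]
    if key.duplicated().any():
        raise ValidationError("(site, plot, season, year) not unique in metadata")
    return meta


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples equals 1.

    Idempotent; returns an identical table when no singletons exist.
    """
    totals = table.data.sum(axis=0)
    keep = totals[totals != 1].index
    if len(keep) == 0:
        warnings.warn("all OTUs are singletons; result has no OTUs")
    dropped = table.n_otus - len(keep)
    if dropped:
        logger.info("remove_singletons: dropped %d singleton OTUs", dropped)
    return table.select_otus(keep)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total count is below ``depth`` are dropped with a logged
    warning.  Deterministic for a given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts()
    totals = counts.sum(axis=1)
    keep_rows = totals >= depth
    n_dropped = int((~keep_rows).sum())
    if n_dropped:
        dropped_ids = [s for s, k in zip(table.sample_ids, keep_rows) if not k]
        warnings.warn(
            f"rarefy: dropped {n_dropped} samples below depth {depth}: "
            f"{dropped_ids[:5]}{'...' if n_dropped > 5 else ''}"
        )
    out = np.zeros((int(keep_rows.sum()), counts.shape[1]), dtype=np.int64)
    row = 0
    for i in np.flatnonzero(keep_rows):
        c = counts[i]
        if totals[i] == depth:
            out[row] = c
        else:
            # multivariate hypergeometric draw = reads without replacement
            out[row] = rng.multivariate_hypergeometric(c, depth)
        row += 1
    kept_ids = [s for s, k in zip(table.sample_ids, keep_rows) if k]
    df = pd.DataFrame(out, index=kept_ids, columns=table.otu_ids)
    return OtuTable(df, taxonomy=table.taxonomy)
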