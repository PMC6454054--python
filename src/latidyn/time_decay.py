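"""Similarity--time decay: seasonal turnover rate estimation and tests.

Community similarity (1 - weighted UniFrac distance) between pairs of
samples is regressed on the time interval separating them on log-log axes,
log10(S) = constant - w log10(T).  The magnitude of the slope, w, is the
temporal turnover rate; larger w means faster compositional change.  The
slope is tested against a permutation null (random re-pairing of
similarities and intervals) and slopes are compared between sites or taxon
groups by bootstrap resampling of pairs.

The time unit is days between sampling dates.  The slope magnitude depends
on this unit; only comparisons made in the same unit are meaningful, and a
different unit can be requested where the relative pattern is all that is
interpreted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .core_io import OtuTable, PhyloTree
from .diversity import weighted_unifrac

logger = logging.getLogger(__name__)

__all__ = [
    "PairSimilaritySeries",
    "TimeDecayFit",
    "build_pair_series",
    "fit_time_decay",
    "test_slope",
    "SlopeTest",
    "compare_slopes",
    "group_turnover",
    "taxon_groups",
]

_TIME_UNIT_DAYS = {"days": 1.0, "months": 30.0, "seasons": 90.0}


@dataclass
class PairSimilaritySeries:
    """Pairwise similarities with their separating time intervals."""

    pairs: pd.DataFrame  # columns: sample_i, sample_j, delta_t, similarity
    site: str | None = None
    group: str | None = None
    n_excluded_same_time: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def intervals(self) -> np.ndarray:
        return np.sort(self.pairs["delta_t"].unique())


@dataclass
class TimeDecayFit:
    w: float  # turnover rate, |slope| when slope < 0
    intercept: float
    r_squared: float
    n_pairs: int
    n_intervals: int
    slope_sign: int  # -1 decay, +1 increase, 0 flat
    p_slope: float | None = None
    site: str | None = None
    group: str | None = None

    @property
    def slope(self) -> float:
        return self.slope_sign * self.w if self.slope_sign != 0 else 0.0


def build_pair_series(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    site: str | None = None,
    year: int | None = None,
    time_unit: str = "days",
) -> PairSimilaritySeries:
    """Turn a distance matrix into (interval, similarity) pairs for one scope.

    Similarity = 1 - distance; the interval is the absolute difference in
    sampling dates.  Pairs sampled on the same date (same campaign) carry no
    temporal signal and are excluded but counted.
    """
    ids = [i for i in dist.ids if i in metadata.index]
    meta = metadata.loc[ids]
    if site is not None:
        meta = meta[meta["site"] == site]
    if year is not None:
        meta = meta[meta["year"] == year]
    ids = list(meta.index)
    if len(ids) < 2:
        raise ValueError("fewer than 2 samples in scope")
    dates = pd.to_datetime(meta["date"]).to_numpy()
    if len(pd.unique(dates)) < 2:
        raise ValueError("fewer than 2 distinct sampling dates in scope")
    sub = dist.filter(ids)
    unit = _TIME_UNIT_DAYS[time_unit]
    rows_i, rows_j, dts, sims = [], [], [], []
    excluded = 0
    day = np.timedelta64(1, "D")
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            dt = abs((dates[a] - dates[b]) / day)
            if dt == 0:
                excluded += 1
                continue
            rows_i.append(ids[a])
            rows_j.append(ids[b])
            dts.append(dt / unit)
            sims.append(1.0 - sub[ids[a], ids[b]])
    pairs = pd.DataFrame(
        {"sample_i": rows_i, "sample_j": rows_j, "delta_t": dts, "similarity": sims}
    )
    return PairSimilaritySeries(pairs, site=site, n_excluded_same_time=excluded)


def _prepare_xy(
    series: PairSimilaritySeries, averaging: str
) -> tuple[np.ndarray, np.ndarray, int]:
    pairs = series.pairs
    sims = pairs["similarity"].to_numpy(dtype=float)
    dts = pairs["delta_t"].to_numpy(dtype=float)
    neg = sims < 0
    if neg.any():
        k = int(np.flatnonzero(neg)[0])
        raise ValueError(
            "negative similarity for pair "
            f"({pairs['sample_i'].iloc[k]}, {pairs['sample_j'].iloc[k]})"
        )
    if (sims == 0).any():
        positive = sims[sims > 0]
        if positive.size == 0:
            raise ValueError("all similarities are zero; log fit undefined")
        floor = positive.min() / 2.0
        n_floored = int((sims == 0).sum())
        logger.info("floored %d zero similarities at %.3g", n_floored, floor)
        sims = np.where(sims == 0, floor, sims)
    n_intervals = len(np.unique(dts))
    if averaging == "per_interval":
        if n_intervals < 3:
            raise ValueError("per-interval fit needs >= 3 distinct intervals")
        frame = pd.DataFrame({"dt": dts, "s": sims}).groupby("dt")["s"].mean()
        x = np.log10(frame.index.to_numpy())
        y = np.log10(frame.to_numpy())
    elif averaging == "pairwise":
        x = np.log10(dts)
        y = np.log10(sims)
    else:
        raise ValueError(f"unknown averaging mode: {averaging}")
    return x, y, n_intervals


def fit_time_decay(
    series: PairSimilaritySeries, averaging: str = "per_interval"
) -> TimeDecayFit:
    """OLS fit of log10(similarity) on log10(interval).

    With ``averaging='per_interval'`` (default) similarities are first
    averaged within each distinct interval, matching a fit to pairwise
    average similarity values; ``'pairwise'`` regresses every pair.
    """
    x, y, n_intervals = _prepare_xy(series, averaging)
    if np.allclose(y, y[0]):
        return TimeDecayFit(
            0.0, float(y[0]), 0.0, series.n_pairs, n_intervals, 0,
            site=series.site, group=series.group,
        )
    res = stats.linregress(x, y)
    slope = float(res.slope)
    sign = -1 if slope < 0 else (1 if slope > 0 else 0)
    return TimeDecayFit(
        w=abs(slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_pairs=series.n_pairs,
        n_intervals=n_intervals,
        slope_sign=sign,
        site=series.site,
        group=series.group,
    )


@dataclass
class SlopeTest:
    p_empirical: float
    p_ttest: float
    observed_slope: float
    null_mean_slope: float
    n_rand: int


def _refit_slope(dts, sims, averaging: str) -> float:
    s = PairSimilaritySeries(
        pd.DataFrame(
            {"sample_i": "", "sample_j": "", "delta_t": dts, "similarity": sims}
        )
    )
    fit = fit_time_decay(s, averaging=averaging)
    return fit.slope


def test_slope(
    series: PairSimilaritySeries,
    n_rand: int = 1000,
    seed: int = 0,
    averaging: str = "per_interval",
) -> SlopeTest:
    """Test whether the decay slope differs from zero.

    Null slopes come from randomly re-pairing similarities with intervals
    ``n_rand`` times and refitting.  Two p-values are reported: a one-sample
    t test of the null slope collection against the observed slope, and the
    two-sided empirical quantile (1 + #{|b*| >= |b|}) / (n_rand + 1).
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99")
    pairs = series.pairs
    sims = pairs["similarity"].to_numpy(dtype=float)
    dts = pairs["delta_t"].to_numpy(dtype=float)
    obs = fit_time_decay(series, averaging=averaging).slope
    if np.allclose(sims, sims[0]):
        warnings.warn("all similarities identical; slope test degenerate, p = 1")
        return SlopeTest(1.0, 1.0, obs, 0.0, n_rand)
    rng = np.random.default_rng(seed)
    null_slopes = np.empty(n_rand)
    for k in range(n_rand):
        null_slopes[k] = _refit_slope(dts, rng.permutation(sims), averaging)
    ge = int((np.abs(null_slopes) >= abs(obs)).sum())
    p_emp = (1 + ge) / (n_rand + 1)
    if np.allclose(null_slopes, null_slopes[0]):
        p_t = 1.0
    else:
        p_t = float(stats.ttest_1samp(null_slopes, popmean=obs).pvalue)
    return SlopeTest(p_emp, p_t, obs, float(null_slopes.mean()), n_rand)


def compare_slopes(
    series_a: PairSimilaritySeries,
    series_b: PairSimilaritySeries,
    n_boot: int = 1000,
    seed: int = 0,
    averaging: str = "per_interval",
) -> tuple[float, float, float]:
    """Compare two decay slopes by bootstrap resampling of pairs.

    Each series is resampled with replacement ``n_boot`` times and refit;
    the two bootstrap slope distributions are compared with a two-sample t
    test.  Returns (p, mean bootstrap slope A, mean bootstrap slope B).
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    out = []
    for series in (series_a, series_b):
        # each series gets an identically-seeded stream: comparing a series
        # against itself then yields exactly matching bootstrap slopes
        rng = np.random.default_rng(seed)
        if len(np.unique(series.pairs["delta_t"])) < 3:
            raise ValueError("series has fewer than 3 distinct intervals")
        dts = series.pairs["delta_t"].to_numpy(dtype=float)
        sims = series.pairs["similarity"].to_numpy(dtype=float)
        n = len(dts)
        slopes = np.empty(n_boot)
        k = 0
        attempts = 0
        while k < n_boot:
            idx = rng.integers(0, n, size=n)
            attempts += 1
            if len(np.unique(dts[idx])) < 3:
                if attempts > 10 * n_boot:
                    raise ValueError("bootstrap cannot retain 3 intervals")
                continue
            slopes[k] = _refit_slope(dts[idx], sims[idx], averaging)
            k += 1
        out.append(slopes)
    a, b = out
    if np.allclose(a, b):
        p = 1.0
    elif np.allclose(a, a[0]) and np.allclose(b, b[0]):
        p = 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, float(a.mean()), float(b.mean())


def _parse_lineage(lineage: str) -> list[str]:
    return [part.strip() for part in lineage.split(";")]


def taxon_groups(
    table: OtuTable, min_rel_abundance: float = 0.01
) -> dict[str, list[str]]:
    """Partition OTUs into the taxon groups used for per-group turnover.

    Groups are Archaea (domain level) and bacterial phyla whose overall
    relative abundance exceeds the threshold; the Proteobacteria phylum is
    replaced by its classes (each still subject to the threshold).
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    if not 0 < min_rel_abundance < 1:
        raise ValueError("min_rel_abundance must be in (0, 1)")
    total = table.data.to_numpy().sum()
    otu_totals = table.data.sum(axis=0)
    members: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        lineage = table.taxonomy.get(otu)
        if not lineage:
            continue
        ranks = _parse_lineage(lineage)
        domain = ranks[0] if ranks else ""
        phylum = ranks[1] if len(ranks) > 1 else ""
        klass = ranks[2] if len(ranks) > 2 else ""
        if domain == "Archaea":
            key = "Archaea"
        elif phylum == "Proteobacteria":
            key = klass if klass else "Proteobacteria_unclassified"
        elif phylum:
            key = phylum
        else:
            continue
        members.setdefault(key, []).append(otu)
    out = {}
    for key, otus in members.items():
        frac = otu_totals[otus].sum() / total
        if frac > min_rel_abundance:
            out[key] = otus
    return out


def group_turnover(
    table: OtuTable,
    tree: PhyloTree,
    metadata: pd.DataFrame,
    min_rel_abundance: float = 0.01,
    sites=None,
    year_scopes=("combined",),
    averaging: str = "per_interval",
    time_unit: str = "days",
) -> pd.DataFrame:
    """Per-taxon-group, per-site turnover rates.

    For each group the table is restricted to its OTUs (counts renormalized
    implicitly by the relative-abundance step of UniFrac), the tree pruned
    to the group's tips, weighted UniFrac recomputed, and the time-decay
    slope fitted per site.  ``year_scopes`` entries are 'combined' or a
    concrete year.  Returns a tidy table with one row per
    (group, site, year_scope).
    """
    groups = taxon_groups(table, min_rel_abundance)
    if sites is None:
        sites = sorted(metadata.loc[metadata.index.isin(table.sample_ids), "site"].unique())
    rows = []
    for gname, otus in sorted(groups.items()):
        otus_on_tree = [o for o in otus if o in set(tree.tip_names)]
        if len(otus_on_tree) < 2:
            warnings.warn(f"group {gname}: fewer than 2 OTUs on tree; skipped")
            continue
        sub = table.select_otus(otus_on_tree)
        keep = sub.data.sum(axis=1) > 0
        if (~keep).any():
            warnings.warn(
                f"group {gname}: {int((~keep).sum())} samples with no group "
                "reads dropped"
            )
            sub = sub.select_samples(sub.data.index[keep])
        subtree = tree.prune_to(otus_on_tree)
        dist = weighted_unifrac(sub, subtree, normalized=True)
        for site in sites:
            for scope in year_scopes:
                year = None if scope == "combined" else int(scope)
                try:
                    series = build_pair_series(
                        dist, metadata, site=site, year=year, time_unit=time_unit
                    )
                    fit = fit_time_decay(series, averaging=averaging)
                except ValueError as exc:
                    warnings.warn(f"group {gname} site {site} ({scope}): {exc}")
                    continue
                rows.append(
                    {
                        "group": gname,
                        "site": site,
                        "year_scope": str(scope),
                        "w": fit.w,
                        "slope_sign": fit.slope_sign,
                        "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                        "n_pairs": fit.n_pairs,
                        "n_intervals": fit.n_intervals,
                    }
                )
    return pd.DataFrame(rows)
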