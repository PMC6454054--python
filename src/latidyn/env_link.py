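"""Climate/plant predictors and statistical linkage to microbial features.

Climate summaries are computed backward from each sampling date: week = 7
days and month = 30 days ending at (and including) the sampling date;
season = the fixed calendar window of the sampling year (Spring
March-May, Summer June-August, Autumn September-November).  DTR is the
window mean of daily (Tmax - Tmin); TR the window-wide max(Tmax) -
min(Tmin); AT the window mean temperature; Precip the window sum of daily
precipitation.

Linkage tools: greedy predictor dereplication at |r| > 0.8, stepwise
OLS/AIC model search on standardized variables, lmg relative-importance
decomposition of R^2 by averaging sequential contributions over all
predictor orderings, 4-way variation partitioning on adjusted R^2 with
per-group forward selection, PCNM spatial eigenvectors with Moran's I
flags, and a two-tailed Pearson screen.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "climate_summaries",
    "plant_summaries",
    "niche_breadth",
    "pcnm",
    "dereplicate_predictors",
    "fit_ols_aic",
    "OlsAicResult",
    "relative_importance_lmg",
    "variation_partition",
    "pearson_screen",
]

SEASON_MONTHS = {"Sp": (3, 4, 5), "Su": (6, 7, 8), "A": (9, 10, 11)}


def _window_days(date: pd.Timestamp, season: str, year: int, scale: str):
    if scale == "week":
        return pd.date_range(end=date, periods=7, freq="D")
    if scale == "month":
        return pd.date_range(end=date, periods=30, freq="D")
    if scale == "season":
        months = SEASON_MONTHS[season]
        start = pd.Timestamp(year=year, month=months[0], day=1)
        end = pd.Timestamp(year=year, month=months[-1], day=1) + pd.offsets.MonthEnd(0)
        return pd.date_range(start, end, freq="D")
    raise ValueError(f"unknown scale: {scale}")


def climate_summaries(
    daily_series: pd.DataFrame, sampling_dates: pd.DataFrame, scale: str = "season"
) -> pd.DataFrame:
    """Windowed climate summaries per (site, season, year).

    ``daily_series`` needs columns site, date, tmax, tmin and precip
    (tmean optional; defaults to the midpoint of tmax and tmin).
    ``sampling_dates`` needs columns site, season, year, date (one row per
    campaign).  Missing days inside a window raise an error listing them.
    """
    daily = daily_series.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    if "tmean" not in daily.columns:
        daily["tmean"] = (daily["tmax"] + daily["tmin"]) / 2.0
    rows = []
    for _, camp in sampling_dates.iterrows():
        site, season, year = camp["site"], camp["season"], int(camp["year"])
        date = pd.Timestamp(camp["date"])
        window = _window_days(date, season, year, scale)
        sub = daily[daily["site"] == site].set_index("date")
        missing = window.difference(sub.index)
        if len(missing):
            raise ValueError(
                f"site {site}: {len(missing)} days missing from climate series "
                f"in {scale} window, e.g. {list(missing[:3])}"
            )
        win = sub.loc[window]
        rows.append(
            {
                "site": site,
                "season": season,
                "year": year,
                "scale": scale,
                "DTR": float((win["tmax"] - win["tmin"]).mean()),
                "TR": float(win["tmax"].max() - win["tmin"].min()),
                "AT": float(win["tmean"].mean()),
                "Precip": float(win["precip"].sum()),
                "Precip_SD": float(win["precip"].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def plant_summaries(monthly: pd.DataFrame) -> pd.DataFrame:
    """Intra-seasonal mean and SD of monthly plant variables.

    ``monthly`` needs columns site, year, month plus one column per
    variable (e.g. GPP, LAI_tree, lf_leaf); output has <var>_avg and
    <var>_SD per (site, season, year) over the season's calendar months.
    """
    value_cols = [
        c for c in monthly.columns if c not in ("site", "year", "month")
    ]
    rows = []
    for (site, year), sub in monthly.groupby(["site", "year"]):
        for season, months in SEASON_MONTHS.items():
            win = sub[sub["month"].isin(months)]
            if win.empty:
                continue
            row = {"site": site, "season": season, "year": int(year)}
            for c in value_cols:
                row[f"{c}_avg"] = float(win[c].mean())
                row[f"{c}_SD"] = float(win[c].std(ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)


def niche_breadth(variable_by_site_season: pd.DataFrame) -> pd.Series:
    """Per-site niche breadth of one climatic variable.

    Input: columns site, value, one row per site x season (x year).  The
    variable is standardized jointly across all rows (mean 0, SD 1);
    breadth per site is the sample variance of that site's standardized
    seasonal values.
    """
    df = variable_by_site_season
    values = df["value"].to_numpy(dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("variable has zero global SD; niche breadth undefined")
    z = (values - values.mean()) / sd
    out = pd.Series(z, index=df["site"].to_numpy()).groupby(level=0).var(ddof=1)
    out.name = "niche_breadth"
    return out


def pcnm(coordinates: np.ndarray, ids=None) -> pd.DataFrame:
    """Principal coordinates of neighbour matrices (spatial eigenvectors).

    The pairwise distance matrix is truncated at t = the longest edge of
    its minimum spanning tree; distances beyond t are replaced by 4t.
    Principal-coordinate eigenvectors with positive eigenvalues are
    returned in descending eigenvalue order, each with Moran's I computed
    against the truncated connectivity (neighbours = pairs within t) and a
    positive-I selection flag.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if n < 3:
        raise ValueError("PCNM needs at least 3 locations")
    d = squareform(pdist(coords))
    if np.all(d[np.triu_indices(n, 1)] == 0):
        raise ValueError("all locations coincident")
    mst = minimum_spanning_tree(d).toarray()
    t = mst.max() * (1.0 + 1e-8)  # tolerance: keep the MST's own edges
    trunc = np.where(d <= t, d, 4.0 * t)
    np.fill_diagonal(trunc, 0.0)
    a = -0.5 * trunc**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10 * abs(vals[0]), 1e-12)
    vals, vecs = vals[pos], vecs[:, pos]
    # Moran's I against the binary truncated-neighbour weights
    w = ((d <= t) & (d > 0)).astype(float)
    s0 = w.sum()
    morans = []
    for k in range(vecs.shape[1]):
        x = vecs[:, k] - vecs[:, k].mean()
        morans.append(float(n / s0 * (x @ w @ x) / (x @ x)))
    cols = [f"PCNM{k + 1}" for k in range(vecs.shape[1])]
    out = pd.DataFrame(
        vecs * np.sqrt(vals), columns=cols,
        index=ids if ids is not None else range(n),
    )
    out.attrs["eigenvalues"] = vals
    out.attrs["morans_i"] = np.array(morans)
    out.attrs["positive_moran"] = np.array(morans) > 0
    out.attrs["truncation"] = float(t)
    return out


def dereplicate_predictors(
    x: pd.DataFrame, r_max: float = 0.8
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Greedy dereplication of strongly correlated predictors.

    Scanning columns in order, a column is dropped when its absolute
    Pearson correlation with an already-kept column strictly exceeds
    ``r_max``.  Returns the reduced matrix and a dropped -> kept report.
    """
    if not 0 < r_max < 1:
        raise ValueError("r_max must be in (0, 1)")
    kept: list[str] = []
    report: dict[str, str] = {}
    for col in x.columns:
        partner = None
        for k in kept:
            r = x[col].corr(x[k])
            if np.isfinite(r) and abs(r) > r_max:
                partner = k
                break
        if partner is None:
            kept.append(col)
        else:
            report[col] = partner
    return x[kept], report


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column; cannot standardize")
    return (a - a.mean(axis=0)) / sd


def _ols_rss(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), beta


def _aic(y: np.ndarray, x: np.ndarray) -> float:
    n = len(y)
    rss, _ = _ols_rss(y, x)
    k = (x.shape[1] if x.ndim == 2 else 0) + 1  # + intercept
    return n * math.log(rss / n) + 2 * (k + 1)  # +1 for the error variance


@dataclass
class OlsAicResult:
    selected: list[str]
    coefficients: pd.Series  # standardized scale, intercept excluded
    aic: float
    r_squared: float
    n: int


def fit_ols_aic(y: pd.Series, x: pd.DataFrame) -> OlsAicResult:
    """Stepwise (both directions) OLS model search minimizing AIC.

    Response and predictors are standardized to mean 0 / SD 1 first; the
    search starts from the full model and adds/removes one predictor per
    step while AIC improves.
    """
    names = list(x.columns)
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = xv.shape
    if n <= p + 2:
        raise ValueError(f"too few observations (n={n}) for p={p} predictors")
    if np.any(~np.isfinite(xv)) or np.any(~np.isfinite(yv)):
        raise ValueError("missing or non-finite values in inputs")
    if yv.std(ddof=1) == 0:
        raise ValueError("response has zero variance")
    xs = _standardize(xv)
    ys = _standardize(yv[:, None])[:, 0]
    if np.linalg.matrix_rank(xs) < p:
        raise ValueError("rank-deficient predictor matrix; dereplicate first")

    current = list(range(p))
    best_aic = _aic(ys, xs[:, current])
    improved = True
    while improved:
        improved = False
        candidates: list[tuple[float, list[int]]] = []
        for j in current:  # drop moves
            trial = [c for c in current if c != j]
            candidates.append((_aic(ys, xs[:, trial]), trial))
        for j in range(p):  # add moves
            if j not in current:
                trial = sorted(current + [j])
                candidates.append((_aic(ys, xs[:, trial]), trial))
        if candidates:
            cand_aic, cand = min(candidates, key=lambda c: (c[0], len(c[1])))
            if cand_aic < best_aic - 1e-10:
                best_aic, current, improved = cand_aic, cand, True
    rss, beta = _ols_rss(ys, xs[:, current])
    tss = float(ys @ ys)
    coeffs = pd.Series(beta[1:], index=[names[j] for j in current])
    return OlsAicResult(
        selected=[names[j] for j in current],
        coefficients=coeffs,
        aic=best_aic,
        r_squared=1.0 - rss / tss,
        n=n,
    )


def _subset_r2(y: np.ndarray, x: np.ndarray) -> dict[frozenset, float]:
    p = x.shape[1]
    tss = float(((y - y.mean()) ** 2).sum())
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for combo in itertools.combinations(range(p), size):
            rss, _ = _ols_rss(y, x[:, combo])
            r2[frozenset(combo)] = 1.0 - rss / tss
    return r2


def relative_importance_lmg(y: pd.Series, x_selected: pd.DataFrame) -> pd.Series:
    """lmg decomposition of a regression's R^2 into per-predictor shares.

    Share of predictor k = average, over all p! predictor orderings, of the
    R^2 increase when k enters.  Shares are non-negative and sum exactly to
    the full-model R^2.  Exact averaging enumerates all subsets, so p is
    guarded at 12.
    """
    p = x_selected.shape[1]
    if p == 0:
        raise ValueError("no predictors")
    if p > 12:
        raise ValueError("lmg exact averaging guarded at p <= 12; group predictors")
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x_selected, dtype=float)
    r2 = _subset_r2(yv, xv)
    shares = np.zeros(p)
    fact = math.factorial
    for k in range(p):
        total = 0.0
        others = [j for j in range(p) if j != k]
        for size in range(0, p):
            weight = fact(size) * fact(p - size - 1) / fact(p)
            for combo in itertools.combinations(others, size):
                s = frozenset(combo)
                total += weight * (r2[s | {k}] - r2[s])
        shares[k] = total
    return pd.Series(shares, index=list(x_selected.columns))


def _adj_r2(y: np.ndarray, x: np.ndarray) -> float:
    n = len(y)
    p = x.shape[1]
    if p == 0:
        return 0.0
    rss, _ = _ols_rss(y, x)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def forward_select(
    y: np.ndarray,
    x: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> list[str]:
    """Forward selection on adjusted R^2 with permutation significance.

    A variable is added while it gives the largest adjusted-R^2 increase
    and its partial F is significant at ``alpha`` under permutation of the
    current model's residuals.
    """
    rng = np.random.default_rng(seed)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    selected: list[str] = []
    remaining = list(x.columns)
    current_adj = 0.0
    while remaining:
        xv_cur = np.asarray(x[selected], dtype=float) if selected else np.empty((n, 0))
        scores = []
        for cand in remaining:
            xv = np.asarray(x[selected + [cand]], dtype=float)
            scores.append((_adj_r2(yv, xv), cand))
        best_adj, best = max(scores, key=lambda s: (s[0], s[1]))
        if best_adj <= current_adj + 1e-12:
            break
        rss0, beta0 = _ols_rss(yv, xv_cur)
        design0 = (
            np.column_stack([np.ones(n), xv_cur]) if xv_cur.size else np.ones((n, 1))
        )
        fitted0 = design0 @ beta0
        resid0 = yv - fitted0
        xv1 = np.asarray(x[selected + [best]], dtype=float)
        p1 = xv1.shape[1]
        rss1, _ = _ols_rss(yv, xv1)
        if rss1 <= 0:
            f_obs = np.inf
        else:
            f_obs = (rss0 - rss1) / (rss1 / (n - p1 - 1))
        ge = 1
        for _ in range(n_perm):
            y_star = fitted0 + rng.permutation(resid0)
            rss0s, _ = _ols_rss(y_star, xv_cur)
            rss1s, _ = _ols_rss(y_star, xv1)
            f_star = (
                (rss0s - rss1s) / (rss1s / (n - p1 - 1)) if rss1s > 0 else np.inf
            )
            if f_star >= f_obs:
                ge += 1
        if ge / (n_perm + 1) > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        current_adj = best_adj
    return selected


def variation_partition(
    y: pd.Series,
    x_groups: dict[str, pd.DataFrame],
    forward: bool = True,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> pd.Series:
    """Variation partitioning of adjusted R^2 across predictor groups.

    Each group is first reduced by permutation-tested forward selection
    (unless ``forward=False``).  Adjusted R^2 (Ezekiel) is computed for
    every union of groups and combined by inclusion-exclusion into unique
    and shared fractions.  Negative shared fractions are reported as-is;
    the fractions sum exactly to the full-model adjusted R^2, which is
    included under key 'total', with 'residual' = 1 - total.
    """
    names = list(x_groups.keys())
    g = len(names)
    if not 2 <= g <= 4:
        raise ValueError("variation partitioning supports 2-4 groups")
    yv = np.asarray(y, dtype=float)
    reduced: dict[str, pd.DataFrame] = {}
    for k, name in enumerate(names):
        frame = x_groups[name]
        if forward and frame.shape[1] > 0:
            cols = forward_select(yv, frame, alpha=alpha, n_perm=n_perm,
                                  seed=seed + k)
            frame = frame[cols]
        reduced[name] = frame

    def adj(subset: frozenset) -> float:
        frames = [reduced[names[i]] for i in sorted(subset)]
        frames = [f for f in frames if f.shape[1] > 0]
        if not frames:
            return 0.0
        xv = np.asarray(pd.concat(frames, axis=1), dtype=float)
        return _adj_r2(yv, xv)

    subsets = []
    for size in range(1, g + 1):
        subsets.extend(frozenset(c) for c in itertools.combinations(range(g), size))
    a = {s: adj(s) for s in subsets}
    # solve A_S = sum over fractions T with T ∩ S nonempty
    m = np.array(
        [[1.0 if t & s else 0.0 for t in subsets] for s in subsets]
    )
    rhs = np.array([a[s] for s in subsets])
    x_frac = np.linalg.solve(m, rhs)
    labels = {}
    for t, v in zip(subsets, x_frac):
        labels["&".join(names[i] for i in sorted(t))] = float(v)
    total = a[frozenset(range(g))]
    labels["total"] = float(total)
    labels["residual"] = float(1.0 - total)
    return pd.Series(labels)


def pearson_screen(
    features: pd.DataFrame, predictors: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-tailed Pearson correlation screen.

    Rows of the output are feature columns, columns are predictor columns;
    returns (r, p) DataFrames.  Zero-variance columns yield NaN cells.
    """
    n = len(features)
    if n != len(predictors):
        raise ValueError("features and predictors must have equal rows")
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    r = pd.DataFrame(index=features.columns, columns=predictors.columns, dtype=float)
    p = r.copy()
    for f in features.columns:
        for q in predictors.columns:
            x = np.asarray(features[f], dtype=float)
            yv = np.asarray(predictors[q], dtype=float)
            if x.std(ddof=1) == 0 or yv.std(ddof=1) == 0:
                warnings.warn(f"zero-variance pair ({f}, {q}); flagged NaN")
                continue
            res = stats.pearsonr(x, yv)
            r.loc[f, q] = float(res.statistic)
            p.loc[f, q] = float(res.pvalue)
    return r, p
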