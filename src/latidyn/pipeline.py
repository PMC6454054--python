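"""End-to-end pipeline: ingest -> rarefy -> beta diversity -> turnover /
ses.MNTD / networks -> environmental linkage.

Every stage writes a tidy TSV into the run directory and records its
parameters, seeds and input checksums in ``manifest.json``; re-running an
identical configuration reproduces identical outputs for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    OtuTable,
    PhyloTree,
    read_metadata,
    read_otu_table,
    read_tree,
    remove_singletons,
    rarefy,
    write_otu_table,
)
from .diversity import pcoa, permanova, weighted_unifrac
from .time_decay import (
    build_pair_series,
    fit_time_decay,
    group_turnover,
    test_slope,
)
from .phylo_structure import ses_mntd, ses_mntd_frame
from .conet import (
    build_network,
    core_otus,
    correlation_matrix,
    network_topology,
    select_threshold,
)
from .env_link import (
    climate_summaries,
    dereplicate_predictors,
    fit_ols_aic,
    pcnm,
    pearson_screen,
    plant_summaries,
    relative_importance_lmg,
    variation_partition,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Input paths may be omitted when in-memory objects are passed to
    :func:`run_pipeline` (the synthetic preset does this).
    """

    out_dir: str = "latidyn_run"
    otu_path: str | None = None
    tree_path: str | None = None
    meta_path: str | None = None
    climate_path: str | None = None
    plant_path: str | None = None
    soil_path: str | None = None
    depth: int = 7000
    seed: int = 0
    prevalence: float = 0.5
    r_max: float = 0.8
    n_null: int = 199
    n_rand: int = 0  # slope-test randomizations; 0 skips the test
    n_perm_adonis: int = 999
    min_rel_abundance: float = 0.01
    network_threshold: str = "auto"  # 'auto' or a fixed value in (0,1)
    run_networks: bool = True
    run_linkage: bool = True

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_config(path) -> RunConfig:
    """Read a flat ``key = value`` config file."""
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in RunConfig.__dataclass_fields__:
            raise ValueError(f"unknown config key: {key}")
        default = getattr(RunConfig(), key)
        if isinstance(default, bool):
            kwargs[key] = value.lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            kwargs[key] = int(value)
        elif isinstance(default, float):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _site_year_climate(climate: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Seasonal-scale climate summaries averaged per (site, year)."""
    campaigns = (
        metadata.reset_index()[["site", "season", "year", "date"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    summaries = climate_summaries(climate, campaigns, scale="season")
    agg = {
        "DTR": "mean", "TR": "mean", "AT": "mean",
        "Precip": "mean", "Precip_SD": "mean",
    }
    return summaries.groupby(["site", "year"], as_index=False).agg(agg)


def run_pipeline(
    config: RunConfig,
    table: OtuTable | None = None,
    tree: PhyloTree | None = None,
    metadata: pd.DataFrame | None = None,
    climate: pd.DataFrame | None = None,
    plant: pd.DataFrame | None = None,
    soil: pd.DataFrame | None = None,
) -> dict:
    """Execute the pipeline; returns a dict of result frames and writes the
    run directory with a provenance manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }

    # ---- ingest -----------------------------------------------------------
    for label, path in (
        ("otu", config.otu_path), ("tree", config.tree_path),
        ("meta", config.meta_path), ("climate", config.climate_path),
        ("plant", config.plant_path), ("soil", config.soil_path),
    ):
        if path is not None:
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"{label} input not found: {path}")
            manifest["inputs"][label] = _sha256(p)
    if table is None:
        if config.otu_path is None:
            raise ValueError("no OTU table given (path or in-memory)")
        table = read_otu_table(config.otu_path)
    if tree is None:
        if config.tree_path is None:
            raise ValueError("no tree given (path or in-memory)")
        tree = read_tree(config.tree_path)
    if metadata is None:
        if config.meta_path is None:
            raise ValueError("no metadata given (path or in-memory)")
        metadata = read_metadata(config.meta_path)
    if climate is None and config.climate_path is not None:
        climate = pd.read_csv(config.climate_path, parse_dates=["date"])
    if plant is None and config.plant_path is not None:
        plant = pd.read_csv(config.plant_path)
    if soil is None and config.soil_path is not None:
        soil = pd.read_csv(config.soil_path)

    table = remove_singletons(table)
    table = rarefy(table, config.depth, seed=config.stage_seed("rarefy"))
    write_otu_table(table, out / "otu_rarefied.tsv")
    manifest["stages"]["ingest"] = {
        "n_samples": table.n_samples,
        "n_otus": table.n_otus,
        "depth": config.depth,
    }
    metadata = metadata.loc[[s for s in table.sample_ids if s in metadata.index]]
    sites = sorted(metadata["site"].unique())
    years = sorted(metadata["year"].unique())

    results: dict = {"table": table, "metadata": metadata}

    # ---- beta diversity / ordination / adonis -----------------------------
    dist = weighted_unifrac(table, tree, normalized=True)
    dist.write(str(out / "weighted_unifrac.tsv"))
    ordination = pcoa(dist)
    ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
    perm = permanova(
        dist,
        metadata[["site", "season"]],
        n_perm=config.n_perm_adonis,
        seed=config.stage_seed("adonis"),
    )
    adonis_frame = pd.DataFrame(
        {
            "term": list(perm.r_squared_by_term),
            "r_squared": list(perm.r_squared_by_term.values()),
            "pseudo_F": [perm.f_by_term[t] for t in perm.r_squared_by_term],
            "p": [perm.p_by_term[t] for t in perm.r_squared_by_term],
        }
    )
    adonis_frame.to_csv(out / "adonis.tsv", sep="\t", index=False)
    results["distance"] = dist
    results["pcoa"] = ordination
    results["adonis"] = perm
    manifest["stages"]["beta"] = {
        "pseudo_F": perm.pseudo_F,
        "p": perm.p_value,
        "r2": perm.r_squared_by_term,
    }

    # ---- turnover ---------------------------------------------------------
    rows = []
    for site in sites:
        scopes = [("combined", None)] + [(str(y), y) for y in years]
        for label, year in scopes:
            try:
                series = build_pair_series(dist, metadata, site=site, year=year)
                fit = fit_time_decay(series)
            except ValueError as exc:
                warnings.warn(f"turnover {site} ({label}): {exc}")
                continue
            p_slope = np.nan
            if config.n_rand >= 99:
                p_slope = test_slope(
                    series, n_rand=config.n_rand,
                    seed=config.stage_seed(f"slope:{site}:{label}"),
                ).p_empirical
            rows.append(
                {
                    "site": site, "year_scope": label, "w": fit.w,
                    "slope_sign": fit.slope_sign, "intercept": fit.intercept,
                    "r_squared": fit.r_squared, "n_pairs": fit.n_pairs,
                    "n_intervals": fit.n_intervals, "p_slope": p_slope,
                }
            )
    turnover = pd.DataFrame(rows)
    turnover.to_csv(out / "turnover.tsv", sep="\t", index=False)
    results["turnover"] = turnover
    manifest["stages"]["turnover"] = {"n_fits": len(turnover)}

    if table.taxonomy:
        groups = group_turnover(
            table, tree, metadata,
            min_rel_abundance=config.min_rel_abundance,
            year_scopes=["combined"] + [str(y) for y in years],
        )
        groups.to_csv(out / "turnover_groups.tsv", sep="\t", index=False)
        results["turnover_groups"] = groups

    # ---- ses.MNTD ---------------------------------------------------------
    ses_frames = []
    for site in sites:
        ids = metadata.index[metadata["site"] == site]
        res = ses_mntd(
            table.select_samples(ids), tree, n_null=config.n_null,
            seed=config.stage_seed(f"ses:{site}"), pool="table",
        )
        frame = ses_mntd_frame(res)
        frame.insert(0, "site", site)
        ses_frames.append(frame)
    ses_table = pd.concat(ses_frames)
    ses_table.to_csv(out / "ses_mntd.tsv", sep="\t")
    results["ses_mntd"] = ses_table
    manifest["stages"]["ses_mntd"] = {
        "n_null": config.n_null,
        "mean_ses_by_site": ses_table.groupby("site")["ses"].mean().to_dict(),
    }

    # ---- co-occurrence networks ------------------------------------------
    if config.run_networks:
        net_rows = []
        for site in sites:
            ids = metadata.index[metadata["site"] == site]
            sub = table.select_samples(ids)
            try:
                core = core_otus(sub, config.prevalence)
                corr = correlation_matrix(core)
                if config.network_threshold == "auto":
                    thr, _ = select_threshold(corr, method="rmt")
                else:
                    thr = float(config.network_threshold)
                net = build_network(corr, thr)
                # when the spectral criterion lands beyond fragmentation,
                # back off to the largest threshold that leaves edges
                while net.n_edges == 0 and thr > 0.35:
                    thr = round(thr - 0.05, 2)
                    net = build_network(corr, thr)
                topo = network_topology(net)
            except ValueError as exc:
                warnings.warn(f"network {site}: {exc}")
                continue
            net.edge_frame().to_csv(
                out / f"network_edges_{site}.tsv", sep="\t", index=False
            )
            net_rows.append(
                {
                    "site": site, "threshold": thr, "nodes": topo.nodes_n,
                    "links": topo.links_n,
                    "negative_links": topo.negative_links_n,
                    "avgCC": topo.avgCC, "GD": topo.GD, "M": topo.M,
                    "CB": topo.CB, "CS": topo.CS,
                }
            )
        networks = pd.DataFrame(net_rows)
        networks.to_csv(out / "network_topology.tsv", sep="\t", index=False)
        results["networks"] = networks
        manifest["stages"]["networks"] = {"n_networks": len(networks)}

    # ---- environmental linkage -------------------------------------------
    if config.run_linkage and climate is not None:
        site_coords = (
            metadata.reset_index()[["site", "latitude", "longitude"]]
            .drop_duplicates("site")
            .set_index("site")
            .loc[sites]
        )
        response = turnover[turnover["year_scope"] != "combined"][
            ["site", "year_scope", "w"]
        ].rename(columns={"year_scope": "year"})
        response["year"] = response["year"].astype(int)

        clim = _site_year_climate(climate, metadata)
        predictors = response.merge(clim, on=["site", "year"], how="left")
        if plant is not None:
            psum = plant_summaries(plant)
            pm = psum.groupby(["site", "year"], as_index=False).mean(numeric_only=True)
            predictors = predictors.merge(pm, on=["site", "year"], how="left")
        if soil is not None:
            sm = soil.groupby(["site", "year"], as_index=False).mean(numeric_only=True)
            predictors = predictors.merge(sm, on=["site", "year"], how="left")
        spatial = pcnm(site_coords.to_numpy(), ids=site_coords.index)
        keep_pcnm = [
            c for c, flag in zip(spatial.columns, spatial.attrs["positive_moran"])
            if flag
        ][:2]
        predictors = predictors.merge(
            spatial[keep_pcnm], left_on="site", right_index=True, how="left"
        )

        climate_cols = [c for c in ("DTR", "TR", "AT", "Precip", "Precip_SD")
                        if c in predictors.columns]
        plant_cols = [
            c for c in predictors.columns
            if c.startswith(("GPP", "LAI", "lf_")) and predictors[c].notna().all()
        ]
        soil_cols = [c for c in ("pH", "WC", "CN", "TNTP", "TOCDOC", "NH4NO3")
                     if c in predictors.columns]
        y = predictors["w"]

        # Pearson screen of turnover vs the seasonal climate variables
        r_tab, p_tab = pearson_screen(
            predictors[["w"]], predictors[climate_cols]
        )
        screen = pd.concat(
            {"r": r_tab, "p": p_tab}, axis=0
        )
        screen.to_csv(out / "pearson_screen.tsv", sep="\t")
        results["pearson_screen"] = (r_tab, p_tab)

        # OLS + AIC + lmg on the dereplicated pooled predictor matrix
        x_all = predictors[climate_cols + plant_cols + soil_cols + keep_pcnm]
        x_red, dropped = dereplicate_predictors(x_all, config.r_max)
        # with few site-year points, keep only the marginally strongest
        # predictors so the OLS stays identifiable
        max_p = max(1, len(y) - 4)
        if x_red.shape[1] > max_p:
            strength = x_red.apply(lambda col: abs(col.corr(y)))
            x_red = x_red[list(strength.sort_values(ascending=False).index[:max_p])]
        linkage = {}
        try:
            fit = fit_ols_aic(y, x_red)
            selected = fit.selected if fit.selected else list(x_red.columns[:1])
            lmg = relative_importance_lmg(y, x_red[selected])
            linkage = {
                "selected": selected,
                "aic": fit.aic,
                "r_squared": fit.r_squared,
                "lmg": lmg.to_dict(),
                "dropped": dropped,
            }
            lmg.rename("lmg_share").to_csv(out / "lmg_w.tsv", sep="\t")
        except ValueError as exc:
            warnings.warn(f"linkage OLS: {exc}")
        results["linkage"] = linkage

        # variation partitioning across the four predictor groups
        groups = {
            name: predictors[cols]
            for name, cols in (
                ("climate", climate_cols), ("plant", plant_cols),
                ("soil", soil_cols), ("spatial", keep_pcnm),
            )
            if cols
        }
        if len(groups) >= 2:
            vpa = variation_partition(
                y, groups, seed=config.stage_seed("vpa")
            )
            vpa.rename("fraction").to_csv(out / "vpa_w.tsv", sep="\t")
            results["vpa"] = vpa
        manifest["stages"]["linkage"] = {
            "n_points": len(predictors),
            "selected": linkage.get("selected", []),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
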