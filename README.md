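# latidyn

Seasonal dynamics of soil microbial communities along latitudinal
gradients: temporal turnover rates from similarity–time decay, null-model
phylogenetic relatedness, co-occurrence network topology, and statistical
linkage of these community features to climate, plant, soil and spatial
drivers.

`latidyn` is written for microbial ecologists who study how 16S OTU
communities change between seasons across a spatial gradient — the common
field design of several sites, repeated seasonal campaigns over multiple
years, and replicate plots per campaign — and who want the whole analysis
chain (counts → beta diversity → turnover/relatedness/networks →
environmental attribution) as one reproducible, tested pipeline.  A
first-class synthetic-study generator emulates that design with known
ground truth, so every stage can be exercised and validated without any
sequencing data.

## The statistics at the core

**Temporal turnover rate *w*.**  For pairs of samples within a site,
community similarity is `S = 1 − d_WU`, where `d_WU` is the normalized
weighted UniFrac distance (branch lengths weighted by differences in the
relative abundance of descendant taxa).  The species–time relationship is
fitted on log–log (Arrhenius) axes,

```
log10(S) = constant − w · log10(T)
```

with `T` the time interval in days between sampling dates and `w` the
turnover rate: larger `w`, faster compositional change.  Similarities are
averaged within each distinct interval before fitting; slopes are tested
against a permutation null (re-pairing similarities with intervals) and
compared between sites by bootstrap resampling of pairs.

**Phylogenetic relatedness (ses.MNTD).**  Mean nearest-taxon distance is
standardized against 999 richness-preserving label-shuffle null
communities; `ses.MNTD = (MNTD_obs − mean_null)/sd_null`.  Negative values
with low quantiles mean co-occurring taxa are more closely related than
chance (phylogenetic clustering).

**Co-occurrence networks.**  Core OTUs (present in >50 % of a site's
samples) are linked when their relative-abundance correlation passes a
threshold chosen by a random-matrix-theory spacing criterion; node degree,
betweenness, stress and clustering coefficient, plus network-level avgCC,
average path distance (GD), modularity (M) and Freeman centralization of
betweenness/stress (CB, CS), are computed in-package.

**Environmental linkage.**  Climate windows (week/month/season backward
from each sampling date) yield DTR, TR, AT and precipitation summaries;
responses are linked to climate/plant/soil/spatial predictor groups by
dereplication (|r| > 0.8), stepwise OLS/AIC on standardized variables,
lmg relative-importance decomposition of R², and 4-way variation
partitioning on adjusted R² with PCNM spatial eigenvectors.

## Worked example

```python
from latidyn.synthetic import StudyDesign, simulate_study
from latidyn.core_io import rarefy
from latidyn.diversity import weighted_unifrac
from latidyn.time_decay import build_pair_series, fit_time_decay

study = simulate_study(StudyDesign(tree_seed=1, dynamics_seed=2, climate_seed=3))
table = rarefy(study.table, 7000, seed=0)

for site in study.design.site_ids:
    ids = study.metadata.index[study.metadata.site == site]
    dist = weighted_unifrac(table.select_samples(ids), study.tree)
    fit = fit_time_decay(build_pair_series(dist, study.metadata, site=site))
    print(f"{site}: w = {fit.w:.4f}  r2 = {fit.r_squared:.2f}  "
          f"(target {study.truth['sites'][site]['w_target']})")
```

prints

```
DHF: w = 0.0006  r2 = 0.93  (target 0.0006)
JGF: w = 0.0011  r2 = 0.92  (target 0.0011)
BTM: w = 0.0048  r2 = 0.88  (target 0.0048)
DLF: w = 0.0260  r2 = 0.85  (target 0.0259)
CBF: w = 0.0276  r2 = 0.85  (target 0.0276)
```

i.e. the southern subtropical sites (DHF, JGF) turn over slowly, the
temperate northern sites (DLF, CBF) some forty times faster, and the
analysis recovers the generator's per-site turnover targets from the raw
counts.  The same objects feed the rest of the chain: `ses_mntd` for
relatedness, `conet` for networks, `env_link`/`pipeline` for the
environmental attribution.

The full pipeline runs from one flat config file:

```bash
latidyn simulate --seed 1 --out study/
latidyn run --config run.cfg        # ingest → beta → turnover → sesMNTD → networks → linkage
```

Each stage writes tidy TSVs and a `manifest.json` with parameters, seeds
and input checksums; identical configs reproduce identical outputs.

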