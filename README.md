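# modefire

Quantifying the influence of global climate modes on annual wildfire
occurrence across a gridded domain, using large initial-condition climate
ensembles.

A 30-year observational record badly under-samples internal climate
variability: the apparent correlation between, say, ENSO and regional
fire activity can change sign from one 30-year draw to the next. Large
ensembles — many independent realizations of the same climate under fixed
forcing — provide the sample size (here 1600 member-years per time slice)
needed to map teleconnections to wildfire robustly. `modefire` implements
the full analysis chain for that design, plus a synthetic-ensemble
generator with known ground truth so every stage is testable without any
data download.

## What it computes

**Mode indices** (`modefire.indices`). The standard catalogue of eleven
climate-mode recipes from monthly sea-level-pressure and sea-surface-
temperature fields: box-difference indices (the equatorial SOI for ENSO —
positive = La Niña; the DMI for the Indian Ocean Dipole), box anomalies
(TNA, TSA), principal-component indices (PDO, NAO, EA, AO, PNA, SAM; EOFs
of cos-latitude-weighted anomalies, orientation fixed by a reference-box
sign convention), and the Atlantic-minus-global-ocean contrast (AMO).
Monthly indices are aggregated to annual values per recipe-specific
windows (calendar mean, NDJFM, DJF, NDJ, JJA — windows starting in the
previous year leave the first ensemble year undefined), optionally lagged
by one year, and classified into phases: positive when the annual value
exceeds +½σ, negative below −½σ, neutral otherwise.

**Fire association** (`modefire.association`). The central model object:

```
y_c(m, t) = α_c + β_c · x(m, t) + ε          (per grid cell c, member m, year t)
```

`FireModeModel(counts, indices).fit("ENSO")` regresses annual fire counts
on the raw index value at every cell, pooling member-years as
exchangeable samples, and controls the false discovery rate across cells
with the Benjamini–Hochberg step-up (the Wilks field-significance
procedure) at control level 0.01. The `FireModeResults` object carries
slope, p-value and significance maps, area-weighted extent percentages,
and phase-conditional effect ratios (mean fires in phase ÷ all-year mean,
whose phase-frequency-weighted sum is exactly 1). `fit_multimode`
regresses counts relative to the cell mean on several *standardized*
indices at once, which disentangles correlated modes (e.g. an IOD "effect"
that is really ENSO seen through their mutual correlation). Cross-phase
conditional tables, driver-field ratio maps (VPD, precipitation, GPP) and
recent-vs-warmer-climate comparisons (strengthening ratios, extent
transitions) complete the stage.

**Seasonality** (`modefire.seasonality`). The fire season's timing on the
annual circle: monthly counts become vectors n_m·exp(2πi(m−1)/12); the
resultant's angle is the mean phase and its normalized length the
seasonal concentration (0 = uniform, 1 = single month; cells below 0.15
have no distinct peak and are excluded from shift maps). Season length is
the mean number of months strictly exceeding half the climatological
peak-month count.

**Small-sample diagnostics** (`modefire.smallsample`). What a short record
can detect: percentile spreads of the index–weather correlation over
random 30-year subsamples of the ensemble, and a bootstrap null for
phase-conditional mean fire totals at reanalysis-period sample sizes
(10,000 replicates by default).

**Synthetic ensemble** (`modefire.synthetic`, `modefire.scenario`).
Standardized AR(1) latent mode series with prescribed cross-correlations;
SLP/SST fields embedding each mode as a fixed spatial loading at exactly
the locations the catalogue recipes read; Poisson fire counts whose
log-rate is linear in the (optionally lagged) latents and whose seasonal
profile rotates or sharpens with mode phase. All parameters are recorded
so recovery can be verified.

## Worked example

```python
import numpy as np
from modefire import (FireModeModel, classify_phase, compute_mode_index,
                      load_mode_catalogue)
from modefire.scenario import build_demo_world

world = build_demo_world(n_members=25, n_years=10, seed=0)
cat = load_mode_catalogue()
enso = compute_mode_index(cat["ENSO"], slp=world.slp, sst=world.sst)
r = np.corrcoef(enso.values.ravel(), world.truth[0].latent.values.ravel())[0, 1]
print(f"index-latent correlation: {r:.3f}")

model = FireModeModel(world.fire_counts, {"ENSO": enso})
res = model.fit("ENSO", alpha_fdr=0.01)
print(res.summary())

phases = classify_phase(enso)
ratios = res.phase_ratio_map(phases)
print(f"mean positive-phase ratio over significant cells: "
      f"{float(ratios['positive'].mean()):.3f}")
```

prints

```
index-latent correlation: 1.000
Fire-mode association: ENSO
  member-years pooled : 250
  cells analysed      : 150
  FDR control level   : 0.01
  significant cells   : 70
  area positive       :   46.7 %
  area negative       :    0.0 %
  area not significant:   53.3 %
mean positive-phase ratio over significant cells: 1.311
```

The demo world loads a positive ENSO effect (β = 0.25 per unit index) on
the western half of the fire grid: the recipe recovers the latent index
from the pressure field essentially exactly, the regression flags the
loaded half of the domain (46.7% of area) with no spurious negative
cells, and positive-phase years carry ~31% more fires than average in the
affected cells.

The same stages run from the shell:

```
modefire synth --members 25 --years 10 --seed 0 --out synth/
modefire indices --slp synth/slp.nc --sst synth/sst.nc --out indices.csv
modefire associate --fires synth/fires.nc --indices indices.csv --out assoc/
modefire run --seed 0 --out pipeline_out/   # full pipeline, demo world
```

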