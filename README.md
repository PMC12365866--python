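# firesev

**Drivers of high-severity wildfire occurrence: forest structure, fire
weather, and spatially robust inference.**

`firesev` implements, end to end and with known-truth synthetic data, a
landscape-scale analysis of why some 30 m pixels of forest burn at high
severity (composite burn index CBI > 2.25, ≈ 95% overstory mortality)
while neighboring pixels do not. It is written for fire ecologists and
remote-sensing analysts who work with LiDAR-derived stem maps, satellite
severity products, active-fire detections, and station weather.

## What it computes

**Forest structure** (per 30 m pixel, in 90 m "neighborhood" and 390 m
"stand" moving windows): stem density (trees ≥ 4 m, ha⁻¹), mean stem
height, mean canopy-gap area, and the Clark–Evans spatial homogeneity

```
h = (1/N) Σᵢ minⱼ uᵢⱼ  /  ½√(A/N)
```

(observed mean nearest-neighbor distance over its expectation under
complete spatial randomness; h < 1 clustered, h ≈ 1 random, h > 1
regular — the plantation signature). Per-pixel **ladder fuels** combine
Simpson evenness of canopy cover across the 2–8 / 8–16 / 16–32 / 32+ m
strata with total cover:

```
l = μ_c · (1/q) · (Σ_{k≤q} c_k)² / Σ_{k≤q} c_k²
```

where q is the tallest occupied band and μ_c the mean four-band cover.

**Fire timing and weather**: per-pixel 8-h burn windows reconstructed
from 375 m heat detections (cumulative buffered hulls), station weather
interpolated by distance and elevation difference, the hot-dry-windy
index (wind speed × vapor pressure deficit), 10-h fuel moisture, and
"incoming severity" (inverse-distance-weighted mean CBI of a 1000-pixel
sample from the previous window — fire contagion). Terrain: Horn slope
and aspect, 300 m topographic position index, McCune–Keon heat load.

**Inference**: binomial GLMs (IRLS) of high-severity occurrence on
standardized covariates, with interactions between the hot-dry-windy
index and four structure metrics; ownership contrasts
(private-industrial vs public vs other); percentile confidence
intervals from a **spatial block bootstrap** (fire severity is
spatially contagious, so i.i.d. resampling understates uncertainty);
spatially blocked k-fold evaluation (log-loss, AUC); and equal-sample
density differences between ownership classes.

A first-class synthetic-landscape module generates stem maps (Poisson /
Thomas-clustered / hard-core), crown cover bands, terrain, station
weather, a stochastic spreading fire with jittered satellite-style
detections, and severity outcomes from a configurable logistic truth —
so every stage is testable against known ground truth.

## Worked example

```python
import numpy as np
from firesev import (LandscapeGrid, WindowSpec, generate_stem_map,
                     spatial_homogeneity, stem_density, odds_ratio)
from firesev.validation import glm_recovery_experiment

grid = LandscapeGrid(0, 0, 30, 30)               # 900 x 900 m of 30 m pixels
plantation = generate_stem_map(grid, "regular", 400, min_spacing=4.0, seed=1)
wild = generate_stem_map(grid, "clustered", 1.0, cluster_parent_intensity=5,
                         cluster_size=20, cluster_sd=5, seed=1)
w = WindowSpec(390)
print(round(float(np.nanmean(spatial_homogeneity(plantation, grid, w))), 3),
      round(float(np.nanmean(spatial_homogeneity(wild, grid, w))), 3))
# 1.427 0.462   -> evenly spaced plantations h > 1, natural clustering h < 1

res = glm_recovery_experiment(n=50_000, seed=0)
print(round(res["fitted"]["stem_density"], 3), round(res["max_abs_error"], 3))
# 0.318 0.015   -> the generating density effect (0.32) is recovered
print(round(odds_ratio(res["fitted"]["stem_density"]), 2))
# 1.37          -> one sd more stems ~ 1.4x the odds of high severity
```

Run the full synthetic pipeline from the shell:

```bash
firesev run --seed 0 --out runs/demo        # all stages, writes a manifest
firesev simulate --workspace ws --seed 0    # or stage by stage
firesev terrain --workspace ws
```

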