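# pelletscape

Spatially explicit *ex post* assessment of timberland structure and carbon
stocks inside wood-pellet-mill procurement landscapes.

Wood pellet mills source fiber from a roughly circular *procurement
landscape* around the plant — 80 km radius for mills of at least 100
thousand tons/year nominal capacity, 48 km for smaller ones (competing
wood-using power plants and pulp mills procure within 80 km and 121 km).
`pelletscape` builds those landscapes, derives their covariates from
auxiliary layers (competition overlap, port access, drought exposure,
population), expands forest-inventory plots into landscape-level timberland
attributes, and estimates how those attributes co-move with the industry's
descriptors using a random-effects spatial-error panel model.  A calibrated
synthetic-data generator stands in for the restricted inventory, census and
drought data, so the entire analysis runs and is testable on a desktop.

It is written for landscape ecologists and spatial econometricians who want
a tested, reusable implementation of this estimation pipeline rather than a
one-off analysis script.

## The model

For each of six timberland attributes (numbers of live, growing-stock and
standing-dead trees; tons of carbon in live trees, standing-dead trees and
soil), the N = 123 landscape panel over t ∈ {2005, 2008, 2011, 2014, 2017}
is modelled as

```
Y_{N,t} = α + X_{N,t}β₁ + F_N β₂ + C_{N,t}β₃ + R_{N,t>2009}β₄
          + P_{N,t}β₅ + D_{N,t−1}β₆ + INT_{N,t}β₇ + u_{N,t}
u_{N,t} = (I_N − ρ W_N)⁻¹ ε_{N,t},        ε_{i,t} = μ_i + ν_{i,t}
```

with X the time-variant mill descriptors (operational dummy, years of
operation), F time-invariant descriptors (large capacity, export-port
access, coastal southeast, seven ecoregion indicators), C the pellet /
power / pulp procurement-area overlap fractions, R a post-2009 indicator,
P population (thousands), D a one-year-lagged extreme-drought flag and INT
eleven pairwise interactions.  W is the row-normalized inverse-distance
weight matrix over landscape centroids, truncated strictly at 161 km;
μ_i ~ N(0, σ²_μ) is a landscape random effect and ν_{i,t} ~ N(0, σ²_ν) an
idiosyncratic innovation.

Estimation is maximum likelihood with the likelihood concentrated over
(ρ, σ²_μ/σ²_ν): spatial filtering by (I − ρW) plus quasi-demeaning in time
reduce generalized least squares to ordinary least squares at each candidate
point, and a bounded quasi-Newton search with deterministic multi-starts
handles the remaining two parameters.  A restricted-likelihood (REML)
variant is available for bias-sensitive work.  A within-demeaned
fixed-effects counterpart and the Hausman χ² specification test support the
random- vs fixed-effects choice, and coefficients are post-processed into
standardized effects (β·S_x/S_y) and per-hectare rates.

## Worked example

```python
import numpy as np
from pelletscape.synthetic import SimulationConfig, generate_facilities, generate_plots
from pelletscape.pipeline import run_pipeline
from pelletscape.model import coef_table

cfg = SimulationConfig(seed=7)
fac, aux = generate_facilities(cfg)
plots = generate_plots(cfg, np.random.default_rng(cfg.seed + 1))
res = run_pipeline(fac, aux, plots, attributes=("live_trees",))

fit = res["fits"]["live_trees"]
print("rho:", round(fit.rho, 3))
print(coef_table(fit).loc[["intercept", "large_capacity", "mill_operational"]])
```

prints (seed 7):

```
rho: 0.26
                  coefficient  std_error        z      p
covariate
intercept           5.128e+08  1.319e+07    38.87      0
large_capacity      9.545e+08  1.867e+07    51.12      0
mill_operational    1.288e+06  8.859e+05    1.454  0.146
```

Read: the average small-mill landscape holds ~5.1 × 10⁸ live trees; a
large-capacity landscape (80 km radius instead of 48 km, so ~2.8× the area)
holds ~9.5 × 10⁸ more, and the spatial autocorrelation of the disturbances
is ρ̂ ≈ 0.26.  Dividing by the mean timberland area per landscape
(697,697 ha here) converts the large-capacity shift into ≈ 1,368 trees/ha.
The Hausman test on this fit (statistic 0.00, 16 d.o.f., p = 1.000) favours
the random-effects specification.  The same pipeline runs from the shell:

```sh
pelletscape all --seed 7 --outdir out        # six attributes + report bundle
```

writing per-attribute coefficient tables (`out/results/<attribute>.csv`
with coefficient, SE, ha-adjusted effect and p), the standardized
coefficients (`out/results/standardized.csv`), the Hausman summaries and a
manifest carrying the seed and config hash.

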