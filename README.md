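# stlgcp

Dynamic log-Gaussian Cox process modelling of spatio-temporal point patterns,
via the SPDE/GMRF discretisation and nested Laplace inference.

`stlgcp` is for analysts of geo-referenced event records — wildfire
detections, disease cases, crime reports — who want to separate *where* events
concentrate from *how their rate evolves*.  Events over a planar window Ω and
periods t = 1..T are modelled as an inhomogeneous Poisson process whose
log-intensity decomposes structurally:

    λ(s,t) = β₀ + z(s,t)ᵀβ + μ_t + s_t + c_t + ξ(s,t)

| term | role | prior |
|------|------|-------|
| μ_t  | long-term trend | second-order random walk (penalises Δ²μ_t) |
| s_t  | seasonality | lag-m autoregression, s_t = φ_s s_{t−m} + η_s |
| c_t  | stochastic cycle | stationary AR(2), PACF-parameterised (p₁, p₂) |
| z β  | covariate effects | diffuse Gaussian |
| ξ(s,t) | spatial heterogeneity | Matérn(ν=1) field × AR(1) in time (Φ) |

The Matérn field is discretised on a triangulation through its stochastic-PDE
representation: with lumped mass matrix C̃ and stiffness matrix G, the field
weights form a Gaussian Markov random field with sparse precision
Q = τ²(κ²C̃ + G)ᵀC̃⁻¹(κ²C̃ + G), where κ = √8/ρ sets the spatial range ρ and τ
the marginal variance σ².  The intractable intensity integral is handled by
dual-cell quadrature, turning the likelihood into (N + n_t) independent
Poisson pseudo-observations per period.  Fitting is a Laplace approximation
for the latent field nested inside an empirical-Bayes (or small-grid) search
over the hyperparameters (precisions, PACFs, log τ, log κ, Φ), reported as
mean / sd / 2.5–50–97.5% quantiles / mode.

A full synthetic-data generator (`stlgcp.simulate`) draws from exactly this
model — component paths, space-time field, covariate stand-ins, and event
placement by per-triangle thinning — so every stage of the pipeline can be
validated against known ground truth without external data.

## Worked example

Simulate a quarterly point pattern with a V-shaped trend and dry-season
seasonality, then decompose it:

```python
import numpy as np
from shapely.geometry import Polygon
from stlgcp import (SimulationScenario, ModelSpec, simulate_pattern,
                    augment_likelihood)
from stlgcp.inference import LGCPModel, fit

T = 16
scen = SimulationScenario(
    window=Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
    T=T, max_edge_inner=2.5, extension_fraction=0.0, intercept=1.0,
    trend_path=-np.abs(np.arange(T) - 8.0) / 4.0,          # decline then rise
    seasonal_path=np.tile([-0.3, -0.2, 0.2, 0.3], T // 4),  # peaks in Q3-Q4
    cycle_pacf=(0.3, -0.35), cycle_sd=0.1, seed=3,
)
pat, truth = simulate_pattern(scen)
data = augment_likelihood(pat, truth["mesh"], truth["weights"])
model = LGCPModel.build(pat, truth["mesh"], truth["fem"], truth["weights"],
                        data, ModelSpec(use_field=False))
res = fit(model, seed=1)

trend = res.components.query("component == 'trend'")["mean"].to_numpy()
print("events:", pat.n_events)
print("trend correlation with truth:",
      round(np.corrcoef(trend, truth["mu"])[0, 1], 3))
print(res.totals[["period", "observed", "mean", "q025", "q975"]].head(4).round(1))
```

Output:

```
events: 5041
trend correlation with truth: 0.979
   period  observed   mean   q025   q975
0       1        91   83.3   66.7  100.9
1       2        73   88.4   72.8  104.2
2       3       169  158.2  137.1  180.9
3       4       241  249.2  220.0  280.6
```

The fitted trend tracks the simulated decline-then-rise path (correlation
0.97), and the per-period predicted totals — the sum of intercept, trend,
seasonal and cycle components pushed through the intensity quadrature — track
the realised counts with calibrated 95% intervals.

The same pipeline is available from the shell:

```bash
stlgcp simulate --scenario scenario.yaml --out sim/
stlgcp fit --events events.csv --boundary window.geojson \
           --max-edge 6.5 --seed 1 --out fit/
stlgcp decompose --fit-dir fit/ --out decomposition/
```

`fit` writes `hyperparameters.csv`, `fixed_effects.csv`, `components.csv`,
`spatial_field.csv`, `intensity.csv`, `totals.csv` and a JSON run log; every
run is byte-reproducible from config + seed.

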