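# Methods

## Model

`stlgcp` fits a dynamic log-Gaussian Cox process to a spatio-temporal point
pattern observed over a planar window Ω and periods t = 1..T.  Conditional on
the log-intensity λ(s,t), events form an inhomogeneous Poisson process; the
log-intensity decomposes as

    λ(s,t) = β₀ + z(s,t)ᵀβ + μ_t + s_t + c_t + ξ(s,t)

with

- **trend** μ_t: second-order random walk, Δ²μ_t ~ N(0, σ²_μ).  Its null space
  (level and slope) makes it the carrier of smooth long-term change;
- **seasonality** s_t: lag-m autoregression s_t = φ_s s_{t−m} + η_s
  (m = 4 quarterly, 12 monthly).  φ_s = 1 gives the intrinsic seasonal random
  walk; by default φ_s is estimated, which covers both the random-walk and the
  damped-seasonal readings of the model;
- **cycle** c_t: stationary AR(2) with coefficients parameterised through the
  first two partial autocorrelations (p₁, p₂), so that stationarity is exactly
  the open box |p_k| < 1 and complex characteristic roots (a genuine cycle)
  occur when θ₁² + 4θ₂ < 0;
- **spatial field** ξ(s,t): a Matérn (ν = 1) Gaussian field in space with
  AR(1) dependence Φ across periods and per-period innovations that are
  independent between periods.  The per-period marginal covariance is held
  fixed at the Matérn covariance for every Φ (the AR(1) factor has unit
  stationary variance), so (σ, ρ) keep their interpretation regardless of the
  temporal dependence.

Covariates may be categorical (one-hot with a dropped reference level, first
level by default) or continuous (standardised).  At event locations covariate
values are taken from the nearest mesh node, not interpolated — categorical
covariates cannot be interpolated and continuous ones follow the same rule for
consistency.

## SPDE discretisation

The Matérn field is the stationary solution of (κ² − Δ) (τ x) = W for α = 2 in
d = 2 (ν = α − d/2 = 1).  On a triangulation with piecewise-linear basis
functions the Galerkin weak solution has precision

    Q = τ² (κ²C̃ + G)ᵀ C̃⁻¹ (κ²C̃ + G)

with C̃ the *lumped* mass matrix (row sums of ⟨φ_i, φ_j⟩ on the diagonal) and
G the stiffness matrix ⟨∇φ_i, ∇φ_j⟩.  We lump C in both factors: this is the
standard Markov construction, keeps Q as sparse as the squared mesh adjacency,
and is what makes the field a GMRF.  Interpretable parameters map to the
internal ones by κ = √(8ν)/ρ (ρ is the distance at which correlation ≈ 0.1)
and σ² = Γ(ν) / (4π κ^{2ν} τ² Γ(ν+1)).

The mesh is a Delaunay triangulation of a hexagonal lattice (spacing =
`max_edge_inner`) plus densified boundary rings, extended by an outer ring of
width `extension_fraction` × window diameter (default 0.2) at 3× coarser
resolution.  The extension pushes the Neumann boundary artefacts of the SPDE
approximation outside the window.  It is not a constrained Delaunay
triangulation; with the extension ring the window interior is nevertheless
covered, and the FEM-implied correlations converge to the analytic Matérn
under refinement (tested at three resolutions).

## Likelihood approximation

The Cox likelihood involves ∫_Ω exp(λ) per period.  We approximate it with a
dual-cell quadrature: each vertex k gets weight α_k = area(dual cell ∩ Ω),
where dual cells are the *barycentric* (centroid/edge-midpoint) polygons —
always positive, exactly area-conserving (Σα_k = |Ω|), and exact for constant
integrands.  The likelihood then factorises into (N + n_t) independent
Poisson-type pseudo-observations per period: node rows with response 0 and
exposure α_k·e(s_k,t), and event rows with response 1 and exposure exactly 0
(their contribution is the linear predictor itself — the clean limit of the
augmented scheme, avoiding spurious quadrature mass at data points).  The
exposure offset e(s,t) defaults to 1 (a pure point process) and is
configurable; only the product α·e enters the likelihood.

## Inference

Fitting is nested-Laplace in the INLA spirit, with two simplifications
relative to the full method, both documented below.

**Inner step.** For fixed hyperparameters θ the latent field x (fixed effects,
component paths, field values) has a log-concave posterior; Newton iteration
with step halving finds the mode x*, and the Gaussian approximation
N(x*, Q_post⁻¹) with Q_post = Q_prior + Bᵀ diag(a e^{η*}) B supplies latent
means, variances and the Laplace evidence

    log π(θ|Y) ≈ log π(θ) + ℓ(x*) − ½x*ᵀQ_p x* + ½log|Q_p| − ½log|Q_post|.

Convergence: max |gradient| < 1e-6 or relative mode change < 1e-8, max 50
iterations; a line search stalled at floating-point resolution is treated as
converged (the objective is concave).  Factorisations use SuperLU in symmetric
mode with diagonal pivoting, which for SPD matrices yields the Cholesky
pivots and hence the log-determinant.

**Hyperparameters.** θ collects the component log-precisions, the Fisher-z
transforms of (φ_s, p₁, p₂, Φ), and (log τ, log κ) — at most nine dimensions.
Default priors are weakly informative: log-gamma(1, 5e-5) on log-precisions,
standard normal on Fisher-z coordinates, and independent normals (sd 1) on
(log τ, log κ) centred at values implying σ = 1 and ρ = 20% of the window
diameter.  All are configurable (`PriorConfig`).  The default strategy `eb`
maximises the evidence with L-BFGS-B (finite-difference gradients, step 1e-4)
and takes hyperparameter uncertainty from the finite-difference Hessian at the
mode; `grid` adds an axial exploration (mode ± 1.2 sd per coordinate) whose
re-weighted moments widen the reported sds.  A full CCD/grid integration is
deliberately out of scope at nine dimensions.

**Constraints.** The RW2 trend (and the seasonal phases when φ_s is fixed
at 1) are intrinsic.  Two choices make the evidence well defined and the
components identifiable: (i) intrinsic prior blocks receive a 1e-6 diagonal
jitter, i.e. the improper prior is replaced by a proper one with very weak
shrinkage on the null space — the jittered log-determinant is computed through
the structure-matrix eigenvalues so it stays stable at extreme precisions;
(ii) sum-to-zero constraints (Σμ_t = 0; Σs_t = 0 for the fixed-φ_s seasonal)
are imposed exactly on the reported posterior by conditioning by kriging, on
both means/variances and the posterior draws.  The explicit intercept carries
the level.  The seasonal constraint is deliberately a *single* overall sum:
constraining each phase's time-sum separately would annihilate the static
phase pattern — the very signal the component exists to carry — because the
phase levels span the intrinsic null space of the lag-m random walk.

**Latent summaries.** The latent covariance at the hyperparameter mode is
inflated by the Kass–Steffey empirical-Bayes correction,
Σ → Σ + J Σ_θ Jᵀ with J = ∂x*(θ)/∂θ (finite differences), so fixed-effect and
component intervals reflect hyperparameter uncertainty instead of conditioning
it away; this matters most for effects confounded with the spatial field
(e.g. static, spatially smooth covariates).  Marginal quantiles are Gaussian
(mean ± z·sd) with no skewness correction — a simplification versus full INLA that the
Laplace-vs-quadrature oracle shows is accurate to ~1% in data-rich settings
and conservative otherwise.  Nonlinear functionals (per-period predicted
totals Σ_k α_k exp(λ_{kt})) are summarised from 500 kriging-corrected draws of
the Gaussian approximation; all draws run off the single `seed` argument, so a
fit is bit-reproducible.

## Synthetic data

The generator draws from exactly the model above: component paths by their
defining recursions (RW2 by double summation, seasonal by lag-m recursion,
cycle by a stationary AR(2) start plus recursion, all centred), the field by a
stationary draw followed by the AR(1) recursion with innovation scale
√(1−Φ²), and events per triangle by Poisson counts with vertex-quadrature
means followed by rejection sampling against the triangle's maximum vertex
intensity — exact for piecewise-linear log-intensity, with no grid bias.
Covariate stand-ins: a nearest-centroid class partition (climate/land-cover
analogue), seasonally modulated random polynomial surfaces standardised to
mean 0/sd 1 (temperature/rainfall analogues), and distance-to-polyline scaled
to unit sd (highway analogue; zero stays zero on the line).

What the generator does *not* emulate: sensor artefacts (detection gaps,
confidence weighting), real geography or genuinely non-separable space-time
dependence.  Passing recovery tests therefore certifies the estimator under
the model's own assumptions — correct likelihood, separable covariance — not
robustness to their violation.

The Amazon-like preset fixes the study conditions used by the validation
runs: an irregular pentagon ≈100×70 km-units, T = 8 quarters, a V-shaped
(decline-then-rise) trend, dry-season seasonality peaking in periods 3–4, a
mild stochastic cycle, β = (+0.3 temperature-like, −0.3 rainfall-like, −0.4
distance-to-road), σ = 1, ρ = 20% of the window diameter, Φ = 0.8, intercept
−4 (a few hundred events per period), and a 6.5 km mesh edge giving ≈200
vertices.  Sign pattern follows the fire-ecology expectation (hotter/drier
and road-accessible areas burn more); magnitudes are ours.

## Validation problem sizes

The validation suite uses deliberately desk-scale problems: the FEM/Matérn
oracle on a 41×41 regular grid; parameter recovery over 20 replicates of the
preset (~200 nodes × 8 periods, ~10³ events per replicate); decomposition
recovery on a 16-quarter single-window study without the spatial field.
These sizes were chosen so the entire validation cycle runs on one CPU in
minutes while keeping every estimate's Monte-Carlo error well below the
tolerance it is checked against.

## Known limitations

- Gaussian latent marginals (no skewness correction) understate asymmetry in
  data-poor regions.
- Empirical-Bayes hyperparameter treatment ignores hyperparameter uncertainty
  in the latent summaries; interval coverage bounds in the tests are set
  accordingly (≥80% rather than nominal 95%).
- Smooth continuous covariates are partially confounded with the spatial
  field; their posterior sds are honest about this (they widen), but point
  estimates can be imprecise in single replicates.
- α is fixed at 2 (ν = 1); no fractional smoothness, non-stationary κ(s)/τ(s),
  spherical meshes, or window polygons with holes.
- Latent dimension is capped (default 8000) by the dense posterior-covariance
  summary step; larger problems need a partial-inversion implementation that
  is out of scope here.
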