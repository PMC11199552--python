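# Methods

## Model

Disease status is a 0/1 vector `Y` over `N` individuals grouped into `N_F`
nuclear families, each family resident at one node of a location graph with
`L` nodes.  Individuals are ordered family-by-family and, within a family,
father, mother, then children by birth year; all vectors follow this
ordering.  The full model is

```
Y = X π + u_g + Z_par u_par + Z_child u_child + Z_s u_s + ε
```

with marginal covariance

```
V = σ²_g blk_diag(G_f) + σ²_par Z_par Z_parᵀ + σ²_child Z_child Z_childᵀ
    + Z_s Σ_s Z_sᵀ + σ²_ε I .
```

Assumptions worth stating explicitly:

- **Linear model on the observed scale.**  The binary outcome is modeled by
  a Gaussian working likelihood.  The covariance-parameter estimating
  equations remain unbiased when the covariance model is correct, so the
  variance components are consistently estimated even though `Y` is not
  Gaussian; efficiency, not consistency, is what is given up.
- **Kinship by label.**  Within a family, all parent–child and sibling
  pairs get expected relationship 0.5 and spouses 0; families are
  genetically unrelated to each other.  Single-parent, children-only, and
  large sibships extend by the same rules.  Half/step relations are not a
  separate kinship class — the simulator's relationship-error injector
  exists precisely to measure the cost of that simplification.
- **One location per family.**  This makes `Z_sᵀ A⁻¹ Z_s` diagonal (see
  Estimation) and matches how families appear in claims data.

Spatial structures, with `W` the 0/1 border adjacency, `D` the diagonal of
neighbor counts and `W̃ = D^{-1/2} W D^{-1/2}`:

| structure | covariance `Σ_s` | precision (σ²_s = 1) |
|---|---|---|
| IND | σ²_s I | I |
| CAR | σ²_s (D − ρW)⁻¹ | D − ρW |
| SAR | σ²_s ((I−ρW̃) D (I−ρW̃))⁻¹ | (I−ρW̃) D (I−ρW̃) |

Both autoregressive precisions are positive definite for |ρ| < 1 because
the spectral radius of `W̃` is below 1 on a connected graph.  Isolated
locations (no neighbors) are treated as independent components with
variance σ²_s and excluded from the normalizations — this preserves
positive definiteness without dropping data.

Because CAR/SAR covariances have unequal diagonals, the reported spatial
variance is the **Gower factor**

```
σ̃²_s = tr[ Z_s (I − 11ᵀ/N) Σ_s Z_sᵀ ] / (N − 1) ,
```

the average per-individual variance of the (centred) community effect —
comparable across traits and structures.

## Estimation

Maximum likelihood with the fixed effects `π` profiled out at every
variance-parameter value (the profile gradient equals the partial gradient
by the envelope theorem).  Plain ML rather than REML keeps BIC comparisons
coherent across sub-models; `BIC = −2·loglik + p·log N` with `p` counting
variance parameters (including ρ where present) plus fixed effects, and
ties broken toward fewer parameters.

`V` is never formed densely.  The non-spatial part `A` is block diagonal
with one block per family; blocks depend only on the family signature
(#parents, #children), so families are grouped by signature and all block
solves are batched `einsum` contractions.  The spatial term is low rank
over locations and handled by the Woodbury identity

```
V⁻¹ = A⁻¹ − σ²_s A⁻¹ Z_s C⁻¹ Z_sᵀ A⁻¹ ,   C = P₀ + σ²_s D_A ,
log|V| = log|A| + log|C| − log|P₀| ,
```

where `P₀` is the unit-variance spatial precision and
`D_A = Z_sᵀ A⁻¹ Z_s` is diagonal.  `C` and `P₀` are `L×L` and factorized
densely; this is exact and fast for the graph sizes this package targets
(hundreds to a few thousand locations).  Gradients are analytic (trace
terms via `diag(C⁻¹)` and the dense `P₀⁻¹`; verified against central
differences to ~1e-9 relative error in the test suite).

Numerical choices:

- Variances are optimized as `log σ²` (bounded 18 log-units below the
  phenotype variance), ρ as `0.99·tanh(·)` — the cap keeps the precision
  comfortably positive definite.
- L-BFGS-B with `ftol = 1e-14`, `gtol = 1e-8`; multi-start from three
  deterministic initializations (equal split, residual-dominant,
  spatial/genetic-dominant).  A fit is flagged non-converged — returned,
  not raised — when the transformed gradient norm stays above
  `1e-3·|loglik|`.
- Standard errors: inverse observed information, where the Hessian is a
  central difference of the analytic gradient on the natural scale.
  Components estimated at the zero boundary are listed in
  `SmileFit.boundary`; their SEs are one-sided.
- Degenerate inputs raise typed errors: all-zero variances (non-PD `V`),
  prevalence 0 or 1, rank-deficient designs (offending columns named),
  |ρ| ≥ 1, empty families, duplicate ids.

## Liability-scale conversion

Estimates on the 0/1 scale are converted at the trait prevalence `K`
(threshold `t = Φ⁻¹(1−K)`, `z = φ(t)`).  The classical multiplier
`K(1−K)/z²` (available as `method="linear"`) is the first-order tetrachoric
expansion and is accurate only when pairwise correlations are small; for
family components (parent–child liability correlation `h²/2`) its relative
error is ≈ `t²ρ/2`, which reaches tens of percent for rare traits.  The
default `method="tetrachoric"` instead inverts the bivariate-normal orthant
map class by class — spouse, parent–child, sibling, and location-mate
observed correlations are mapped back to liability correlations with
`Φ₂(t,t;·)`, and the liability components are solved from the class system
(the map reduces exactly to the linear multiplier as components shrink).
The residual takes the remainder so liability components sum to 1.  The
round trip is validated in simulation at K = 0.01, 0.05, 0.2.

Known limitation: with spatially heterogeneous community variance the
per-location prevalence varies, and the single-threshold inversion is an
approximation; at the variance levels studied here the residual bias is
inside Monte-Carlo noise.

## BLUPs and community risk factors

`û_s = Σ_s Z_sᵀ V⁻¹ (Y − Xπ̂)` (empirical-Bayes shrinkage: `‖û_s‖ → 0` as
`σ²_s → 0`).  `correlate_blup_covariates` regresses/correlates BLUPs
against location-level covariates, after filtering traits to prevalence
≥ 2% and spatial variance ≥ 2% so that only traits with estimable
community signal are screened; constant covariates are reported as missing
rather than raising.

## Two-stage causal inference (SMILE-2)

Stage 1: OLS of the location-level exposure on the wind encoding
`(sin θ, cos θ, v, v·sin θ, v·cos θ)` — circular-safe in direction, with
speed–direction interactions; first-stage R² and F are reported as
instrument-strength diagnostics and a near-zero R² triggers a
weak-instrument warning (zero instrument variance is an error).

Stage 2: the fitted exposure `P̃`, centred and scaled by the observed
exposure SD (so β is per exposure SD — the two-stage estimand), enters the
G+P+C mixed model as the leading fixed effect.  Wald p-values come from the
fixed-effect covariance at the variance-component optimum.  The reported
odds ratio converts the linear-probability effect at the trait prevalence:
`OR = [(K+β)/(1−K−β)] / [K/(1−K)]`.

Two deliberate simplifications, both flagged in the API docs: second-stage
SEs do not propagate first-stage uncertainty (standard two-stage behavior;
exact under the null), and the stage-2 model carries **no spatial random
effect**, because the exposure is itself a location-level variable.  The
cost of the latter is that location-level residual variance the model
cannot absorb (community effects, confounder effects on liability) inflates
the test slightly; calibration holds when that residual variance is small
(~1–3% of liability variance, the regime of the packaged null experiments),
and degrades as it grows — a documented limitation of the no-spatial
second stage rather than of the implementation.

`IND-FE` is the comparator: OLS of `Y` on `(P̃, X)` over parents only
(genetically unrelated individuals, shared couple environment ignored).
The phenome screen tests every trait against PM2.5, NO2, and their
standardized sum, excludes traits under 0.1% prevalence with a recorded
reason, and applies Bonferroni at `0.05/(n_traits × 3)`.

## The synthetic-data generator

What it emulates, and the defaults:

- **Cohort geometry.**  Nuclear families (default: 2,000 quad families) on
  a 2-D 4-neighbor lattice (default 10×10) standing in for the county/MSA
  border graph.  Families are placed with log-normal location weights
  (σ = 1.25), reproducing the heavy-tailed families-per-location profile of
  claims cohorts (median within the reported (5, 50) interquartile band);
  an `even` allocation exists for calibration studies that need minimal
  clustering.  Ages, sexes, and enrollment durations mimic the published
  cohort summaries (parents ≈ 45–47, children ≈ 15 at first enrollment,
  enrollment ≥ 72 months with median ≈ 84).
- **Phenotypes.**  Liability = genetic (per-family multivariate normal on
  the relationship matrix) + parental + children + spatial + optional
  exposure and confounder terms + residual; components must sum to 1, and
  the default generating values (h² = 0.30, parental = 0.10,
  children = 0.10, spatial = 0.05 with CAR ρ = 0.6, residual 0.45) are in
  the range reported for moderately heritable complex diseases.  σ²_s is
  specified as the *Gower-standardized* variance: the spatial field is
  rescaled so its realized per-individual variance matches, and is drawn
  centred because the cohort-wide mean of community effects is absorbed by
  the intercept.  Binary outcomes threshold the liability at
  `Φ⁻¹(1−K)`; a `binary=False` mode returns the liability itself, used
  where an exactly Gaussian truth makes recovery checks sharp.
- **Exposures and instruments.**  Wind speed/direction are smooth fields on
  the graph (CAR ρ = 0.9 draws); exposure = 0.8·(wind signal) +
  0.5·confounder + 0.6·noise on the z-scale, mapped to realistic PM2.5 /
  NO2 levels.  The confounder is a smooth field drawn independently of
  wind (exogeneity by construction) and enters the liability, creating the
  endogeneity that instrumental variables exist to defeat.  A causal effect
  is specified as a relative risk per exposure SD and converted to a
  liability shift `t − Φ⁻¹(1 − RR·K)`.
- **Perturbations.**  `inject_relationship_errors` relabels a fraction of
  children as biological when they are adopted (no sharing) or
  stepchildren (one parent, quarter-sib siblings), leaving cohort labels
  untouched and recording the truth; `add_measurement_noise` adds relative
  Gaussian noise to pollution and wind (direction wrapped to [0, 360)).
  `scenario_grid` spans RR ∈ {1.0, 1.01, 1.05, 1.1, 1.2} × prevalence ×
  pollutant for power studies.

What it does **not** emulate — and what passing tests therefore do not
show: real US geography and its adjacency irregularities, diagnosis-code
noise and care-seeking behavior, enrollment dynamics and censoring,
ascertainment of insured families, time-varying exposures, and
assortative mating.  Conclusions from the simulation studies are about the
estimators under the stated generative model, not about any real cohort.

## Problem sizes in the packaged experiments

The validation suite runs desk-scale versions of the reference simulation
designs, sized so the full suite completes in minutes: 50 replicates of
2,000 quad families (10×10 lattice) for component recovery and
omitted-component bias (with a 25-replicate arm at tripled spatial
variance); 500 null replicates of 400 families (20×20, even allocation) for
type-I error; 200 replicates of 800 families for power/MSE; 10 replicates
each of 5,000 and 25,000 families × 8 candidate models for BIC selection
consistency (the weak children's component, 0.03, is sized by a power
calculation to be borderline at the smaller n and clearly detectable at the
larger — the regime in which selection consistency is visible); 15
replicates per prevalence for the liability round trip.  Every replicate
redraws the cohort, so Monte-Carlo standard errors include allocation
variability.
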