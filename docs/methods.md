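# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limitations of the `avivuln` pipeline.

## Origin assignment

A feather grown at cell *c* is modelled as δ²H ~ Normal(μ_c, σ_c), where
(μ_c, σ_c) come from a feather-calibrated isoscape (calibration is affine
in the mean, `μ' = intercept + slope·μ`, with the calibration residual SD
added in quadrature).  For an observed value the per-cell likelihoods over
the species range are normalized into origin probabilities p_c, always in
log space, so observations tens of SDs away from every cell still produce
finite, normalized surfaces.

The plausible-origin region uses a per-cell odds ratio against a
uniform-origin null: OR_c = [p_c/(1−p_c)] / [p₀/(1−p₀)] with p₀ = 1/K for
K range cells, including cells with OR ≥ 5 (ties included).  The exact
per-pixel odds computation is not standardized in the assignment
literature; the main alternative — the smallest set of top-probability
cells holding 5/6 cumulative mass — is available via `rule="cumulative"`.
The uniform-null form is the default because it yields per-pixel values
that the catchment weighting can aggregate.  Two consequences worth
knowing:

- In the diffuse limit (cell SD large relative to the isoscape gradient)
  every OR tends to 1 and the mask is empty: the data cannot beat the
  uniform null anywhere.  Masks therefore are not monotone in SD globally,
  only in the concentrating regime.
- A bird is called *local* iff the facility cell lies in its mask ∩ range.
  With one-cell-deep regions and a clear gradient this recovers true
  origins perfectly as SD → 0.

## Catchment areas and N_p

The aggregate surface of an origin class is the mean of the *binary*
individual masks, so each pixel holds the proportion of individuals whose
plausible region covered it.  (Averaging raw OR magnitudes instead can
exceed 1 and was rejected; the proportion reading keeps the
"stressor-affected proportion" interpretation.)  Catchment membership is
`aggregate > 0` by default; a minimum-proportion cutoff is available.

For each BCR *b* intersecting the catchment, the contribution to N_p is
w_b · estimate_b · frac_b, with w_b the mean aggregate over catchment cells
in *b* and frac_b the cell-count fraction of *b* inside the flyway (cells
are equal-area by construction).  The identical weights applied to the
95% LCI/UCI estimate columns propagate uncertainty, preserving
LCI ≤ mean ≤ UCI.  Species without regional estimates use continental
totals C_p scaled by the catchment's share of the range, with hypothetical
bounds 0.5×/2× — a spread slightly wider than the 0.52–1.63× range observed
for species that do have regional estimates.  Species with no isotope data
at all take the range ∩ flyway (minus the local BCR) as a non-local
catchment with weight 1.

## Demographic model

The projection matrix has Φ₁ on the first subdiagonal entry, Φ₂ on
intermediate ones, Φa on both the final transition and the adult-persistence
corner, and fecundity f in the first row (terminal class only by default;
earlier breeding via a flag).  λ is the spectral radius, which for these
non-negative matrices is the Perron root; it is robust even when a floored
Φa = 0 makes the matrix periodic.

The fit is a state-space model chosen as the simplest structure consistent
with annual index data: a deterministic projection from initial total N₀
(spread across classes at the stable stage distribution of the prior-mean
matrix) gives latent totals, and y_t ~ LogNormal(log(q·ΣN_t), σ²) with free
scale q and observation SD σ.  Process (demographic) stochasticity is
deliberately excluded from the fit and listed as a limitation below.

Priors: survivals get Beta distributions moment-matched to literature
mean/SE (falling back to uniform when the SE is too large for a Beta);
fecundity a Normal truncated at 0.  Three constraint levels truncate
further — none; μ_Φ ± 0.2 and μ_f ± 0.5μ_f; μ_Φ ± 0.1 and μ_f ± 0.25μ_f —
and the truncated densities are properly normalized.  Nuisance parameters:
σ ~ Half-Normal(1); q and N₀ get wide log-normal priors.

**Sampler.**  Adaptive random-walk Metropolis-within-Gibbs, compiled with
numba.  Two numerical choices matter:

- q and N₀ enter the likelihood only through their product, so the sampler
  works in rotated coordinates u = log(qN₀), v = log(q/N₀): u is data-
  identified, v prior-identified, and coordinate proposals mix both.
  Reported draws are q and N₀.
- The demographic block (survivals + f) lies on a near-constant-λ ridge
  that single-coordinate proposals traverse slowly.  Each sweep therefore
  adds one joint proposal from a Haario-style empirical-covariance normal
  (scaled 2.38/√d, adapted to 23% acceptance).  All adaptation happens
  during burn-in only and is then frozen, so retained draws satisfy
  detailed balance.

Default ("desk") protocol: 3 chains, 5 000 burn-in, 20 000 iterations,
thinning 20.  The full-scale protocol (9 chains, 50 000 burn-in, 200 000
iterations, thinning 1 000) is available as preset `"paper"`; the code path
is identical and the desk scale keeps a three-level fit under a second
while recovering λ to ±0.001 at σ_obs = 0.05 over 48 years.

Convergence uses R̂ = √[((n−1)/n·W + B/n)/W] per parameter over the stored
thinned draws (a completely stuck parameter reports 1.0 with a warning);
any R̂ ≥ 1.1 triggers one automatic doubling of iterations, after which a
still-failing fit is returned flagged non-converged so the species can be
excluded.  Candidates are compared by DIC = D̄ + p_D with
p_D = D̄ − D(posterior-mean parameters); the lowest-DIC converged candidate
wins, and a posterior-mean λ outside [0.5, 2] raises a biological-
feasibility warning rather than an automatic rejection.

## Fatality sensitivity

Added fatalities ΔD (grid 100…min(5000, N_p) in steps of 100, and 1–50% of
N_p in 1% steps) are all adults, additive, constant in time, and enter
solely through adult survival: Φa' = max(0, Φa − ΔD/N_p), the unique value
for which D = N_p(1−Φa) rises by exactly ΔD.  N_p itself is held constant
over the horizon.  Each of 1 000 iterations resamples a posterior vector,
perturbs Φa and projects 48 years; the projection starts at the perturbed
matrix's stable stage distribution, so the realized rate
(ΣN₄₈/ΣN₀)^(1/48) equals the dominant eigenvalue of the perturbed matrix
to machine precision.  The resampling indices are drawn once per
subpopulation and reused across the whole ΔD grid, which makes λ_s
monotone non-increasing draw-by-draw and vulnerability curves monotone
non-decreasing by construction.

CIU is the ratio of sample means of λ_s and λ_original (the full λ_s
distribution is retained; the summary is configurable to the median).  The
classification comparison `vulnerability ≥ 0.2` tolerates ~1e−9 of float
rounding so a reduction computed as 1 − 0.8/1.0 counts as hitting the
threshold.  The relative-risk 95% CI uses the Katz log-Wald form
exp(log RR ± 1.96·√(1/x_l − 1/N_l + 1/x_n − 1/N_n)); it is undefined (and
reported as such) when either fatality count is zero.

## Synthetic study system

The generator emulates the pipeline's inputs on an abstract north-up grid:
a row-linear isoscape (default slope −8 ‰ per row, cell SD 3 ‰, i.e.
adjacent rows ~2.7 SD apart — a clean but not noise-free gradient), BCRs as
horizontal bands, a flyway as a set of BCR labels (optionally clipped to a
column range to create partial BCRs), a single pooled facility cell, and
log-normal observation noise on the index series (indices are positive and
multiplicative; default σ_obs = 0.05 over 48 years).  Feather δ²H values
are drawn from the true origin cell's Normal; true origins and rates go to
a sidecar table that the pipeline under test never reads.

The demo cohort pairs a species with a ~2 500-bird local catchment and
λ = 1 exactly (Φ₁ = 0.5, Φa = 0.8, f = 0.4) against one with multi-million
catchments; the first is driven past the 0.2 threshold by ≤1 000 added
fatalities, the second barely moves at 5 000.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: real isoscape spatial structure and calibration
error, region geometry and area weighting, demographic stochasticity and
density dependence in the index series, observation error structure of real
surveys, multi-facility spatial spread, and seasonal moult variation.

## Known limitations

- The state-space likelihood linking indices to the matrix model is a
  documented stand-in; no standard form exists for this kind of fit.
- No immigration, emigration, density dependence or Allee effects; because
  fatalities are fully additive, vulnerability estimates are upper bounds.
- Grid cells are equal-area; no map projections.
- The per-pixel OR rule and the CIU summary are choices among defensible
  alternatives (both alternatives are implemented and documented above).
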