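# Methods

`dielocc` estimates how a guild of carnivores uses a human-dominated
landscape separately by day and by night, from camera-trap data, while
correcting for imperfect detection. This note documents the model, the
estimation machinery, the synthetic-data generator, and the numerical and
design choices a user should know about.

## Data model

A survey consists of camera stations `i = 1..N`, each deployed for `k_i`
whole trap days. Each photo is assigned a diel period from solar geometry
at a single reference point (the landscape centroid): **day** is the
half-open interval [sunrise − 1 h, sunset + 1 h); **night** is the
complement. Sunrise and sunset come from the NOAA solar position
equations (accuracy ~1–2 minutes at mid-latitudes); latitudes poleward of
66.5° are rejected because the day/night partition degenerates there.

An *occasion* is one trap day within one period at one station, so every
trap day contributes one day occasion and one night occasion and `k` is
identical for both periods of a site. `y_ij` counts occasions in period
`j` with at least one photo. Photos of one species at one site within a
rolling 24-hour window (anchored at the first photo of the current event)
are collapsed into a single *detection event* for effort reporting; the
event rule does not enter `y`, which is already binary per occasion.

Timestamps must carry an explicit UTC offset — naive timestamps are
rejected rather than guessed. Partial first/last deployment days count as
whole trap days. Boundary conventions (half-open day window, greedy event
anchoring) were open choices; they are fixed as stated so that rebuilding
histories is bit-identical.

## Occupancy model

For site `i` and period `j` (1 = day, 2 = night):

    z_ij ~ Bernoulli(psi_ij)                    presence
    y_ij | z_ij ~ Binomial(k_i, z_ij p_ij)      detection

    logit(psi_ij) = alpha1_j + beta_j' X_i + gamma_j psiD_ij + U_i + d_ij
    logit(p_ij)   = alpha2_j + delta_j' X_i + S_i

* `X_i` — standardized site covariates (elevation, distance to the
  protected area, native-forest presence at the plot, forest cover and
  road density and mean patch size in 250 m and 500 m buffers; detection
  side: season fraction and understory cover). Right-skewed covariates
  are log-transformed (`log(x + s)`, `s` = half the smallest positive
  value when zeros occur, as with road density); all non-binary columns
  are centered and scaled to unit sd. A Spearman/VIF screen (thresholds
  |r| < 0.62, VIF < 3.1) is advisory: violations are reported, nothing is
  dropped. The binary plot indicator is excluded from the rank screen.
* `psiD_ij` — the occurrence probability of free-ranging dogs, fitted
  first from a covariate-free occurrence model (detection covariates
  retained) and entered into native-species models as a plug-in
  posterior-mean covariate. This two-stage scheme does not propagate dog
  uncertainty; that is a deliberate simplification.
* `U_i` — intrinsic Gaussian CAR field on the Voronoi neighbor graph of
  the stations. Two stations are neighbors iff their Voronoi cells,
  clipped to the convex hull buffered by the mean nearest-neighbor
  distance, share a boundary segment of positive length (a shared point
  does not count; exactly collinear stations fall back to the chain
  graph). The CAR density is the pairwise-difference form
  −(τ/2) Σ (U_a − U_b)², invariant to level shifts, so the sampler
  recenters `U` each sweep and folds the mean into the intercepts.
* `d_i = (d_i1, d_i2)` — a site-level bivariate normal diel random effect
  with free sds and correlation ρ. ρ is the day/night occurrence
  coupling: a species whose good sites by day are also its good sites by
  night has ρ near 1.
* `S_i` — unstructured detection site effect.
* Optionally, a site-level bivariate residual `e_i = (e_psi, e_p)` with
  free 2×2 covariance couples the occurrence and detection logits. It is
  **off by default**: with `S_i` already present the extra detection-side
  residual is redundant unless the ψ–p correlation itself is the
  estimand. All four random-effect structures are independently
  togglable.

Overall (24-hour) occurrence is the union of the two periods,
`psi_i = 1 − (1 − psi_i1)(1 − psi_i2)`. Reported overall occupancy is the
posterior average of the site-level union, which is not the same number
as the union of the two posterior-mean occupancies.

The latent `z` is marginalized analytically; the exported likelihood per
site and period is
`psi C(k,y) p^y (1−p)^{k−y} + 1{y=0} (1 − psi)`. Linear predictors are
clamped at |35| before the inverse logit, so probabilities stay strictly
inside (0, 1) in floating point.

## Priors

Intercepts and slopes: Normal(0, 10²). CAR precision: Gamma(0.5, 0.0005)
with the τ^{rank/2} intrinsic normalizer (rank = N − number of graph
components). Correlations: Uniform(−1, 1). Random-effect sds:
Half-Normal(0, 1.5). The sd scale is deliberately tighter than the
coefficient prior: with a single presence pair per site the diel-field
scale is identified mostly through its prior (see *Identifiability*
below), and logit-scale site heterogeneity much beyond sd 1.5 saturates
the probabilities it generates. Every scale is configurable through
`PriorSettings`.

## Model selection

Each occurrence-side fixed effect (nine landscape/habitat covariates plus
the dog term, per period — 20 indicators, a 2^20 model space with the
full roster) carries a Bernoulli(0.5) inclusion indicator `w_c`.
Detection-side indicators are available behind a flag. Posterior model
probabilities are the relative frequencies of indicator combinations
among retained draws; models above 0.05 are reported as supported; ties
are broken by fewer included effects, then lexicographically.
Model-averaged coefficients are summarized conditional on inclusion
(draws with `w_c = 1`); an effect never included is reported as "−".
Unconditional averaging (zeros included) is available behind a flag.
Intervals are central 95% percentile intervals, with a flag marking
intervals that exclude zero.

While an effect is excluded its coefficient is refreshed from a
*pseudo-prior*, Normal(0, 1.5) by default, and the indicator-flip
acceptance ratio carries the prior/pseudo-prior correction. The
pseudo-prior affects only mixing, never the stationary model posterior;
with the sd-10 coefficient prior itself as pseudo-prior, flips toward
inclusion essentially never accept.

## Sampler

Metropolis-within-Gibbs, chosen to keep the indicator space explorable
without a probabilistic-programming dependency:

* scalar adaptive random-walk updates on intercepts, slopes and variance
  components (scales adapt toward ~0.35 acceptance every 50 sweeps;
  adaptation ends at burn-in);
* vectorized simultaneous single-site updates on `d`, `S` and `e`
  (exact, because sites are conditionally independent);
* the CAR field updated by graph-coloring classes, so simultaneous
  single-site moves never touch two neighbors; the CAR precision has a
  conjugate Gibbs draw; the field is recentered with the mean folded into
  the intercepts (a Metropolis move whose only non-unit factor is the
  intercept prior);
* interweaved non-centered moves on every random-effect scale and
  correlation: the field is rescaled (or re-correlated, keeping the
  whitened field fixed) together with the proposed hyperparameter, the
  Gaussian density ratio cancelling against the transform Jacobian. The
  centered conditionals alone mix through a funnel (observed split-chain
  PSRF ≈ 1.5 on ρ at 5,000 sweeps; ≈ 1.1 with interweaving at the same
  length);
* one flip proposal per indicator per sweep.

Runs are reproducible: chains draw from `SeedSequence(seed).spawn`, and
identical inputs and seed give bit-identical retained draws. The
reference protocol is 5 chains × 40,000 iterations, 10,000 burn-in,
thinned by 5; the test suite and the acceptance script use shorter chains
(stated per experiment below) sized so that Monte-Carlo error is small
relative to the tolerance being checked. Convergence is summarized by the
split-chain Potential Scale Reduction factor with a 1.1 flag threshold.

## Synthetic surveys

The generator mirrors the survey design the model assumes:

* ~210 stations by hard-core inhibition sampling at ≥500 m spacing;
* per-site effort Normal(37, 12²) days, truncated at 7;
* covariates from smoothed Gaussian random fields with shared latent
  axes ("forest", "terrain", "human footprint"); loadings are set so the
  generated tables pass the |r| < 0.62 / VIF < 3.1 screen in ≥95% of
  seeds, while keeping realistic within-family correlation (~0.3 between
  the 250 m and 500 m versions of a covariate);
* an eight-species guild, dog first, with day/night occupancy intercepts
  placed at realistic per-species levels; species with nonzero dog
  coefficients receive the dog's realized occurrence field;
* detections drawn exactly from the hierarchical model; photo timestamps
  placed uniformly inside the generating diel window of the trap day
  (the model ignores finer timing).

What the generator does **not** emulate: animal movement and home-range
structure (detections are independent across occasions given presence),
lure decay, camera failure, species misidentification, raster landcover
geometry. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
robustness to their violation in field data.

## Identifiability of the diel correlation

With a single season, each site contributes one Bernoulli presence pair,
so the observable day/night association is the *tetrachoric* correlation
of the latent pair including the logistic noise:
r\* = ρ σ² / (σ² + π²/3). At σ_d = 1 this is ≈ 0.14 for ρ = 0.6 — nearly
flat likelihood in ρ — and the field scale itself is constrained only by
its prior. The diel-correlation recovery experiment therefore generates
σ_d = 2.0 (occupancies spanning ~0.02–0.98 across sites), the weakest
field strength at which the posterior can resolve ρ to the precision the
experiment checks (±0.15 at 300 sites). Users should treat reported ρ
from weakly heterogeneous surveys as prior-dominated.

## Numerical choices and degenerate inputs

* Probabilities clipped away from 0/1 before logs; binomial coefficients
  cached once per dataset (they do not affect sampling).
* Constant covariate columns, nonpositive values under an unshifted log,
  duplicate station coordinates, fewer than three stations, `y > k`,
  ρ outside (−1, 1), and nonpositive precisions/sds are rejected with
  named errors rather than silently handled.
* Exact collinearity yields an infinite VIF with the culprit named; an
  infinite VIF threshold disables that check.
* Initialization retries up to 10 draws for a finite likelihood, then
  fails.

## Problem sizes used by the shipped experiments

Flat ψ/p recovery: 200 sites × 30 occasions, 2 chains × 8,000.
Grid-quadrature comparison: 12 sites, 2 chains × 6,000 against an
81³-point trapezoid grid. Model-probability comparison: 20 sites,
2 chains × 8,000 against 41-point-per-dimension per-model quadrature
(day/night blocks factorize, making the day block an exact 4-model
comparison). Diel-correlation recovery: 300 sites, 2 chains × 12,000.
Selection power: ten replicates, 2 chains × 1,500 each. Guild round trip:
210 sites, eight species, detection intercept at logit⁻¹(6) ≈ 0.998.

## Known limitations

Single-season model only; no species-interaction likelihood beyond the
plug-in dog covariate; dog uncertainty not propagated; proper-CAR (with
estimated spatial dependence) not implemented; reversible-jump and
information-criterion model comparison out of scope. The indicator-flip
sampler mixes slowly if the pseudo-prior is far from the conditional
posterior of an included coefficient; the pseudo-prior scale is
configurable for such cases.
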