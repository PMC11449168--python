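# Methods

`crocsoc` reimplements, as a tested pipeline over synthetic data, an
analysis of spatial–social behavioural variation in acoustically tagged
estuarine crocodiles (*Crocodylus porosus*): monthly behavioural metrics
derived from fixed-receiver detections, a trivariate double-hierarchical
Gaussian model (DHGLM) partitioning among- and within-individual variance,
and the personality/predictability statistics derived from its posterior.
The field data themselves are deposited elsewhere and are not required:
every stage is validated against generators with known truth.

## Behavioural metrics

**Centres of activity (COA).** Raw detections are binned into half-open
windows of configurable length (default 60 min; the method leaves the bin
user-defined, and an hour is the common choice for receiver arrays with
~100 s ping intervals). The COA of a bin is the detection-count weighted
mean chainage of the receivers involved. Because the study river is a
single channel, least-cost in-river distance equals the absolute chainage
difference, and all spatial work is one-dimensional (km of chainage from
the downstream origin). Planar positions are projected to chainage via the
nearest point on the centreline; ties resolve to the lower chainage.

**Activity** is the mean daily river distance (km/d): successive COA
distances are assigned to the calendar day of the earlier COA, summed per
day, and averaged over the days of each month that carry at least one
segment. A month with fewer than two contributing COAs yields a missing
value, never zero — summing sparse days to zero would bias activity
downward.

**Monthly utilization distributions** are Gaussian kernel densities over
chainage (default bandwidth 1 km, grid step 0.5 km — the source method
does not state its smoothing parameter), truncated to the river extent
and renormalized to unit mass. A minimum of five *unique* COA positions is
required per month; with fewer, the home range is absent. (Whether the
original minimum counted unique positions or unique receivers is
ambiguous; unique positions is the stricter reading and the one
implemented.) The 95% home range is the smallest set of grid bins reaching
0.95 of the mass (descending-density threshold); its size is reported in
km of channel, with a nominal channel width (default 0.1 km) available to
convert to km² for the associates model.

**Site fidelity** is the volume of intersection (VI = Σ min of the two
densities ∈ [0, 1]) between consecutive monthly home ranges, assigned to
the later month of each pair; calendar gaps produce no value.

**Sociability.** The monthly social environment of a focal individual is
the set of tagged conspecifics detected, in the same calendar month, at
any receiver the focal also visited that month (monthly, receiver-set
based — co-presence at the shared receiver need not be contemporaneous).
Associations are co-occurrences at the same receiver within a 4-minute
window; the default semantics are a sliding pairwise |Δt| ≤ 240 s, which
avoids bin-boundary artefacts, with a fixed-bin mode available for
comparison with the source method. Sociability is observed / potential
associates; with an empty environment the ratio is undefined and the value
is missing, not zero. Calendar months are evaluated in the study timezone
(configurable, default UTC+10).

## The model

For behaviour k ∈ {sociability, activity, site fidelity} of individual i
in month t (year y):

    y_ikt ~ Normal(μ_ikt, σ_ikt)
    μ_ikt       = x_it' β_k + a_ik + u_yk            (mean model)
    log σ_ikt   = x_it' γ_k + b_ik + v_yk            (dispersion model)

with a shared design x (intercept, month factor with January reference,
standardized total length, standardized log monthly detection count). The
six individual intercepts are jointly multivariate normal,
(a_i1..a_i3, b_i1..b_i3) ~ MVN(0, Σ_ID), with Σ_ID parameterized as six
SDs (sd_ID,k for the mean side, ω_k for the dispersion side) and a full
15-correlation matrix; year intercepts likewise under Σ_year. Sociability
and activity are cube-root transformed before standardization (both are
right-skewed); all responses are standardized to mean 0, SD 1, and the
transform parameters are retained to express results in original units.
Missing cells are handled by per-cell masks in one joint model — the
likelihood contributions are identical to fitting each behaviour on its
own available subset, and one model keeps the correlation structure in a
single place. Individuals with fewer than a configurable minimum of
observed months (default 2) are excluded; the sensitivity analysis varies
exactly this threshold.

Priors (all configurable): Normal(0, 5) on fixed effects, half-Normal(0, 1)
on all SDs, LKJ(η = 1) — uniform over valid correlation matrices. Sex is
excluded from the default model.

## Sampling

No general-purpose Bayesian engine is used; the sampler in
`crocsoc.dhglm.sampler` is written for this model's conditional structure:

* mean-model fixed effects and the mean random intercepts have exact
  Gaussian full conditionals given the cell SDs (conjugate Gibbs, batched
  3×3 linear algebra across individuals/years);
* dispersion fixed effects, year dispersion intercepts, SDs (on the log
  scale) and individual correlation entries use univariate stepping-out
  slice sampling, which needs no tuning and treats a non-PSD correlation
  proposal as simply falling outside the slice; the multivariate-normal
  quadratic form is carried through a precomputed 6×6 scatter matrix, so
  these updates cost O(1) in the number of individuals;
* individual dispersion intercepts are updated by a vectorized
  random-walk Metropolis step per individual, with per-individual scales
  adapted during warm-up only;
* extra Gibbs moves resample the exact Gaussian conditional along the
  translation directions that confound a fixed effect with its
  random-effect block (the intercepts at both levels, and the total-length
  slope with the individual intercepts, total length being constant within
  individual). Without these moves the intercepts random-walk badly,
  because the year block has very few levels.

Random effects are sampled centred rather than non-centred: the conjugate
updates are exact on the centred scale, and at the panel sizes used the
data dominate the hierarchy, so the small-SD funnel that motivates
non-centring does not bind.

Default chain settings mirror the study protocol — 4 chains × 8000
iterations, 6000 warm-up, thinning 2 — which retains 1000 draws per chain
(4000 total; the retained count is always reported). The convergence
contract is split-R̂ < 1.01 and bulk ESS > 1000 (via arviz) for every
fixed effect, SD and correlation; a run that misses it returns with
`converged=False` and a warning, leaving the decision to the caller.
Everything is reproducible from one integer seed.

## Derived statistics

All derived quantities are computed per posterior draw and then
summarized by the mean and 95% highest-posterior-density interval (the
narrowest interval with 95% mass); plug-in variants on point estimates
exist because the published worked examples are plug-in computations on a
printed table.

* **Repeatability** R_k = sd²_ID,k / (sd²_ID,k + sd²_year,k + (exp γ0_k)²).
  The residual variance uses only the dispersion intercept (exponentiated,
  then squared), not the month/covariate dispersion effects.
* **Coefficient of predictability** CV_p,k = √(exp(ω_k²) − 1), the CV of a
  lognormal with log-scale SD ω_k. The source presentation of this formula
  omits the square root relative to the lognormal-CV form and prints the
  row label as ω²; the values only reproduce with the square root and ω
  read as an SD, which is what this package implements. Under that reading
  the site-fidelity value (ω = 0.26) evaluates to 0.264 and rounds to
  0.26, one unit below the published 0.27 — a rounding artefact of 2-dp
  inputs, left as is.
* **Realized phenotypes**: β0_k + a_ik destandardized and, for cube-root
  responses, cubed back to original units. **Realized rIIV**:
  exp(γ0_k + b_ik) rescaled by the response's standardization SD; for
  cube-root responses the original-unit value is flagged approximate,
  because a power transform maps means, not SDs.
* **Correlations**: the mean–rIIV correlation r(a_k, b_k) per behaviour
  and the syndrome r(a_k, a_k′) per pair are read off Σ_ID's posterior,
  flagged significant when the 95% HPD excludes 0.
* **Associates model**: a Bayesian Poisson GLMM (log link) for monthly
  potential/observed associate counts with standardized home-range size,
  association type, their interaction, and individual and year random
  intercepts, fitted by the same slice-within-Gibbs machinery.

## Synthetic data

The **panel generator** draws directly from the generative model above
with configurable truth. Its defaults are the monitored population's
conditions: 118 individuals over 120 months; fixed effects, SDs, the
three mean–rIIV correlations and the three syndromes set to the field
study's published point estimates; unpublished cross-correlations set to
0; year-level correlations 0 (the resulting 6×6 matrix is verified
positive-definite). Per-behaviour missingness (0, 0.001, 0.486) matches
the field study's per-behaviour subset sizes, treated as
missing-completely-at-random per behaviour. Covariates are generated
standardized so the panel is directly model-ready.

The **telemetry simulator** is mechanistic: a 100 km straight channel,
receivers every 2–5 km (default 3 km), ping intervals uniform on 90–120 s,
and a hard 400 m detection radius (no detection-probability decay with
distance is described for the array; a hook for a range curve is the
obvious extension). Movement is a discrete-time mean-reverting Gaussian
step process on chainage — x_{j+1} = c + φ(x_j − c) + ε — whose attraction
φ spans resident (small φ) to nomadic (φ near 1) phenotypes; defaults
(φ = 0.995, step SD 0.2 km per ping) give a stationary range SD of ~2 km
so individuals span several receivers. Timestamps are logged to whole
seconds, as receivers do.

What the simulator does *not* emulate: tides, temperature tags, tag loss,
receiver outages, detection-range decay, or behaviour calibrated to the
field population's metric values (the simulated animals are more mobile
and more gregarious than wild crocodiles). Passing metric and recovery
tests therefore demonstrates correctness of the computations under the
stated generative assumptions, not realism of any particular metric value.

## Verification and problem sizes

* The joint log posterior is checked to 1e-8 against an independent
  brute-force evaluation (explicit loops, scipy distributions, naive MVN
  via determinant/solve) on 5-individual toys.
* Correlation recovery uses 100 individuals × 36 months with generating
  r(a_soc, b_soc) = −0.6 and r(a_soc, a_act) = −0.35: posterior signs and
  95% HPDs excluding zero.
* Calibration uses 20 seeded replicates at 30 individuals × 24 months,
  pooling HPD coverage of all generating fixed effects and
  among-individual SDs; pooled coverage is required to stay within
  binomial noise of the nominal 95% (≥ 0.90 allowing for within-replicate
  correlation and Monte Carlo error of short chains).
* Test and example fits run shortened chains (1–2 chains, 500–3000
  iterations); these are runtime choices for the bundled experiments, and
  the convergence contract above is what a production fit should meet.

## Known limitations

* The 1D river-constrained kernel replaces the original 2D least-cost
  utilization distribution; for an effectively linear river the two agree
  up to the channel-width factor, but braided or branching systems are out
  of scope.
* The year level often has few levels (3 in the bundled experiments), so
  its SDs are prior-sensitive; this mirrors the inferential reality of
  any study with few years.
* Original-unit rIIVs for cube-root transformed responses are
  approximate (standardization SD only).
* The slice/Metropolis sampler mixes more slowly than gradient-based
  samplers on the dispersion month effects of sparsely observed responses;
  the ESS contract, not iteration count, is the quality gate.
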