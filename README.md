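# crocsoc

Spatial–social behavioural variation from river acoustic telemetry.

Passive acoustic telemetry — coded tags detected by a fixed array of
underwater receivers — is the standard way to follow large aquatic
animals such as estuarine crocodiles (*Crocodylus porosus*) over years.
This package turns raw detection tables from a single-channel river into
monthly behavioural metrics, fits a multivariate double-hierarchical
Gaussian model (DHGLM) to them, and derives the individual-level
statistics used in animal-personality research. It is aimed at movement
ecologists who want the full chain — detections → behaviours → variance
partitioning → personality/predictability statistics — as inspectable,
tested Python, with a synthetic-data generator standing in for field data
so every stage can be verified by parameter recovery.

## The metrics

Per individual and calendar month (study timezone, default UTC+10):

* **sociability** — observed associates (co-occurrence at the same
  receiver within a 4-min window) over potential associates (tagged
  conspecifics sharing any receiver the focal visited that month);
* **activity** — mean daily river distance (km/d) between successive
  centres of activity (detection-weighted positions in hourly bins),
  measured along the channel (chainage);
* **site fidelity** — volume-of-intersection overlap between consecutive
  monthly 95% kernel home ranges on the 1-D channel (0 = disjoint,
  1 = identical).

## The model

For behaviour *k*, individual *i*, month *t* in year *y*:

    y_ikt ~ Normal(mu_ikt, sigma_ikt)
    mu_ikt        = x_it' beta_k + a_ik + u_yk      (mean model)
    log sigma_ikt = x_it' gamma_k + b_ik + v_yk     (dispersion model)

with month, standardized total length and standardized log detection
count as covariates, and a full 6×6 among-individual covariance between
the three mean intercepts a and the three dispersion intercepts b
(crossed with an analogous year-level structure). From the posterior the
package derives, per behaviour:

* repeatability `R = sd_ID^2 / (sd_ID^2 + sd_year^2 + exp(gamma0)^2)`,
* coefficient of predictability `CV_p = sqrt(exp(omega^2) - 1)` where
  omega is the among-individual SD of dispersion intercepts,
* realized phenotypes and realized rIIVs (residual intra-individual
  variation) per individual in original units,
* mean–rIIV correlations and cross-behaviour syndromes with 95% HPD
  intervals,

plus a Poisson GLMM relating monthly associate counts to home-range size.
The sampler is a model-specific blocked Gibbs/slice scheme (see
`docs/methods.md`) with split-R̂/ESS diagnostics via arviz; everything is
reproducible from one integer seed.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (`python analysis/01_simulate.py`, then `02`…`05`). Script 01 draws
a 118-individual × 120-month behavioural panel from the generative model
(truth saved alongside) and a mechanistic telemetry simulation; 02
computes the metric tables; 03 fits the DHGLM to a 60-individual,
48-month slice and prints recovery against the known truth:

```
fitting 2880 rows, 60 individuals, 4 years
among-individual SDs, posterior mean vs truth:
  a_soc  0.276 vs 0.27
  a_act  0.507 vs 0.58
  a_fid  0.521 vs 0.49
  b_soc  0.296 vs 0.29
  b_act  0.307 vs 0.31
  b_fid  0.248 vs 0.26
mean-rIIV corr (sociability): -0.49 vs -0.56
syndrome corr (soc~act):      -0.41 vs -0.33
retained draws: 1500; converged contract: False
```

(the short bundled chains trade ESS for runtime — the `converged` flag
reports the strict R̂ < 1.01 / ESS > 1000 contract, and this run stops at
R̂ = 1.05). Script 04 prints the derived statistics:

```
sociability    R = 0.11 (0.06 to 0.16)  CV_p = 0.30 (0.24 to 0.37)
activity       R = 0.22 (0.09 to 0.34)  CV_p = 0.31 (0.25 to 0.38)
site_fidelity  R = 0.29 (0.16 to 0.42)  CV_p = 0.25 (0.19 to 0.32)
mean_riiv  sociability                  r = -0.49 (-0.69 to -0.24)*
mean_riiv  activity                     r = -0.04 (-0.29 to +0.21)
mean_riiv  site_fidelity                r = -0.67 (-0.85 to -0.44)*
syndrome   sociability~activity         r = -0.41 (-0.64 to -0.20)*
```

— a repeatability of 0.22 means 22% of the variance in (transformed)
daily activity is among-individual; a CV_p of 0.31 means individuals'
residual SDs themselves spread ~31% around the population mean rIIV; the
starred negative mean–rIIV correlations say that more sociable and more
site-attached individuals are also the more *consistent* ones. Script 05
refits under minimum-months thresholds {2, 6, 12} on staggered monitoring
spans and reports the largest shift in any fixed-effect posterior mean
(0.051 SD units at study scale — the inclusion threshold is immaterial).

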