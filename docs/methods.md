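# Methods

## Study setting and data model

The package targets single-day diurnal cortisol designs: each participant
provides a first-morning urine void and one or two later samples at least
4 h apart, plus a short stressor questionnaire administered once through a
translator. Analyses run on three tables (samples, participants,
questionnaire) in plain CSV; the access-restricted field data are replaced
by a synthetic generator with the same schemas.

### Specific-gravity correction

Urinary analyte concentration depends on hydration. Each raw cortisol
value (pg/mL) is rescaled by `(SG_target − 1)/(SG_sample − 1)`, where
`SG_target` is the population mean specific gravity. `SG_target` is
computed over the analysis set *after* the pregnancy and missing-age
exclusions but *before* the questionnaire-completeness exclusion that only
affects the joint model; the value used is recorded in the outputs. A
config override (`sg_target`) is available when a canonical population
value exists.

### Sunrise anchoring

Exact waking and first-void times are unreliable in the field, so
first-morning samples are anchored at relative time 0 and later samples
are expressed as hours since local sunrise, computed from the NOAA
solar-position equations (Julian century → solar declination and equation
of time → hour angle at zenith 90.833°). Community coordinates and a fixed
UTC offset (−4 h, no DST for lowland Bolivia) come from configuration.
Agreement with an independently coded solar routine is within ±5 minutes
throughout the tropics, far below the hour-scale uncertainty of true
waking times; the sunrise proxy itself (not recovering individual waking
times) is a stated design limit of this class of study.

### Exclusions

Pregnancy removes a participant (cortisol is strongly elevated in
pregnancy); missing age removes a participant from both models; an
incomplete questionnaire removes a participant from the joint model only.
Every removal is logged with participant id, stage, and reason, and the
filter is idempotent.

### Questionnaire scoring

Six analysis variables: self-rated health (1–3), food insecurity (sum of
two 1–5 items, range 2–10), social conflicts (sum of two 1–5 items),
hunger (1–5), rumination (1–5), debt (binary). The community-conflict item
is not scored: its responses are near-constant and a cumulative-logit
model cannot identify cutpoints for it. Because composite sums leave
unobserved categories, observed values are recoded to contiguous 1..K
indices before fitting and the mapping is persisted for reporting.

## Models

### Model 0 — censored-lognormal multilevel cortisol model

log-cortisol is normal with mean
`μ0 + β_t·t + β_a·age_z + β_g·woman + β_c·community + β_ta·t·age_z +
β_tg·t·woman + β_ag·age_z·woman + β_tag·t·age_z·woman + u_i + v_i·t`
and scale σ. Age is z-scored over the analysis set of the model being fit.
Reference categories are man and community 1. Assay values at/above the
highest standard are right-censored: they contribute the lognormal
upper-tail probability instead of the density, so over-range mornings
inform the fit without pretending precision. Individual intercepts and
slopes (u_i, v_i) are bivariate normal with SDs (sd_int, sd_slope) and
correlation ρ.

### Model 1 — joint multivariate model

The cortisol submodel is retained in full. Each ordinal item k follows a
cumulative logit with ordered cutpoints κ and linear predictor
`β_a·age_z + β_g·woman + β_c·community + translator_j + ε_i`; the binary
debt item is Bernoulli-logit with the same structure plus a global
intercept (the likelihood would otherwise pin P(debt) to 0.5 at the
covariate reference; the intercept carries the N(0, 2) coefficient prior).
Translator random intercepts absorb interviewer effects on reported
stress; they enter item submodels only, not the cortisol model. The
per-individual latent vector `(ε per item, v_i, u_i)` is multivariate
normal with covariance `diag(s) Ρ diag(s)`, one joint correlation matrix
over all items and both cortisol latents. The item↔intercept and
item↔slope entries of Ρ are the residual correlations of interest:
associations between relative stress and the diurnal profile after
adjusting both sides for age, gender, community, and translator.

### Priors

μ0 ~ Normal(0, 100) (deliberately flat on the log scale);
all other coefficients ~ Normal(0, 2); every SD (residual, individual,
translator, item latent) ~ Exponential(2); Ρ ~ LKJcorr(2). Cutpoints get
independent Normal(0, 10) priors with ordering enforced by a
first-value-plus-log-gaps transform — a prior the reporting conventions of
this analysis family leave unstated, chosen wide enough to be
noninfluential for 2–10 category items while keeping extreme cutpoints
numerically tame.

## Computation

No probabilistic-programming backend is assumed. The models compile onto a
flat unconstrained vector: log transforms for SDs, the gap transform for
cutpoints, non-centered scaling for all random effects, and canonical
partial correlations (CPCs) for Ρ. The LKJ(η) distribution factorizes
exactly over the C-vine CPCs as independent shifted Betas, so the prior is
placed there (plus the tanh Jacobian) and Ρ is reconstructed from its
Cholesky factor for reporting; a property test confirms the construction
reproduces the known LKJ marginal `2·Beta(η−1+d/2, ·)−1`.

Gradients come from a small reverse-mode autodiff over numpy arrays
(`cortrhythm.autodiff`) with fused primitives for the three heavy terms
(censored-lognormal likelihood, cumulative-logit likelihood, CPC→Cholesky
recursion), each with a hand-derived reverse pass verified against central
finite differences at 1e−5 relative tolerance.

Sampling is dynamic Hamiltonian Monte Carlo in the NUTS family:
multinomial sampling over a doubling trajectory, no-U-turn stopping,
divergence flagging at ΔH > 1000, dual-averaging step-size adaptation, and
windowed diagonal mass-matrix estimation. Chains are seeded from a single
`SeedSequence`, making every fit bit-reproducible from (data, config,
seed). Split R-hat and effective sample size are computed with ArviZ;
convergence problems attach warnings to the result instead of aborting.
Defaults are 4 chains × 1000 warmup + 1000 kept at target acceptance
0.95; the test suite and acceptance script use 0.90 with 400–600 warmup
draws, which on these posteriors keeps divergences at zero while roughly
halving tree depth. The joint model's item-latent scale parameters are the
slowest-mixing quantities (a single ordinal observation informs each
latent), so their effective sample sizes are the ones to watch in the
diagnostics table.

### Posterior summaries

Medians and 89% equal-tailed intervals throughout; directional
probabilities are the fractions of draws strictly above/below zero (exact
zeros, a measure-zero event, count in neither). The ICC with random slopes
uses the variance partition
`V = sd_int² + sd_slope²·E[t²] + 2ρ·sd_int·sd_slope·E[t] + σ²`
evaluated at the observed relative-time moments, with
`ICC_int = sd_int²/V` and `ICC_slope = sd_slope²·E[t²]/V`; the
intercept–slope covariance term is kept in the denominator only, so the
intercept, slope, residual, and covariance shares sum to one per draw.
This convention (one of several possible with random slopes) is recorded
in output metadata. Diurnal curves are posterior summaries of
`exp(μ(t))`, at population level (latents zero) or per individual (adding
that individual's latent draws).

## Synthetic data

The generator runs Model 1 forward. Defaults mirror the study design:
129 analyzable participants (57% women; communities of 37/53/39; ages
uniform 15–83; two translators), 2–3 samples per person (Pr[3] = 45/129,
matching 303 samples from 129 people), afternoon samples uniform on 4–10 h
after sunrise (the protocol's ≥4 h gap, bounded by daylight), cortisol
fixed effects at the published point estimates (μ0 = 12.66,
β_t = −0.03, …), σ = 0.4, intercept SD 0.5 vs slope SD 0.05 (the
order-of-magnitude dominance of intercept variance), intercept–slope
correlation 0.22, and item↔cortisol latent correlations at the reported
median values. Enrollment extras reproduce the exclusion load: 8 pregnant
(cortisol shifted +1 log unit), 3 missing age, 4 incomplete
questionnaires — 140 enrolled, 129 in Model 0, 125 in Model 1. Specific
gravity is uniform (1.005, 1.035) with raw values back-computed from the
generative corrected value, so the correction stage is exercised end to
end. Item fixed effects, cutpoints, and translator SDs have no published
values; the defaults produce realistic skewed category frequencies
(most mass at "never/rarely", debt prevalence ≈ 38%) and are free
configuration, not reported facts.

What the generator does **not** emulate: day-to-day within-individual
variation (the repeated-day subsample design), assay plate effects and
CVs, the cortisol awakening response, non-linear time trends, item
non-response mechanisms other than missing-at-random blanks, and any
market-integration covariate. Passing recovery tests therefore show the
estimator is consistent with its own generative assumptions at the study's
size — not that those assumptions hold in real field data.

## Test and acceptance problem sizes

The recovery surface uses one fit per condition with fixed seeds: Model 0
at the full study design (n = 129, 3 chains × 400/400), a Model 1
null-calibration fit (n = 200, all latent correlations zero,
2 chains × 400/250), a prior-only fit (4000 draws), and a reduced
simulation-based-calibration sweep (20 Model 0 fits at n = 30,
2 chains × 150/150, 89% interval coverage ≥ 14/20). These sizes are the
package's chosen trade-off between posterior precision and a suite that
runs on a single CPU; sharper checks simply scale the same code up.

## Known limitations

* With 2–3 samples per person on one day, individual slopes are barely
  identified; their latent correlations with stressors are
  prior-dominated (the LKJ(2) marginal has SD ≈ 0.3 at d = 8), and wide
  directional probabilities are the honest output.
* The joint model's latent-scale funnels mix slowly; effective sample
  sizes for `sd_latent_*` run an order of magnitude below those of fixed
  effects at equal draw counts.
* The censoring threshold (assay upper standard) is configuration, since
  no canonical value ships with the package.
* Sunrise is a proxy for waking; systematic individual offsets load onto
  individual intercepts by construction.
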