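# cortrhythm

Bayesian multilevel modelling of **diurnal urinary cortisol rhythms** and
their associations with **psychosocial stressors** (food insecurity, social
conflict, hunger, rumination, debt, self-rated health) in field studies of
small-scale subsistence populations.

Field endocrinology hands you awkward data: urine specimens of varying
dilution, first-morning voids with no reliable clock time, assay values
that saturate above the highest standard, Likert-scale stressor items
collected through translators, and only two or three samples per person on
a single day. `cortrhythm` implements the full analysis path for that
setting:

* **Preprocessing** — specific-gravity correction
  (`corCORT = rawCORT × (SG_target − 1)/(SG_sample − 1)`), sunrise-anchored
  relative time computed from NOAA solar-position equations (first-morning
  voids at *t* = 0, later samples as hours since sunrise), and logged
  exclusion rules (pregnancy, missing age, incomplete questionnaires).
* **Model 0 (cortisol)** — a censored-lognormal multilevel model

  ```
  CORT_ij ~ LogNormal(μ_ij, σ)
  μ_ij = μ0 + β_t·time + β_a·age_z + β_g·woman + β_c·community
         + interactions + u_i + v_i·time
  (u_i, v_i) ~ MVNormal(0, Σ(sd_int, sd_slope, ρ))
  ```

  with right-censoring handled through the lognormal upper-tail
  probability.
* **Model 1 (joint multivariate)** — the cortisol submodel plus one
  submodel per stressor item (cumulative ordinal logit with cutpoints κ,
  Bernoulli-logit for debt), each with translator random intercepts and an
  individual latent residual ε; all individual-level latents
  (ε per item, v_i, u_i) share a correlation matrix **Ρ** under an
  LKJ(2) prior. The entries of Ρ linking items to the cortisol intercept
  and slope are the *residual correlations* the analysis reports.
* **Inference** — a NUTS-style dynamic Hamiltonian Monte Carlo sampler
  running on the package's own reverse-mode autodiff
  (`cortrhythm.autodiff`), with priors μ0 ~ N(0, 100), β ~ N(0, 2),
  SDs ~ Exponential(2), Ρ ~ LKJcorr(2).
* **Summaries** — posterior medians with 89% equal-tailed intervals,
  directional probabilities (p_>0 / p_<0), intraclass correlations for
  random intercepts and slopes, descriptive tables, and diurnal-curve
  predictions in pg/mL.
* **Synthetic data** — a generator that runs the joint model forward at
  known parameters, mirroring the study design (129 analyzable
  participants, 57% women, three communities, ages 15–83, 2–3 samples per
  day, 140 enrolled including pregnancy/age/questionnaire exclusions), so
  the whole pipeline is testable by parameter recovery without the
  access-restricted field data.

## Worked example

```python
import warnings
import numpy as np
from cortrhythm import (SamplerConfig, default_study_config, default_truth,
                        fit_model, generate_dataset, hourly_percent_change,
                        prepare_model_data)

study = default_study_config()
truth = default_truth(seed=3, n_participants=60, n_pregnant=0,
                      n_missing_age=0, n_incomplete_questionnaire=0)
samples, participants, questionnaire, _ = generate_dataset(truth, study)
data, _ = prepare_model_data(samples, participants, questionnaire,
                             study, "model0")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    draws = fit_model("model0", data, cfg=SamplerConfig(
        chains=2, warmup_draws=300, kept_draws=300, seed=10,
        target_accept=0.9))
b = draws.stacked("beta_time")
print(f"time slope: {np.median(b):+.3f} "
      f"[{np.quantile(b, 0.055):+.3f}, {np.quantile(b, 0.945):+.3f}]")
print(f"decline: {hourly_percent_change(float(np.median(b))):.1f}% per hour")
```

prints (the same fit as `examples/03_fit_cortisol_model.py`):

```
time slope: -0.038 [-0.066, -0.009]
decline: 3.8% per hour
```

i.e. the posterior for the population diurnal slope concentrates near the
generative value of −0.03 log-units per hour — a 3–4% hourly decline from
the waking level — with an 89% credible interval excluding zero. The
`examples/` directory holds one short script per capability
(preprocessing, sunrise/SG primitives, Model 0, the joint stressor model,
and the recovery harness); each prints what it computes and what the
numbers mean.

A thin CLI mirrors the pipeline stages
(`cortrhythm simulate|preprocess|fit|summarize|recover|run-all --config
run.yaml --seed 7 --out results/`); configurations are YAML/JSON and every
run writes a manifest (config hash, seed, versions) so reruns are
byte-identical.

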