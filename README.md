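# gazezib

Hierarchical Bayesian analysis of where people look on faces and how that
relates to who they are.

When observers rate facial impressions (the five Big Five items) while an
eye tracker records their gaze, each trial leaves a *dwell weight*
G<sub>n</sub> ∈ [0, 1) on each of six facial regions — eyes, nose, mouth,
eyebrows, glabella, forehead.  Many region/trial combinations receive no
gaze at all, so G<sub>n</sub> is zero-inflated.  `gazezib` implements the
full analysis pipeline for such experiments, including the contrast between
**free viewing** and **aperture-restricted viewing** (only a small disc
around the mouse cursor is visible, isolating deliberate, conscious gaze).

## The model

Per (condition × impression item × region), dwell follows a zero-inflated
Beta (ZIB) distribution:

```
G ~ ZIB(q, a, b):   P(G = 0) = 1 − q ;   G | G > 0 ~ Beta(a, b)

q  = logistic( α_bern + Σ_k β_bern_k P_k + r_subj + r_pic )
μ  = logistic( α_Beta + Σ_k β_Beta_k P_k + r_subj + r_pic )
a = φ μ ,   b = φ (1 − μ)
```

* `q` — probability of looking at the region at all (Bernoulli part),
* `μ`, `φ` — mean and precision of the positive dwell (Beta part),
* `P_1..P_5` — the viewer's Big Five scores on the raw 1–7 scale,
* `r_subj`, `r_pic` — crossed random intercepts for participant and image.

Priors: fixed effects Normal(0, 10); random-effect scales Gamma(10, 10);
precision φ Exponential(0.1).  Fitting is Hamiltonian Monte Carlo with
analytic gradients (non-centered random effects, dual-averaging step size,
diagonal mass adaptation); the default configuration — 4 chains, 2000
iterations, 1000 warmup, thin 1 — retains 4000 draws.  A fit counts as
converged when it used ≥ 3 chains and every parameter's split-R̂ < 1.1, and
a trait coefficient is *credible* when its 95% highest-density interval
(HDI) excludes 0.

The package also contains

* a **synthetic-experiment generator** (42 participants, 50 trials per
  condition, 3 s of 120 Hz gaze on a 412×558 stimulus centered in a
  1920×1080 screen) with recorded ground truth, at weight-level or
  gaze-level fidelity;
* the **preprocessing** chain from raw gaze samples to dwell weights
  (coordinate shift, Gaussian density SD 10 px, per-region area division,
  per-trial normalisation);
* **diagnostics** (split-R̂, sliding-window HDI, significance tables);
* **trait sweeps**: model-based simulation sweeping one trait over 1–7
  (others fixed at 3) and draw-wise restricted − free difference curves.

## Worked example

`examples/03_fit_zib_model.py` generates a 12-participant single-scope
dataset from known parameters and fits it:

```
retained draws: 1200 (4 chains x 300)
max split-Rhat: 1.020  converged: True

Bernoulli-part trait coefficients (posterior mean [95% HDI] | truth):
  extraversion       +0.34 [-0.23, +0.90] | +0.18
  agreeableness      +0.22 [-0.41, +0.93] | -0.05
  conscientiousness  +0.52 [+0.01, +1.05] | +0.19
  neuroticism        -0.11 [-0.92, +0.71] | -0.34
  openness           -0.40 [-1.31, +0.46] | -0.34

significance table (1 credible coefficients):
    Model Impression Area         Predictor     Mean  HDI_low  HDI_high
Bernoulli   openness eyes conscientiousness 0.517173  0.00955  1.045681

Beta precision phi: 29.1 +/- 8.0 (truth 30.0)
```

Every planted coefficient lies inside its 95% HDI, and the Beta precision is
recovered.  The other examples cover the generator
(`01_synthetic_experiment.py`), gaze preprocessing and allocation recovery
(`02_preprocess_gaze.py`, Pearson r ≈ 0.98), and trait sweeps with
free-vs-restricted differences (`04_trait_sweep.py`).

A thin CLI wraps the same stages:

```
gazezib simulate --out ds --participants 6 --seed 1
gazezib preprocess ds --out weights.csv
gazezib fit weights.csv ds/personality.csv --out post --scope condition=free,impression=openness
gazezib report post --out report --sweep-trait conscientiousness
```

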