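# Methods

## Observation model

The unit of analysis is the dwell weight G ∈ [0, 1) a single trial leaves in
a single facial region.  G mixes a point mass at zero (the region was never
looked at) with a continuous Beta component:

    P(G = 0) = 1 − q,    G | G > 0 ~ Beta(φμ, φ(1 − μ)),

so the Beta part has mean μ and precision φ = a + b.  Both q and μ are
logistic in the viewer's five trait scores (raw 1–7 scale, uncentered in the
reported parameterisation) with crossed random intercepts for participant
and stimulus image.  One model is fitted independently per
(condition × impression item × region): the regional models share no
parameters, and reporting is per-region, so joint fitting would buy nothing
while coupling unrelated posteriors.

Priors: Normal(0, 10) on intercepts and trait coefficients; Gamma(10, 10)
on the four random-effect scales σ (a gamma prior cannot sit on the signed
effects themselves, so it attaches to their scales; effects are
Normal(0, σ)); Exponential(rate 0.1, mean 10) on φ — weakly informative on
the precision of area-normalised dwell weights, overridable.

Trait scores enter uncentered because the simulation convention (sweep one
trait, fix the others *at 3*) is defined on the raw scale.

## Sampler

Fitting is Hamiltonian Monte Carlo with analytically coded gradients — no
autodiff framework is used.  Numerical design:

* **Unconstrained space.** φ and the four σ are log-transformed (Jacobians
  included); random effects use the non-centered parameterisation r = σu,
  u ~ N(0, 1), which removes the funnel between scales and effects.
* **Internal centering.** Inside the sampler the trait design matrix is
  centered at the scale midpoint 4 and the intercept redefined accordingly
  (an exact linear change of variables; priors are still evaluated on the
  raw-scale intercept).  Without this, the intercept–coefficient posterior
  correlation under a diagonal mass matrix slows mixing severely at small n.
* **Adaptation.** Dual averaging tunes the step size toward 0.8 acceptance;
  a diagonal mass matrix is re-estimated from two warmup windows (at 50% and
  85% of warmup, only when warmup ≥ 200 so smoke-test runs stay trivial).
  Trajectory lengths are drawn uniformly from 1..32 leapfrog steps to avoid
  resonance.
* **Degenerate inputs.** Non-finite proposals are rejected (overflow is
  silenced, the Metropolis step handles it); an all-zero slice leaves the
  Beta part prior-dominated and logs a warning rather than failing.
* Draw accounting follows the usual convention: iterations include warmup,
  so the default 4 × (2000 − 1000)/1 = 4000 retained draws.

Chains are seeded by spawning one `SeedSequence` per chain from the
configuration seed; fits are bit-reproducible for a fixed seed.

## Preprocessing

Screen-coordinate samples are shifted by the centered-placement offset
((1920−412)/2, (1080−558)/2); off-image samples are **discarded**, not
clipped — clipping would pile spurious mass on border regions.  Pixel
coordinates are 0-based, origin top-left, with the half-open image rectangle
[0, W) × [0, H).

The per-trial histogram is smoothed with an isotropic Gaussian, SD 10 px,
truncated at 4 SD with a renormalised kernel (the standard numerically safe
choice), then divided by its total: a unit-mass density surface.  Each
region's mass is divided by its pixel area (per-pixel dwell weight), and the
six values are placed on a unified scale by per-trial normalisation to sum
≤ 1.  Two guards keep the ZIB support meaningful:

* values below 10⁻⁶ × max are zeroed first — smoothing spreads strictly
  positive mass everywhere within 4 SD, so without a floor a true "never
  looked" zero could not occur;
* a weight reaching 1 (single nonzero region) is clamped to 1 − 10⁻⁶.

Whether the original unified scale was per-trial, per-participant or global
is not recoverable from the reporting conventions this package mirrors; the
per-trial choice is a documented package decision that guarantees Beta
support and cross-trial comparability.

## Synthetic experiments

The generator reproduces the study design it emulates: 42 participants
(trait scores uniform on the integer 7-point grid by default), 10 images per
impression item × 5 items = 50 trials per condition, 3 s × 120 Hz = 360
samples per trial, 412×558 stimuli centered in a 1920×1080 screen, six
disjoint parametric facial regions with per-image jitter.  The restricted
condition's aperture is a 40 px hard disc with a 40 px Gaussian edge; the
wider variant scales both to 60 px (1.5×, matching the 2°→3° widening of
the visible field).

Ground-truth ZIB parameters default to trait coefficients drawn
N(0, 0.2) (Bernoulli part) and N(0, 0.1) (Beta part) per scope, with
intercepts chosen so the mid-scale profile gives q = 0.7 and μ = 0.12,
φ = 30, and all random-effect scales 0.5 — moderate, realistic effect and
clustering sizes for logit-scale gaze models.  μ is kept small because the
six region weights are drawn independently from the regional ZIB models
(exactly the independence the fitted model assumes); a trial's six weights
may therefore rarely sum above 1, which the preprocessing-derived table can
never do.  Parameter-recovery studies use the weight-level fidelity, where
this is immaterial.

Gaze-level synthesis allocates the 360-sample budget across regions in
proportion to the trial's weights; dwell samples sit at uniformly drawn
region pixels with isotropic 10 px jitter, rejection-sampled to stay inside
the region (an escaped sample would silently reallocate dwell).  In the
restricted condition the same allocation is ordered as a cursor tour from
the canvas center; transit legs are fast (≤ 4 samples) and the remaining
non-dwell budget rests on background pixels.  The generator does not model
saccade kinematics, fixation events, tracker noise beyond the isotropic
jitter, or photorealistic faces — so pipeline tests demonstrate that the
preprocessing recovers planted dwell structure, not that it is robust to
real tracker artefacts.

Because preprocessing divides by region area and renormalises per trial,
the pipeline-recovery correlation is measured against the area-corrected,
trial-normalised transform of the planted allocation (a deterministic
function of truth); the gaze-level fixture achieves Pearson r ≈ 0.98.

## Diagnostics and reporting

Split-R̂ halves each chain and returns √(V̂/W) (rank-free variant; an
all-constant input returns 1 by convention).  Convergence requires ≥ 3
chains and max R̂ < 1.1, applied per fit.  The HDI is the shortest window of
⌈0.95 n⌉ sorted draws, ties broken toward the lowest start — deterministic
given draws and verifiable by exhaustive search, unlike kernel-density
intervals.  The significance table lists a trait coefficient iff its HDI
excludes 0; non-converged fits are excluded with a loud log message rather
than raising, mirroring reporting practice.

Trait sweeps evaluate q and μ per posterior draw on the 7-point grid with
non-swept traits at 3 and random effects at 0 (the population mode under the
symmetric effect prior); summaries are always computed draw-wise —
mean/HDI of the transformed draws, never the transform of the summary.  μ is
reported as the "dwell frequency" curve, with q·μ (the unconditional
expected dwell) available as an option.  Condition differences are formed
per draw (draws paired by index) before summarising.

## Problem sizes and verification

The test suite and acceptance script regenerate everything they measure.
Sizes were chosen as the smallest designs whose posteriors are still
well-identified: single-scope fits use 12 participants × 6 images (72
observations) with 2 × 600/300 chains for replicated studies, and 20 × 10
(200 observations) with the full default configuration for the convergence
check.  Across 20 seeded replicates the 95% HDIs cover planted coefficients
at the nominal rate within binomial tolerance, and with null truth the HDI
rule flags ≈ 5% of coefficients.  The brute-force posterior-density oracle,
quadrature normalisation of the ZIB density, exhaustive-window HDI oracle
and finite-difference gradient checks are all part of the suite.

## Known limitations

* Independent per-scope fits ignore cross-region dependence of a trial's
  weights; no joint or multi-region model is provided.
* No model comparison (WAIC/LOO), effective-sample-size reporting, or
  divergence diagnostics beyond split-R̂.
* The restricted-condition generator collapses eye and cursor into one
  trajectory and starts the cursor at the canvas center (the initialisation
  used in the emulated design is unreported).
* Real eye-tracking artefacts (blinks, calibration drift, saccade dynamics)
  are out of scope; conclusions from synthetic tests transfer to real data
  only to the extent those artefacts are handled upstream.
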