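"""Generate a synthetic gaze-personality experiment and inspect its design.

The generator emulates a two-condition face-viewing study: participants with
Big Five profiles view 10 face images per impression item (50 trials per
condition) while their dwell on six facial regions is produced by a known
zero-inflated Beta model, recorded as ground truth for later recovery checks.
"""

import gazezib as gz
from gazezib.design import ExperimentConfig

config = ExperimentConfig(n_participants=6)  # default: 10 images x 5 impressions
bundle = gz.generate_experiment(config, seed=42)

trials = bundle.weights.drop_duplicates(
    ["participant_id", "image_id", "condition", "impression"]
)
print("participants:", len(bundle.personality))
print("stimulus images:", len(bundle.masks))
print("trials per participant per condition:")
print(trials.groupby(["participant_id", "condition"]).size().unstack())

w = bundle.weights["weight"]
print(f"\ndwell weights: {len(w)} rows, zero fraction {(w == 0).mean():.3f}, "
      f"mean positive weight {w[w > 0].mean():.3f}")

truth = bundle.truth.zib[("free", "openness", "eyes")]
print("\nplanted Bernoulli-part coefficients for free/openness/eyes:")
for trait, beta in zip(gz.TRAITS, truth.beta_bern):
    print(f"  {trait:18s} {beta:+.3f}")
print("(positive values: higher trait scores raise the probability of"
      " looking at the eyes at all)")
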