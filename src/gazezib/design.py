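"""Study-design constants and configuration objects.

The experimental design emulated throughout the package: participants rate
facial photographs on the five Big Five impression items while their gaze is
recorded, under a free-viewing condition and a condition where only a small
aperture around the mouse cursor is visible.  Each participant sees 10 images
per impression item (50 trials per condition), each trial lasting 3 s sampled
at 120 Hz on a 412x558 stimulus centered in a 1920x1080 screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TRAITS: tuple[str, ...] = (
    "extraversion",
    "agreeableness",
    "conscientiousness",
    "neuroticism",
    "openness",
)
#: Impression-rating items are the same five Big Five constructs.
IMPRESSIONS: tuple[str, ...] = TRAITS

REGIONS: tuple[str, ...] = ("eyes", "nose", "mouth", "eyebrows", "glabella", "forehead")
#: Integer label codes used in mask images; 0 is background.
REGION_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(REGIONS)}

CONDITIONS: tuple[str, ...] = ("free", "restricted")

SCREEN_DIMS: tuple[int, int] = (1920, 1080)  # (width, height) px
IMAGE_DIMS: tuple[int, int] = (412, 558)  # (width, height) px

TRAIT_SCALE = (1.0, 7.0)  # 7-point personality / impression scale


class GazezibError(Exception):
    """Base class for package errors."""


class UserInputError(GazezibError, ValueError):
    """Invalid arguments, configuration or missing resources supplied by the caller."""


@dataclass(frozen=True)
class ApertureModel:
    """Circular cursor aperture used in the restricted-viewing condition.

    A hard disc of radius ``hard_radius_px`` is fully visible; beyond it,
    visibility falls off as a Gaussian with scale ``falloff_px`` so the edge
    is smooth rather than sharp.
    """

    hard_radius_px: float = 40.0
    falloff_px: float = 40.0

    def visibility(self, r):
        """Visibility in [0, 1] at radial distance ``r`` px from the cursor."""
        import numpy as np

        r = np.asarray(r, dtype=float)
        excess = np.clip(r - self.hard_radius_px, 0.0, None)
        return np.exp(-0.5 * (excess / self.falloff_px) ** 2)


#: Aperture of the narrow (~2 deg, "discrimination visual field") restriction.
APERTURE_NARROW = ApertureModel(hard_radius_px=40.0, falloff_px=40.0)
#: Aperture of the wider (~3 deg, "effective visual field") restriction, scaled 1.5x.
APERTURE_WIDE = ApertureModel(hard_radius_px=60.0, falloff_px=60.0)


@dataclass(frozen=True)
class TrialDesign:
    """One trial: a participant views one image under one condition for one item."""

    participant_id: str
    image_id: str
    condition: str
    impression: str
    duration_s: float = 3.0
    sample_rate_hz: float = 120.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of a synthetic experiment.

    ``fidelity`` selects the generated granularity: ``"weights"`` emits the
    per-region dwell-weight table directly from the generative model (used for
    parameter recovery); ``"gaze"`` additionally synthesises raw gaze streams
    so the preprocessing stage can be exercised end to end.
    """

    n_participants: int = 42
    images_per_impression: int = 10
    impressions: tuple[str, ...] = IMPRESSIONS
    conditions: tuple[str, ...] = CONDITIONS
    fidelity: str = "weights"
    duration_s: float = 3.0
    sample_rate_hz: float = 120.0
    screen_dims: tuple[int, int] = SCREEN_DIMS
    image_dims: tuple[int, int] = IMAGE_DIMS
    trials_per_condition: int = 50
    aperture: ApertureModel = field(default_factory=lambda: APERTURE_NARROW)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise UserInputError("n_participants must be >= 1")
        if self.fidelity not in ("weights", "gaze"):
            raise UserInputError(f"unknown fidelity {self.fidelity!r}")
        expected = self.images_per_impression * len(self.impressions)
        if expected != self.trials_per_condition:
            raise UserInputError(
                "inconsistent design: images_per_impression x impressions "
                f"= {expected} trials, but trials_per_condition = {self.trials_per_condition}"
            )
        iw, ih = self.image_dims
        sw, sh = self.screen_dims
        if iw > sw or ih > sh:
            raise UserInputError("stimulus image must fit within the screen")
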