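"""Facial-region masks: the six areas of interest on the stimulus canvas.

Masks assign each pixel of the 412x558 stimulus to exactly one of the regions
eyes, nose, mouth, eyebrows, glabella, forehead, or to background (code 0).
Real studies hand-draw these per photograph; here a parametric face layout
with per-image jitter stands in for them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .design import REGION_CODES, REGIONS, UserInputError


@dataclass
class RegionMaskSet:
    """Per-pixel region labels for one stimulus image.

    ``labels`` is a ``(height, width)`` uint8 array of region codes
    (0 = background, 1..6 = eyes, nose, mouth, eyebrows, glabella, forehead).
    """

    image_id: str
    labels: np.ndarray
    _areas: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise UserInputError("labels must be a 2-D array")
        for name in REGIONS:
            area = int(np.count_nonzero(self.labels == REGION_CODES[name]))
            if area == 0:
                raise UserInputError(f"region {name!r} is empty in mask {self.image_id!r}")
            self._areas[name] = area

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def region_area(self, region: str) -> int:
        """Pixel area of a region (> 0 by construction)."""
        try:
            return self._areas[region]
        except KeyError:
            raise UserInputError(f"unknown region {region!r}") from None

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == REGION_CODES[region]

    def region_pixels(self, region: str) -> np.ndarray:
        """``(n, 2)`` array of (x, y) pixel coordinates belonging to the region."""
        ys, xs = np.nonzero(self.region_mask(region))
        return np.column_stack([xs, ys])


def _stable_image_seed(seed: int, image_id: str) -> int:
    digest = hashlib.sha256(f"{seed}:{image_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def generate_face_layout(image_id: str, width: int, height: int, seed: int = 0) -> RegionMaskSet:
    """Place six disjoint facial regions in a plausible layout with per-image jitter.

    Vertical order: forehead, eyebrows (glabella between them), eyes, nose,
    mouth.  Eyes and eyebrows are bilateral (two components sharing one code).
    Raises ``UserInputError`` when the canvas is too small to hold disjoint
    regions.
    """
    if width <= 0 or height <= 0:
        raise UserInputError("canvas dimensions must be positive")
    if width < 60 or height < 80:
        raise UserInputError(f"canvas {width}x{height} too small for a six-region face layout")

    rng = np.random.default_rng(_stable_image_seed(seed, image_id))
    labels = np.zeros((height, width), dtype=np.uint8)
    yy, xx = np.mgrid[0:height, 0:width]

    def jit(scale: float) -> float:
        return float(rng.uniform(-scale, scale))

    jx, jy = jit(0.015 * width), jit(0.01 * height)

    def ellipse(cx, cy, rx, ry):
        return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0

    def rect(x0, x1, y0, y1):
        return (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)

    shapes = {
        "forehead": rect(
            (0.25 + jit(0.02)) * width, (0.75 + jit(0.02)) * width,
            (0.06 + jit(0.01)) * height, 0.18 * height,
        ),
        "eyebrows": (
            rect(0.18 * width + jx, 0.40 * width + jx, 0.285 * height + jy, 0.325 * height + jy)
            | rect(0.60 * width + jx, 0.82 * width + jx, 0.285 * height + jy, 0.325 * height + jy)
        ),
        "glabella": rect(
            0.44 * width + jx, 0.56 * width + jx, 0.265 * height + jy, 0.345 * height + jy
        ),
        "eyes": (
            ellipse(0.30 * width + jx, 0.42 * height + jy, 0.095 * width, 0.035 * height)
            | ellipse(0.70 * width + jx, 0.42 * height + jy, 0.095 * width, 0.035 * height)
        ),
        "nose": ellipse(
            0.50 * width + jx, 0.555 * height + jy, 0.085 * width, 0.075 * height
        ),
        "mouth": ellipse(
            0.50 * width + jx, 0.73 * height + jy, 0.16 * width, 0.05 * height
        ),
    }

    for name in REGIONS:
        mask = shapes[name]
        if not mask.any():
            raise UserInputError(f"canvas {width}x{height} too small: region {name!r} empty")
        if (labels[mask] != 0).any():
            raise UserInputError(
                f"canvas {width}x{height} too small: region {name!r} overlaps another"
            )
        labels[mask] = REGION_CODES[name]

    return RegionMaskSet(image_id=image_id, labels=labels)
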