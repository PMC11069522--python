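"""Gaze-stream preprocessing into per-region dwell weights.

Screen-coordinate gaze samples are shifted into stimulus-image coordinates
(the 412x558 image is centered on the 1920x1080 screen; off-image samples are
discarded), accumulated into a pixel histogram, smoothed with an isotropic
Gaussian (SD 10 px, truncated at 4 SD) and normalised to a unit-mass density
surface.  The density mass inside each facial-region mask is divided by the
region's pixel area, and the six area-corrected values are put on a unified
scale by per-trial normalisation, giving the dwell weights G_n in [0, 1)
that the ZIB model consumes.  Values below a relative epsilon are zeroed
first so that "never looked at" regions genuinely carry G = 0 and the
zero-inflation component stays meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .design import REGIONS, UserInputError
from .regions import RegionMaskSet
from .synth import ExperimentBundle, GazeStream

#: Gaussian smoothing SD in pixels applied to the gaze histogram.
DENSITY_SIGMA = 10.0
#: Kernel truncation radius in units of sigma.
DENSITY_TRUNCATE = 4.0
#: Relative threshold below which a region's raw weight is treated as zero,
#: and the clamp distance keeping weights strictly below 1.
UNIFY_EPS = 1e-6


def screen_to_image(
    samples,
    screen_dims: tuple[int, int],
    image_dims: tuple[int, int],
) -> np.ndarray:
    """Map screen-coordinate samples to image coordinates, dropping off-image ones.

    ``samples`` is an ``(n, 2)`` array (or DataFrame with x, y columns) of
    screen-pixel positions; the stimulus is centered on screen, so the offset
    ((screen_w - img_w)/2, (screen_h - img_h)/2) is subtracted and samples
    outside the image rectangle are discarded.
    """
    sw, sh = screen_dims
    iw, ih = image_dims
    if iw > sw or ih > sh:
        raise UserInputError("image larger than screen")
    if isinstance(samples, pd.DataFrame):
        xy = samples[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(samples, dtype=float).reshape(-1, 2)
    shifted = xy - np.array([(sw - iw) / 2.0, (sh - ih) / 2.0])
    keep = (
        (shifted[:, 0] >= 0)
        & (shifted[:, 0] < iw)
        & (shifted[:, 1] >= 0)
        & (shifted[:, 1] < ih)
    )
    return shifted[keep]


def density_map(
    samples: np.ndarray,
    image_dims: tuple[int, int],
    sigma: float = DENSITY_SIGMA,
) -> np.ndarray:
    """Smoothed, unit-mass gaze density surface on the stimulus canvas.

    One unit of mass per sample is deposited at its pixel, convolved with an
    isotropic Gaussian (``sigma`` px, truncated at 4 SD), and the result is
    divided by its total so it sums to 1.  An empty sample list yields an
    all-zero map.  Returned array has shape (height, width).
    """
    if sigma <= 0:
        raise UserInputError("sigma must be > 0")
    iw, ih = image_dims
    grid = np.zeros((ih, iw), dtype=float)
    xy = np.asarray(samples, dtype=float).reshape(-1, 2)
    if xy.shape[0] == 0:
        return grid
    xs = np.clip(xy[:, 0].astype(int), 0, iw - 1)
    ys = np.clip(xy[:, 1].astype(int), 0, ih - 1)
    np.add.at(grid, (ys, xs), 1.0)
    grid = gaussian_filter(grid, sigma=sigma, truncate=DENSITY_TRUNCATE, mode="constant")
    total = grid.sum()
    if total > 0:
        grid /= total
    return grid


def region_weights(density: np.ndarray, masks: RegionMaskSet) -> np.ndarray:
    """Per-pixel dwell weight of each region: density mass over region / area."""
    density = np.asarray(density, dtype=float)
    if density.shape != masks.labels.shape:
        raise UserInputError(
            f"density {density.shape} and masks {masks.labels.shape} differ in shape"
        )
    out = np.empty(len(REGIONS))
    for idx, region in enumerate(REGIONS):
        area = masks.region_area(region)  # > 0 guaranteed by RegionMaskSet
        out[idx] = density[masks.region_mask(region)].sum() / area
    return out


def unify_scale(raw: np.ndarray, epsilon: float = UNIFY_EPS) -> np.ndarray:
    """Normalise six raw area-corrected weights to the unified G scale.

    Values below ``epsilon * max(raw)`` are zeroed (smoothing never spreads
    exactly zero mass, so a floor is needed for true zeros), the rest are
    divided by the sum of the six raw values, and anything reaching 1 is
    clamped to ``1 - epsilon`` to stay inside the Beta support.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise UserInputError("raw weights must be non-negative")
    if not raw.any():
        return np.zeros_like(raw)
    total = raw.sum()
    g = np.where(raw < epsilon * raw.max(), 0.0, raw) / total
    return np.clip(g, 0.0, 1.0 - epsilon)


def weights_from_stream(
    stream: GazeStream,
    masks: RegionMaskSet,
    screen_dims: tuple[int, int],
    sigma: float = DENSITY_SIGMA,
) -> np.ndarray:
    """Full per-trial pipeline: screen -> image -> density -> region G vector."""
    image_dims = (masks.width, masks.height)
    in_image = screen_to_image(stream.samples, screen_dims, image_dims)
    density = density_map(in_image, image_dims, sigma=sigma)
    return unify_scale(region_weights(density, masks))


def build_weight_table(bundle: ExperimentBundle, sigma: float = DENSITY_SIGMA) -> pd.DataFrame:
    """Region weight table of a dataset bundle (one row per trial x region).

    Weight-level bundles pass their generated table through untouched;
    gaze-level bundles run the preprocessing pipeline on every stream.
    """
    if bundle.fidelity == "weights":
        return bundle.weights.copy()
    rows = []
    for stream in bundle.gaze:
        trial = stream.trial
        masks = bundle.masks.get(trial.image_id)
        if masks is None:
            raise UserInputError(f"no mask available for image {trial.image_id!r}")
        g = weights_from_stream(stream, masks, bundle.config.screen_dims, sigma=sigma)
        for idx, region in enumerate(REGIONS):
            rows.append(
                (
                    trial.participant_id,
                    trial.image_id,
                    trial.condition,
                    trial.impression,
                    region,
                    g[idx],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "image_id", "condition", "impression", "region", "weight"],
    )
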