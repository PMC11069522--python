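"""Seeded synthetic datasets with the statistical structure the analysis assumes.

Two fidelity levels are generated from the same ground-truth ZIB parameters:

* ``"weights"`` — per-trial, per-region dwell weights drawn directly from the
  zero-inflated Beta generative model (the observation the fit consumes);
  used for parameter-recovery and calibration studies.
* ``"gaze"`` — raw 120 Hz gaze streams whose region allocation matches those
  weights, so the preprocessing stage can be tested end to end.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .design import (
    REGIONS,
    TRAITS,
    ApertureModel,
    ExperimentConfig,
    TrialDesign,
    UserInputError,
)
from .model import RandomEffects, ZIBParams, link_mu, link_q
from .regions import RegionMaskSet, generate_face_layout

#: Isotropic jitter (px) around the targeted point when synthesising gaze.
GAZE_JITTER_SD = 10.0
#: Upper clamp keeping generated weights inside the ZIB support [0, 1).
WEIGHT_EPS = 1e-6


def generate_participants(
    n: int, seed: int, distribution: str = "grid-uniform"
) -> pd.DataFrame:
    """Synthetic Big Five profiles: ``n`` rows, five trait scores each in [1, 7].

    The default draws each score uniformly from the integer 7-point grid,
    mirroring questionnaire scores; ``"continuous-uniform"`` draws from the
    continuous interval instead (questionnaire item-pair averages fall on
    half-points, so continuous values are equally plausible).
    """
    if n <= 0:
        raise UserInputError("number of participants must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "grid-uniform":
        scores = rng.integers(1, 8, size=(n, len(TRAITS))).astype(float)
    elif distribution == "continuous-uniform":
        scores = rng.uniform(1.0, 7.0, size=(n, len(TRAITS)))
    else:
        raise UserInputError(f"unknown trait distribution {distribution!r}")
    table = pd.DataFrame(scores, columns=list(TRAITS))
    table.insert(0, "participant_id", [f"p{i:03d}" for i in range(n)])
    return table


@dataclass
class GazeStream:
    """Ordered gaze samples of one trial, in screen coordinates."""

    trial: TrialDesign
    samples: pd.DataFrame  # columns t, x, y

    def __post_init__(self) -> None:
        t = self.samples["t"].to_numpy()
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.trial.duration_s):
            raise UserInputError("timestamps must be strictly increasing within [0, duration]")
        if len(t) > self.trial.n_samples:
            raise UserInputError("sample count exceeds duration x rate budget")


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests.

    ``zib`` maps (condition, impression, region) to the fixed-effect /
    precision parameters; ``effects`` maps the same scope to the realised
    random intercepts.
    """

    zib: dict[tuple[str, str, str], ZIBParams]
    effects: dict[tuple[str, str, str], RandomEffects]
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "zib": {"|".join(k): v.to_dict() for k, v in self.zib.items()},
            "effects": {
                "|".join(k): {
                    "r_subj_bern": eff.r_subj_bern,
                    "r_pic_bern": eff.r_pic_bern,
                    "r_subj_beta": eff.r_subj_beta,
                    "r_pic_beta": eff.r_pic_beta,
                }
                for k, eff in self.effects.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            seed=d["seed"],
            zib={tuple(k.split("|")): ZIBParams.from_dict(v) for k, v in d["zib"].items()},
            effects={
                tuple(k.split("|")): RandomEffects(**v) for k, v in d["effects"].items()
            },
        )


@dataclass
class ExperimentBundle:
    """Everything one synthetic experiment produced."""

    config: ExperimentConfig
    personality: pd.DataFrame
    masks: dict[str, RegionMaskSet]
    weights: pd.DataFrame  # region weight table (one row per trial x region)
    truth: GroundTruth
    gaze: list[GazeStream] = field(default_factory=list)

    @property
    def fidelity(self) -> str:
        return self.config.fidelity


def default_ground_truth(
    scopes,
    seed: int,
    effect_scale: float = 0.2,
    base_q: float = 0.7,
    base_mu: float = 0.12,
    phi: float = 30.0,
    sigma: float = 0.5,
    null: bool = False,
) -> dict[tuple[str, str, str], ZIBParams]:
    """Moderate, reproducible ground-truth ZIB parameters for each scope.

    Trait coefficients are drawn Normal(0, ``effect_scale``) (zero when
    ``null``); intercepts are chosen so that at the mid-scale personality
    profile (all traits 4) the focus probability is ``base_q`` and the mean
    positive dwell is ``base_mu``.  ``base_mu`` is small enough that the six
    independently drawn region weights rarely sum above 1, matching the
    area-normalised dwell weights real preprocessing produces.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    out: dict[tuple[str, str, str], ZIBParams] = {}
    for scope in scopes:
        b_bern = np.zeros(5) if null else rng.normal(0.0, effect_scale, 5)
        b_beta = np.zeros(5) if null else rng.normal(0.0, effect_scale / 2, 5)
        out[tuple(scope)] = ZIBParams(
            alpha_bern=float(logit(base_q) - 4.0 * b_bern.sum()),
            beta_bern=b_bern,
            alpha_beta=float(logit(base_mu) - 4.0 * b_beta.sum()),
            beta_beta=b_beta,
            phi=phi,
            sigma_subj_bern=sigma,
            sigma_pic_bern=sigma,
            sigma_subj_beta=sigma,
            sigma_pic_beta=sigma,
        )
    return out


def sample_trial_weights(
    params: ZIBParams | dict[str, ZIBParams],
    personality_row,
    subject_effect=0.0,
    picture_effect=0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the six region dwell weights of one trial from the ZIB model.

    For each region: z ~ Bernoulli(q); zero weight when z = 0, otherwise a
    Beta(phi*mu, phi*(1-mu)) draw, with q and mu from the logistic links at
    this participant's trait scores.  ``params`` is one ``ZIBParams`` shared
    by all regions or a mapping region -> ``ZIBParams``; each effect is a
    (bernoulli, beta) offset pair (or a single float for both parts), again
    shared or per-region.
    """
    rng = rng if rng is not None else np.random.default_rng()

    def pick(obj, region):
        return obj[region] if isinstance(obj, dict) else obj

    def pair(val):
        if np.isscalar(val):
            return float(val), float(val)
        rb, rB = val
        return float(rb), float(rB)

    out = np.empty(len(REGIONS))
    for idx, region in enumerate(REGIONS):
        p = pick(params, region)
        r_subj_b, r_subj_B = pair(pick(subject_effect, region))
        r_pic_b, r_pic_B = pair(pick(picture_effect, region))
        q = float(link_q(personality_row, p.alpha_bern, p.beta_bern, r_subj_b, r_pic_b))
        if rng.uniform() >= q:
            out[idx] = 0.0
            continue
        mu = float(link_mu(personality_row, p.alpha_beta, p.beta_beta, r_subj_B, r_pic_B))
        draw = rng.beta(p.phi * mu, p.phi * (1.0 - mu))
        out[idx] = float(np.clip(draw, 1e-9, 1.0 - WEIGHT_EPS))
    return out


def generate_gaze_stream(
    trial: TrialDesign,
    target_weights: np.ndarray,
    masks: RegionMaskSet,
    aperture: ApertureModel | None,
    seed: int,
    screen_dims: tuple[int, int] = (1920, 1080),
    jitter_sd: float = GAZE_JITTER_SD,
) -> GazeStream:
    """Synthesise one trial's gaze stream matching a target region allocation.

    The per-trial sample budget (duration x rate) is split across regions in
    proportion to ``target_weights``; the remainder falls on background
    pixels.  Free viewing scatters the dwell samples in random trial order;
    restricted viewing (``aperture`` given) orders them as a cursor tour that
    starts at the canvas center and visits each allocated region in turn,
    spending the background budget on transit between regions.
    """
    w = np.asarray(target_weights, dtype=float)
    if w.shape != (len(REGIONS),) or np.any(w < 0):
        raise UserInputError("target_weights must be six non-negative values")
    if w.sum() > 1.0 + 1e-9:
        raise UserInputError("target_weights must sum to <= 1")
    rng = np.random.default_rng(seed)
    budget = trial.n_samples
    counts = np.floor(w * budget).astype(int)
    n_bg = budget - int(counts.sum())

    code = {r: i + 1 for i, r in enumerate(REGIONS)}

    def region_points(region: str, n: int) -> np.ndarray:
        """Jittered points that stay inside the allocated region.

        A jittered point escaping the region would silently reallocate dwell
        to a neighbour, so jitter is rejection-sampled (pixel kept as-is
        after a few failures)."""
        pix = masks.region_pixels(region)
        if pix.shape[0] == 0:
            raise UserInputError(f"region {region!r} is empty")
        pts = pix[rng.integers(0, pix.shape[0], n)].astype(float)
        out = pts.copy()
        pending = np.arange(n)
        for _ in range(8):
            if not pending.size:
                break
            cand = pts[pending] + rng.normal(0.0, jitter_sd, (pending.size, 2))
            xi = np.clip(cand[:, 0].astype(int), 0, masks.width - 1)
            yi = np.clip(cand[:, 1].astype(int), 0, masks.height - 1)
            ok = masks.labels[yi, xi] == code[region]
            out[pending[ok]] = cand[ok]
            pending = pending[~ok]
        return out

    bg_pix = np.column_stack(np.nonzero(masks.labels == 0)[::-1])  # (x, y)

    segments: list[np.ndarray] = []
    if aperture is None:
        for idx, region in enumerate(REGIONS):
            if counts[idx]:
                segments.append(region_points(region, counts[idx]))
        if n_bg:
            segments.append(bg_pix[rng.integers(0, bg_pix.shape[0], n_bg)].astype(float))
        order = rng.permutation(len(segments))
        segments = [segments[i] for i in order]
    else:
        # cursor tour: center -> region -> region ...; cursor moves between
        # targets are fast, so each transit leg carries only a few samples and
        # the rest of the non-dwell budget is spent hovering over background
        visit = [i for i in rng.permutation(len(REGIONS)) if counts[i] > 0]
        pos = np.array([masks.width / 2.0, masks.height / 2.0])
        bg_left = n_bg
        for idx in visit:
            pix = masks.region_pixels(REGIONS[idx])
            target = pix[rng.integers(0, pix.shape[0])].astype(float)
            n_transit = min(4, bg_left)
            if n_transit:
                frac = np.linspace(0.0, 1.0, n_transit, endpoint=False)[:, None]
                path = pos + frac * (target - pos)
                segments.append(path + rng.normal(0.0, jitter_sd / 2, path.shape))
                bg_left -= n_transit
            segments.append(region_points(REGIONS[idx], counts[idx]))
            pos = target
        if bg_left:
            segments.append(bg_pix[rng.integers(0, bg_pix.shape[0], bg_left)].astype(float))

    xy = np.concatenate(segments) if segments else np.empty((0, 2))
    # image -> screen coordinates (stimulus centered on screen)
    sw, sh = screen_dims
    xy = xy + np.array([(sw - masks.width) / 2.0, (sh - masks.height) / 2.0])
    t = (np.arange(len(xy)) + 0.5) / trial.sample_rate_hz
    frame = pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1]})
    return GazeStream(trial=trial, samples=frame)


def _image_ids(config: ExperimentConfig) -> dict[str, list[str]]:
    """Ten fixed images per impression item, distinct across items (50 total)."""
    ids: dict[str, list[str]] = {}
    counter = 0
    for impression in config.impressions:
        ids[impression] = [f"img{counter + k:03d}" for k in range(config.images_per_impression)]
        counter += config.images_per_impression
    return ids


def generate_experiment(
    config: ExperimentConfig | None = None,
    seed: int = 0,
    truth: dict[tuple[str, str, str], ZIBParams] | None = None,
    null_effects: bool = False,
) -> ExperimentBundle:
    """Generate a full synthetic experiment bundle, reproducibly.

    ``truth`` overrides the default ground-truth ZIB parameters (keyed by
    (condition, impression, region)); ``null_effects`` zeroes all planted
    trait coefficients (for calibration studies).
    """
    config = config or ExperimentConfig()
    config.validate()
    root = np.random.SeedSequence(seed)
    ss_pers, ss_truth, ss_effects, ss_weights, ss_gaze = root.spawn(5)

    personality = generate_participants(
        config.n_participants, int(ss_pers.generate_state(1)[0] % 2**31)
    )
    images = _image_ids(config)
    all_images = [img for imgs in images.values() for img in imgs]
    iw, ih = config.image_dims
    masks = {img: generate_face_layout(img, iw, ih, seed=seed) for img in all_images}

    scopes = [
        (cond, impr, region)
        for cond in config.conditions
        for impr in config.impressions
        for region in REGIONS
    ]
    if truth is None:
        truth = default_ground_truth(
            scopes, int(ss_truth.generate_state(1)[0] % 2**31), null=null_effects
        )
    else:
        missing = [s for s in scopes if tuple(s) not in truth]
        if missing:
            raise UserInputError(f"ground truth missing for scopes: {missing[:3]}...")

    eff_rng = np.random.default_rng(ss_effects)
    effects: dict[tuple[str, str, str], RandomEffects] = {}
    for scope in scopes:
        params = truth[scope]
        _, impr, _ = scope
        effects[scope] = RandomEffects(
            r_subj_bern={
                p: float(eff_rng.normal(0, params.sigma_subj_bern))
                for p in personality["participant_id"]
            },
            r_pic_bern={
                j: float(eff_rng.normal(0, params.sigma_pic_bern)) for j in images[impr]
            },
            r_subj_beta={
                p: float(eff_rng.normal(0, params.sigma_subj_beta))
                for p in personality["participant_id"]
            },
            r_pic_beta={
                j: float(eff_rng.normal(0, params.sigma_pic_beta)) for j in images[impr]
            },
        )

    w_rng = np.random.default_rng(ss_weights)
    rows = []
    trait_lookup = personality.set_index("participant_id")[list(TRAITS)]
    for cond in config.conditions:
        for _, prow in personality.iterrows():
            pid = prow["participant_id"]
            pvec = trait_lookup.loc[pid].to_numpy()
            for impr in config.impressions:
                params_by_region = {r: truth[(cond, impr, r)] for r in REGIONS}
                subj_eff = {
                    r: (
                        effects[(cond, impr, r)].r_subj_bern[pid],
                        effects[(cond, impr, r)].r_subj_beta[pid],
                    )
                    for r in REGIONS
                }
                for img in images[impr]:
                    pic_eff = {
                        r: (
                            effects[(cond, impr, r)].r_pic_bern[img],
                            effects[(cond, impr, r)].r_pic_beta[img],
                        )
                        for r in REGIONS
                    }
                    wvec = sample_trial_weights(
                        params_by_region, pvec, subj_eff, pic_eff, w_rng
                    )
                    for ridx, region in enumerate(REGIONS):
                        rows.append((pid, img, cond, impr, region, wvec[ridx]))
    weights = pd.DataFrame(
        rows,
        columns=["participant_id", "image_id", "condition", "impression", "region", "weight"],
    )

    gaze: list[GazeStream] = []
    if config.fidelity == "gaze":
        g_rng = np.random.default_rng(ss_gaze)
        wide = weights.pivot_table(
            index=["participant_id", "image_id", "condition", "impression"],
            columns="region",
            values="weight",
            sort=False,
        )[list(REGIONS)]
        for key, wrow in wide.iterrows():
            pid, img, cond, impr = key
            trial = TrialDesign(
                participant_id=pid,
                image_id=img,
                condition=cond,
                impression=impr,
                duration_s=config.duration_s,
                sample_rate_hz=config.sample_rate_hz,
            )
            wvec = wrow.to_numpy(dtype=float)
            total = wvec.sum()
            if total > 1.0:
                wvec = wvec / total
            gaze.append(
                generate_gaze_stream(
                    trial,
                    wvec,
                    masks[img],
                    config.aperture if cond == "restricted" else None,
                    seed=int(g_rng.integers(0, 2**31)),
                    screen_dims=config.screen_dims,
                )
            )

    return ExperimentBundle(
        config=config,
        personality=personality,
        masks=masks,
        weights=weights,
        truth=GroundTruth(zib=truth, effects=effects, seed=seed),
        gaze=gaze,
    )
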