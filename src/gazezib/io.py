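"""File formats: personality / gaze / weight CSVs, mask PNGs, posterior dumps.

All tabular data travels as plain CSV; masks are 8-bit PNG label images
(0 = background, 1..6 = eyes, nose, mouth, eyebrows, glabella, forehead)
with a JSON sidecar carrying the code map and image id; ground truth and
posterior metadata are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .design import REGION_CODES, TRAITS, TrialDesign, UserInputError
from .regions import RegionMaskSet
from .sampler import MCMCConfig, PosteriorSamples
from .synth import GazeStream, GroundTruth

PERSONALITY_COLUMNS = ["participant_id", *TRAITS]
GAZE_COLUMNS = ["participant_id", "image_id", "condition", "impression", "t", "x", "y"]
WEIGHT_COLUMNS = ["participant_id", "image_id", "condition", "impression", "region", "weight"]


def write_personality(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table[PERSONALITY_COLUMNS].to_csv(path, index=False, float_format="%.10g")
    return path


def read_personality(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(PERSONALITY_COLUMNS) - set(table.columns)
    if missing:
        raise UserInputError(f"personality table missing columns: {sorted(missing)}")
    table = table[PERSONALITY_COLUMNS]
    return table.astype({t: float for t in TRAITS})


def write_weights(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table[WEIGHT_COLUMNS].to_csv(path, index=False, float_format="%.12g")
    return path


def read_weights(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(WEIGHT_COLUMNS) - set(table.columns)
    if missing:
        raise UserInputError(f"weight table missing columns: {sorted(missing)}")
    return table


def write_gaze(streams, path) -> Path:
    """All gaze streams in one long CSV (screen coordinates, origin top-left)."""
    path = Path(path)
    frames = []
    for stream in streams:
        f = stream.samples.copy()
        f.insert(0, "impression", stream.trial.impression)
        f.insert(0, "condition", stream.trial.condition)
        f.insert(0, "image_id", stream.trial.image_id)
        f.insert(0, "participant_id", stream.trial.participant_id)
        frames.append(f)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=GAZE_COLUMNS)
    )
    out[GAZE_COLUMNS].to_csv(path, index=False, float_format="%.6g")
    return path


def read_gaze(path, duration_s: float = 3.0, sample_rate_hz: float = 120.0) -> list[GazeStream]:
    table = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(table.columns)
    if missing:
        raise UserInputError(f"gaze table missing columns: {sorted(missing)}")
    streams = []
    keys = ["participant_id", "image_id", "condition", "impression"]
    for key, sub in table.groupby(keys, sort=False):
        trial = TrialDesign(
            participant_id=key[0],
            image_id=key[1],
            condition=key[2],
            impression=key[3],
            duration_s=duration_s,
            sample_rate_hz=sample_rate_hz,
        )
        streams.append(
            GazeStream(trial=trial, samples=sub[["t", "x", "y"]].reset_index(drop=True))
        )
    return streams


def write_mask(masks: RegionMaskSet, directory) -> tuple[Path, Path]:
    """8-bit PNG label image plus JSON sidecar with the code map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png_path = directory / f"{masks.image_id}_mask.png"
    Image.fromarray(masks.labels, mode="L").save(png_path)
    sidecar = {
        "image_id": masks.image_id,
        "width": masks.width,
        "height": masks.height,
        "codes": {"background": 0, **REGION_CODES},
    }
    json_path = directory / f"{masks.image_id}_mask.json"
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return png_path, json_path


def read_mask(png_path) -> RegionMaskSet:
    png_path = Path(png_path)
    sidecar_path = png_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise UserInputError(f"mask sidecar {sidecar_path} not found")
    sidecar = json.loads(sidecar_path.read_text())
    labels = np.asarray(Image.open(png_path), dtype=np.uint8)
    return RegionMaskSet(image_id=sidecar["image_id"], labels=labels)


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    return path


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_posterior(post: PosteriorSamples, directory) -> tuple[Path, Path]:
    """Long-format draws CSV plus a JSON sidecar with scope/config/digest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scope = post.scope
    model_id = "_".join(
        scope.get(k, "") for k in ("condition", "impression", "region")
    ).strip("_") or "fit"
    rows = []
    for name, arr in post.flat():
        c_idx, d_idx = np.meshgrid(
            np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij"
        )
        rows.append(
            pd.DataFrame(
                {
                    "model_id": model_id,
                    "parameter": name,
                    "chain": c_idx.ravel(),
                    "draw": d_idx.ravel(),
                    "value": arr.ravel(),
                }
            )
        )
    csv_path = directory / f"{model_id}_draws.csv"
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False, float_format="%.12g")
    meta = {
        "model_id": model_id,
        "scope": scope,
        "config": post.config.to_dict(),
        "data_digest": post.data_digest,
        "subjects": post.subjects,
        "images": post.images,
        "warnings": post.warnings,
    }
    meta_path = directory / f"{model_id}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path, meta_path


def read_posterior(csv_path) -> PosteriorSamples:
    csv_path = Path(csv_path)
    meta_path = csv_path.with_name(csv_path.name.replace("_draws.csv", "_meta.json"))
    if not meta_path.exists():
        raise UserInputError(f"posterior metadata {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    table = pd.read_csv(csv_path)
    config = MCMCConfig(**meta["config"])
    n_chains = int(table["chain"].max()) + 1
    n_draws = int(table["draw"].max()) + 1

    scalar: dict[str, np.ndarray] = {}
    for name, sub in table.groupby("parameter", sort=False):
        scalar[name] = (
            sub.sort_values(["chain", "draw"])["value"]
            .to_numpy()
            .reshape(n_chains, n_draws)
        )

    def collect(base: str, labels: list[str]) -> np.ndarray:
        return np.stack([scalar.pop(f"{base}[{lab}]") for lab in labels], axis=2)

    params: dict[str, np.ndarray] = {}
    for name in (
        "alpha_bern",
        "alpha_beta",
        "phi",
        "sigma_subj_bern",
        "sigma_pic_bern",
        "sigma_subj_beta",
        "sigma_pic_beta",
    ):
        params[name] = scalar.pop(name)
    params["beta_bern"] = collect("beta_bern", list(TRAITS))
    params["beta_beta"] = collect("beta_beta", list(TRAITS))
    params["r_subj_bern"] = collect("r_subj_bern", meta["subjects"])
    params["r_pic_bern"] = collect("r_pic_bern", meta["images"])
    params["r_subj_beta"] = collect("r_subj_beta", meta["subjects"])
    params["r_pic_beta"] = collect("r_pic_beta", meta["images"])
    return PosteriorSamples(
        params=params,
        scope=meta["scope"],
        config=config,
        subjects=meta["subjects"],
        images=meta["images"],
        data_digest=meta["data_digest"],
        warnings=meta.get("warnings", []),
    )
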