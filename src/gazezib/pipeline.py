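"""End-to-end orchestration: simulate -> preprocess -> fit -> report.

Each stage is an importable function operating on directories of the plain
file formats in :mod:`gazezib.io`; a JSON run manifest records config and
seed digests plus a SHA-256 digest of every file written, so deterministic
stages are verifiable by digest equality across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .design import REGIONS, ExperimentConfig, UserInputError
from .diagnostics import check_convergence, significance_table
from .preprocess import build_weight_table
from .sampler import MCMCConfig, fit
from .sweep import condition_difference, export_sweep, trait_sweep
from .synth import ExperimentBundle, generate_experiment

logger = logging.getLogger(__name__)

try:  # package version for the manifest
    from importlib.metadata import version as _pkg_version

    _VERSION = _pkg_version("gazezib")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, stage: str, seed: int, config: dict, files) -> Path:
    outdir = Path(outdir)
    manifest = {
        "stage": stage,
        "seed": seed,
        "package_version": _VERSION,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_digest": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "files": {str(Path(f).name): _sha256(Path(f)) for f in files},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise UserInputError("config file must contain a YAML mapping")
    return cfg


def experiment_config_from_dict(d: dict) -> ExperimentConfig:
    base = ExperimentConfig()
    known = {
        "n_participants",
        "images_per_impression",
        "impressions",
        "conditions",
        "fidelity",
        "duration_s",
        "sample_rate_hz",
        "trials_per_condition",
    }
    unknown = set(d) - known
    if unknown:
        raise UserInputError(f"unknown experiment config keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("impressions", "conditions"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "images_per_impression" in kwargs and "trials_per_condition" not in kwargs:
        n_impr = len(kwargs.get("impressions", base.impressions))
        kwargs["trials_per_condition"] = kwargs["images_per_impression"] * n_impr
    return replace(base, **kwargs)


def simulate(config: ExperimentConfig, seed: int, outdir, null_effects: bool = False) -> Path:
    """Generate a synthetic dataset bundle and write it to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_experiment(config, seed=seed, null_effects=null_effects)
    files = [
        gio.write_personality(bundle.personality, outdir / "personality.csv"),
        gio.write_weights(bundle.weights, outdir / "weights.csv"),
        gio.write_ground_truth(bundle.truth, outdir / "ground_truth.json"),
    ]
    mask_dir = outdir / "masks"
    for masks in bundle.masks.values():
        files.extend(gio.write_mask(masks, mask_dir))
    if bundle.gaze:
        files.append(gio.write_gaze(bundle.gaze, outdir / "gaze.csv"))
    cfg_dict = {
        "n_participants": config.n_participants,
        "images_per_impression": config.images_per_impression,
        "impressions": list(config.impressions),
        "conditions": list(config.conditions),
        "fidelity": config.fidelity,
        "null_effects": null_effects,
    }
    (outdir / "experiment.json").write_text(json.dumps(cfg_dict, indent=1, sort_keys=True))
    files.append(outdir / "experiment.json")
    write_manifest(outdir, "simulate", seed, cfg_dict, files)
    return outdir


def load_bundle(dataset_dir) -> ExperimentBundle:
    """Rehydrate a simulated dataset directory into an in-memory bundle."""
    dataset_dir = Path(dataset_dir)
    exp_path = dataset_dir / "experiment.json"
    if not exp_path.exists():
        raise UserInputError(f"{dataset_dir} is not a dataset directory (no experiment.json)")
    exp = json.loads(exp_path.read_text())
    config = experiment_config_from_dict(
        {k: v for k, v in exp.items() if k != "null_effects"}
    )
    masks = {}
    for png in sorted((dataset_dir / "masks").glob("*_mask.png")):
        m = gio.read_mask(png)
        masks[m.image_id] = m
    gaze_path = dataset_dir / "gaze.csv"
    gaze = (
        gio.read_gaze(gaze_path, config.duration_s, config.sample_rate_hz)
        if gaze_path.exists()
        else []
    )
    return ExperimentBundle(
        config=config,
        personality=gio.read_personality(dataset_dir / "personality.csv"),
        masks=masks,
        weights=gio.read_weights(dataset_dir / "weights.csv"),
        truth=gio.read_ground_truth(dataset_dir / "ground_truth.json"),
        gaze=gaze,
    )


def preprocess(dataset_dir, out_path) -> Path:
    """Build the region weight table of a dataset directory."""
    bundle = load_bundle(dataset_dir)
    table = build_weight_table(bundle)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    gio.write_weights(table, out_path)
    write_manifest(out_path.parent, "preprocess", 0, {"dataset": str(dataset_dir)}, [out_path])
    return out_path


def parse_scope(scope_str: str | None) -> dict:
    """Parse ``condition=free,impression=openness,region=eyes`` style filters."""
    out: dict[str, list[str]] = {}
    if not scope_str:
        return out
    for part in scope_str.split(","):
        if "=" not in part:
            raise UserInputError(f"bad scope fragment {part!r}; expected key=value")
        key, value = part.split("=", 1)
        key = key.strip()
        if key not in ("condition", "impression", "region"):
            raise UserInputError(f"unknown scope key {key!r}")
        out.setdefault(key, []).append(value.strip())
    return out


def fit_scopes(
    weights: pd.DataFrame,
    personality: pd.DataFrame,
    scope_filters: dict | None,
    config: MCMCConfig,
    outdir=None,
):
    """Fit one ZIB model per (condition, impression, region) in the filters."""
    scope_filters = scope_filters or {}
    conditions = scope_filters.get("condition") or sorted(weights["condition"].unique())
    impressions = scope_filters.get("impression") or sorted(weights["impression"].unique())
    regions = scope_filters.get("region") or list(REGIONS)
    posteriors = []
    files = []
    for cond in conditions:
        for impr in impressions:
            for region in regions:
                t0 = time.time()
                post = fit(weights, personality, (cond, impr, region), config)
                logger.info(
                    "fitted %s/%s/%s in %.1fs", cond, impr, region, time.time() - t0
                )
                posteriors.append(post)
                if outdir is not None:
                    files.extend(gio.write_posterior(post, outdir))
    if outdir is not None:
        write_manifest(
            Path(outdir), "fit", config.seed, {"scopes": scope_filters or "all", **config.to_dict()}, files
        )
    return posteriors


def report(posteriors, outdir, sweep_trait: str | None = "conscientiousness", plot: bool = False):
    """Convergence report, significance table, and trait sweeps / differences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    convergence = {
        "_".join(p.scope.get(k, "") for k in ("condition", "impression", "region")):
            check_convergence(p).to_dict()
        for p in posteriors
    }
    conv_path = outdir / "convergence.json"
    conv_path.write_text(json.dumps(convergence, indent=1, sort_keys=True))
    files.append(conv_path)

    table = significance_table(posteriors)
    sig_path = outdir / "significance.csv"
    table.to_csv(sig_path, index=False, float_format="%.6g")
    files.append(sig_path)

    if sweep_trait is not None:
        by_scope: dict[tuple[str, str], dict[str, object]] = {}
        for p in posteriors:
            key = (p.scope.get("condition", ""), p.scope.get("impression", ""))
            by_scope.setdefault(key, {})[p.scope.get("region", "")] = p
        sweeps = {}
        for (cond, impr), region_fits in by_scope.items():
            if set(REGIONS) - set(region_fits):
                continue  # incomplete scope; skip sweep for this pair
            curves = trait_sweep(region_fits, sweep_trait)
            sweeps[(cond, impr)] = curves
            files.extend(export_sweep(curves, outdir / "sweeps", plot=plot))
        for impr in {k[1] for k in sweeps}:
            if ("restricted", impr) in sweeps and ("free", impr) in sweeps:
                diff = condition_difference(
                    sweeps[("restricted", impr)], sweeps[("free", impr)]
                )
                files.extend(export_sweep(diff, outdir / "sweeps", plot=plot))

    write_manifest(outdir, "report", 0, {"sweep_trait": sweep_trait}, files)
    return outdir
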