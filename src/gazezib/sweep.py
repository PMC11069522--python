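"""Posterior trait sweeps: model-based simulation of gaze change with personality.

One trait is swept over the 7-point scale while the other four are fixed at
3; for every posterior draw and every region the Bernoulli focus probability
q and the Beta dwell mean mu are evaluated at the population level (random
effects zero), then summarised pointwise by the posterior mean and 95% HDI.
Restricted minus free condition differences are formed draw-wise (draws
paired by index) before summarising, so the interval reflects the posterior
of the difference, not the difference of intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import REGIONS, TRAITS, UserInputError
from .diagnostics import hdi
from .sampler import PosteriorSamples

DEFAULT_GRID = np.arange(1.0, 8.0)
FIXED_TRAIT_VALUE = 3.0


@dataclass
class SweepCurves:
    """Per-region draw-level curves plus pointwise summaries.

    ``draws`` maps region -> statistic -> (n_draws, n_grid) array; statistics
    are "q" (focus probability), "mu" (dwell frequency) and optionally "qmu"
    (unconditional expected dwell, q * mu).
    """

    condition: str
    impression: str
    trait: str
    grid: np.ndarray
    draws: dict[str, dict[str, np.ndarray]]
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summarise(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for region, stats in self.draws.items():
            for stat, arr in stats.items():
                for gi, t in enumerate(self.grid):
                    lo, hi = hdi(arr[:, gi], mass=mass)
                    rows.append((region, float(t), stat, float(arr[:, gi].mean()), lo, hi))
        return pd.DataFrame(
            rows, columns=["region", "grid_value", "statistic", "mean", "hdi_low", "hdi_high"]
        )


def trait_sweep(
    posteriors: dict[str, PosteriorSamples],
    trait: str,
    grid=DEFAULT_GRID,
    fixed_value: float = FIXED_TRAIT_VALUE,
    include_qmu: bool = False,
    mass: float = 0.95,
) -> SweepCurves:
    """Sweep one trait over ``grid`` with the others fixed, per region.

    ``posteriors`` maps each of the six region names to that region's fit for
    a single condition and impression item.  Random effects are set to zero
    (population-level curves); q and mu are evaluated per posterior draw and
    summarised pointwise.
    """
    missing = [r for r in REGIONS if r not in posteriors]
    if missing:
        raise UserInputError(f"missing region fits for sweep: {missing}")
    if trait not in TRAITS:
        raise UserInputError(f"unknown trait {trait!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise UserInputError("grid must be strictly increasing")

    scopes = {r: posteriors[r].scope for r in REGIONS}
    conditions = {s.get("condition", "") for s in scopes.values()}
    impressions = {s.get("impression", "") for s in scopes.values()}
    if len(conditions) > 1 or len(impressions) > 1:
        raise UserInputError("sweep posteriors must share one condition and impression")

    k = TRAITS.index(trait)
    # design matrix over the grid: swept trait varies, others fixed
    P = np.full((grid.size, len(TRAITS)), fixed_value)
    P[:, k] = grid

    from scipy.special import expit

    draws: dict[str, dict[str, np.ndarray]] = {}
    for region in REGIONS:
        post = posteriors[region]
        q = expit(
            post.stacked("alpha_bern")[:, None]
            + post.stacked("beta_bern") @ P.T
        )
        mu = expit(
            post.stacked("alpha_beta")[:, None]
            + post.stacked("beta_beta") @ P.T
        )
        stats = {"q": q, "mu": mu}
        if include_qmu:
            stats["qmu"] = q * mu
        draws[region] = stats

    curves = SweepCurves(
        condition=next(iter(conditions)),
        impression=next(iter(impressions)),
        trait=trait,
        grid=grid,
        draws=draws,
    )
    curves.summaries = curves.summarise(mass=mass)
    return curves


def condition_difference(
    restricted: SweepCurves, free: SweepCurves, mass: float = 0.95
) -> SweepCurves:
    """Draw-wise restricted - free difference curves (> 0: restricted dominant)."""
    if restricted.impression != free.impression or restricted.trait != free.trait:
        raise UserInputError("sweeps differ in impression or swept trait")
    if restricted.grid.shape != free.grid.shape or np.any(restricted.grid != free.grid):
        raise UserInputError("sweeps differ in trait grid")
    diff: dict[str, dict[str, np.ndarray]] = {}
    for region in REGIONS:
        a, b = restricted.draws[region], free.draws[region]
        if set(a) != set(b):
            raise UserInputError("sweeps differ in computed statistics")
        diff[region] = {}
        for stat in a:
            if a[stat].shape != b[stat].shape:
                raise UserInputError(
                    f"draw counts differ for {region}/{stat}: "
                    f"{a[stat].shape} vs {b[stat].shape}"
                )
            diff[region][stat] = a[stat] - b[stat]
    curves = SweepCurves(
        condition=f"{restricted.condition}-{free.condition}",
        impression=restricted.impression,
        trait=restricted.trait,
        grid=restricted.grid.copy(),
        draws=diff,
    )
    curves.summaries = curves.summarise(mass=mass)
    return curves


def export_sweep(result: SweepCurves, path, plot: bool = False) -> list[Path]:
    """Write a sweep (or difference) to CSV, optionally with per-region plots.

    CSV rows: region, grid_value, statistic, mean, hdi_low, hdi_high.  Files
    are named ``{condition}_{impression}_{trait}_{statistic}``; re-exporting
    the same result is byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stem = f"{result.condition}_{result.impression}_{result.trait}"
    written = []
    table = result.summaries.sort_values(
        ["statistic", "region", "grid_value"], kind="mergesort"
    ).reset_index(drop=True)
    for stat, sub in table.groupby("statistic"):
        csv_path = path / f"{stem}_{stat}.csv"
        sub.to_csv(csv_path, index=False, float_format="%.10g")
        written.append(csv_path)

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for stat, sub in table.groupby("statistic"):
            fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
            for ax, region in zip(axes.ravel(), REGIONS):
                rsub = sub[sub["region"] == region]
                ax.plot(rsub["grid_value"], rsub["mean"], marker="o")
                ax.fill_between(
                    rsub["grid_value"], rsub["hdi_low"], rsub["hdi_high"], alpha=0.25
                )
                ax.set_title(region)
                ax.set_xlabel(f"{result.trait} score")
                ax.set_ylabel(stat)
            fig.suptitle(f"{result.condition} / {result.impression} ({stat})")
            fig.tight_layout()
            png_path = path / f"{stem}_{stat}.png"
            fig.savefig(png_path, dpi=100)
            plt.close(fig)
            written.append(png_path)
    return written
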