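"""Convergence diagnostics, highest-density intervals and significance tables.

Split-Rhat is the Gelman-Rubin potential scale reduction computed after
halving each chain (rank-free variant); a fit counts as converged when it
used at least three chains and every parameter's split-Rhat is below 1.1.
The 95% HDI is found by exhaustive sliding-window search over the sorted
draws (shortest contiguous window holding the requested mass).  A trait
coefficient enters the significance table iff its HDI excludes zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import UserInputError
from .sampler import PosteriorSamples

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1
MIN_CHAINS = 3

#: Display names used in the reported tables.
MODEL_PART_LABELS = {"bern": "Bernoulli", "beta": "Beta"}


def split_rhat(draws: np.ndarray) -> float:
    """Rank-free split-Rhat of one parameter.

    ``draws`` has shape (chains, iterations).  Each chain is halved, and the
    usual sqrt(V_hat / W) ratio of pooled to within-half-chain variance is
    returned; a degenerate all-constant input returns 1.0 by convention.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise UserInputError("draws must be (chains, iterations)")
    n_chains, n_iter = draws.shape
    if n_chains < 2 or n_iter < 4:
        raise UserInputError("need >= 2 chains of >= 4 draws for split-Rhat")
    if np.all(draws == draws.flat[0]):
        return 1.0  # degenerate constant input: 0/0 treated as converged
    half = n_iter // 2
    halves = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = float(halves.var(axis=1, ddof=1).mean())
    B = float(n * means.var(ddof=1))
    if W == 0.0:
        return 1.0
    v_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(v_hat / W))


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Sliding-window search over the sorted sample vector: the window holds
    ceil(mass * n) points; ties in width are broken toward the lowest
    starting index.
    """
    if not 0 < mass < 1:
        raise UserInputError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < math.ceil(1.0 / (1.0 - mass)):
        raise UserInputError(f"too few draws ({n}) for a {mass:.0%} HDI")
    k = math.ceil(mass * n)
    widths = x[k - 1 :] - x[: n - k + 1]
    start = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(x[start]), float(x[start + k - 1])


@dataclass
class ConvergenceReport:
    """Per-parameter split-Rhat values and the overall verdict for one fit."""

    rhat: dict[str, float]
    n_chains: int
    threshold: float = RHAT_THRESHOLD

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.n_chains >= MIN_CHAINS and self.max_rhat < self.threshold

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "threshold": self.threshold,
            "max_rhat": self.max_rhat,
            "converged": self.converged,
            "rhat": self.rhat,
        }


def check_convergence(
    posterior: PosteriorSamples, threshold: float = RHAT_THRESHOLD
) -> ConvergenceReport:
    """Split-Rhat for every scalar parameter plus the chains >= 3 rule."""
    rhats = {name: split_rhat(arr) for name, arr in posterior.flat()}
    return ConvergenceReport(rhat=rhats, n_chains=posterior.n_chains, threshold=threshold)


def significance_table(
    posteriors, mass: float = 0.95, threshold: float = RHAT_THRESHOLD
) -> pd.DataFrame:
    """Credible trait effects across a collection of fits.

    For each converged fit and each of the five trait coefficients in the
    Bernoulli and Beta parts, a row (Model, Impression, Area, Predictor,
    Mean, HDI_low, HDI_high) is emitted iff the ``mass`` HDI excludes zero.
    Non-converged fits are skipped with a logged warning.  Rows are sorted
    by (Model, Impression, Area, Predictor).
    """
    from .design import TRAITS

    rows = []
    for post in posteriors:
        report = check_convergence(post, threshold=threshold)
        scope = post.scope
        if not report.converged:
            logger.warning(
                "excluding non-converged fit %s (chains=%d, max Rhat=%.3f)",
                scope,
                report.n_chains,
                report.max_rhat,
            )
            continue
        for part in ("bern", "beta"):
            coefs = post.stacked(f"beta_{part}")  # (total_draws, 5)
            for k, trait in enumerate(TRAITS):
                lo, hi = hdi(coefs[:, k], mass=mass)
                if lo > 0 or hi < 0:
                    mean = float(coefs[:, k].mean())
                    if not lo <= mean <= hi:
                        logger.warning(
                            "posterior mean outside HDI for %s/%s (skewed posterior)",
                            scope,
                            trait,
                        )
                    rows.append(
                        (
                            MODEL_PART_LABELS[part],
                            scope.get("impression", ""),
                            scope.get("region", ""),
                            trait,
                            mean,
                            lo,
                            hi,
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=["Model", "Impression", "Area", "Predictor", "Mean", "HDI_low", "HDI_high"],
    )
    return table.sort_values(
        ["Model", "Impression", "Area", "Predictor"], kind="mergesort"
    ).reset_index(drop=True)
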