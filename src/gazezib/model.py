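"""Zero-inflated Beta (ZIB) hierarchical model of per-region gaze dwell.

The observation unit is the dwell weight G in [0, 1) that one trial left in
one facial region.  G is modelled as a mixture of a point mass at zero and a
Beta distribution on (0, 1):

    G ~ ZIB(q, a, b):   P(G = 0) = 1 - q;   G | G > 0 ~ Beta(a, b)

q (the probability of looking at the region at all) and the Beta mean mu
(how much attention the region received) are both logistic regressions on
the viewer's five Big Five trait scores P_1..P_5 (raw 1-7 scale), with
crossed random intercepts for participant and stimulus image:

    q  = logistic(alpha_bern + sum_k beta_bern_k P_k + r_subj + r_pic)
    mu = logistic(alpha_beta + sum_k beta_beta_k P_k + r_subj + r_pic)
    a = phi * mu,  b = phi * (1 - mu)

so the Beta part has mean mu and precision phi = a + b.  One such model is
fitted independently per (condition, impression item, region).

Priors: fixed effects ~ Normal(0, 10); random effects ~ Normal(0, sigma)
with each scale sigma ~ Gamma(10, 10); precision phi ~ Exponential(0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, log_expit

from .design import TRAITS, UserInputError

N_TRAITS = len(TRAITS)

#: Standard deviation of the Normal(0, sd) prior on intercepts and trait coefficients.
FIXED_EFFECT_PRIOR_SD = 10.0
#: Shape and rate of the Gamma prior on the four random-effect scales.
SIGMA_PRIOR_SHAPE = 10.0
SIGMA_PRIOR_RATE = 10.0
#: Rate of the Exponential prior on the Beta precision phi (mean 10, weakly informative).
PHI_PRIOR_RATE = 0.1


@dataclass
class ZIBParams:
    """Fixed effects, precision and random-effect scales of one ZIB model."""

    alpha_bern: float
    beta_bern: np.ndarray  # (5,) trait coefficients, logit scale
    alpha_beta: float
    beta_beta: np.ndarray  # (5,)
    phi: float
    sigma_subj_bern: float = 0.5
    sigma_pic_bern: float = 0.5
    sigma_subj_beta: float = 0.5
    sigma_pic_beta: float = 0.5

    def __post_init__(self) -> None:
        self.beta_bern = np.asarray(self.beta_bern, dtype=float)
        self.beta_beta = np.asarray(self.beta_beta, dtype=float)
        if self.beta_bern.shape != (N_TRAITS,) or self.beta_beta.shape != (N_TRAITS,):
            raise UserInputError(f"trait coefficient vectors must have length {N_TRAITS}")
        if not (
            np.isfinite(self.phi)
            and np.isfinite(self.alpha_bern)
            and np.isfinite(self.alpha_beta)
            and np.all(np.isfinite(self.beta_bern))
            and np.all(np.isfinite(self.beta_beta))
        ):
            raise UserInputError("ZIB parameters must be finite")
        if self.phi <= 0:
            raise UserInputError("phi must be > 0")
        for name in ("sigma_subj_bern", "sigma_pic_bern", "sigma_subj_beta", "sigma_pic_beta"):
            if getattr(self, name) <= 0:
                raise UserInputError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "alpha_bern": float(self.alpha_bern),
            "beta_bern": [float(v) for v in self.beta_bern],
            "alpha_beta": float(self.alpha_beta),
            "beta_beta": [float(v) for v in self.beta_beta],
            "phi": float(self.phi),
            "sigma_subj_bern": float(self.sigma_subj_bern),
            "sigma_pic_bern": float(self.sigma_pic_bern),
            "sigma_subj_beta": float(self.sigma_subj_beta),
            "sigma_pic_beta": float(self.sigma_pic_beta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZIBParams":
        return cls(**{k: (np.asarray(v) if k.startswith("beta_") else v) for k, v in d.items()})


@dataclass
class RandomEffects:
    """Realised random intercepts, indexed by participant and image id."""

    r_subj_bern: dict[str, float] = field(default_factory=dict)
    r_pic_bern: dict[str, float] = field(default_factory=dict)
    r_subj_beta: dict[str, float] = field(default_factory=dict)
    r_pic_beta: dict[str, float] = field(default_factory=dict)


def _linear_predictor(personality_row, alpha, beta, r_subj, r_pic):
    p = np.asarray(personality_row, dtype=float)
    if p.shape[-1] != N_TRAITS:
        raise UserInputError(f"personality row must have {N_TRAITS} trait scores")
    eta = alpha + p @ np.asarray(beta, dtype=float) + r_subj + r_pic
    if not np.all(np.isfinite(eta)):
        raise UserInputError("non-finite linear predictor")
    return eta


def link_q(personality_row, alpha_bern, beta_bern, r_subj=0.0, r_pic=0.0):
    """Probability q of directing any gaze at the region (Bernoulli part)."""
    return expit(_linear_predictor(personality_row, alpha_bern, beta_bern, r_subj, r_pic))


def link_mu(personality_row, alpha_beta, beta_beta, r_subj=0.0, r_pic=0.0):
    """Mean mu of the positive dwell weight (Beta part)."""
    return expit(_linear_predictor(personality_row, alpha_beta, beta_beta, r_subj, r_pic))


def beta_shapes(phi, mu):
    """Beta shape parameters (a, b) = (phi*mu, phi*(1-mu)); mean mu, precision phi."""
    phi = np.asarray(phi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(phi <= 0):
        raise UserInputError("phi must be > 0")
    if np.any((mu <= 0) | (mu >= 1)):
        raise UserInputError("mu must lie strictly inside (0, 1)")
    return phi * mu, phi * (1.0 - mu)


def _beta_logpdf(g, a, b):
    return (
        gammaln(a + b) - gammaln(a) - gammaln(b)
        + (a - 1.0) * np.log(g) + (b - 1.0) * np.log1p(-g)
    )


def zib_logpdf(g, q, a, b):
    """Log density of the zero-inflated Beta at g (point mass at 0, Beta on (0,1))."""
    g = np.asarray(g, dtype=float)
    if np.any((g < 0) | (g >= 1)):
        raise UserInputError("g must lie in [0, 1)")
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any((q <= 0) | (q >= 1)) or np.any(a <= 0) or np.any(b <= 0):
        raise UserInputError("require 0 < q < 1 and a, b > 0")
    zero = g == 0
    out = np.where(
        zero,
        np.log1p(-q),
        np.log(q) + _beta_logpdf(np.where(zero, 0.5, g), a, b),
    )
    return out if out.ndim else float(out)


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _normal_logpdf(x, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * (np.asarray(x) / sd) ** 2


class ModelData:
    """A (condition, impression, region) slice aligned for likelihood evaluation.

    Holds the dwell weights ``g``, the per-row 5-trait design matrix ``X`` and
    integer participant / image indices into the sorted unique id lists.
    """

    def __init__(self, data: pd.DataFrame, personality: pd.DataFrame):
        if len(data) == 0:
            raise UserInputError("empty data slice")
        required = {"participant_id", "image_id", "weight"}
        if not required.issubset(data.columns):
            raise UserInputError(f"data slice must contain columns {sorted(required)}")
        g = data["weight"].to_numpy(dtype=float)
        if np.any((g < 0) | (g >= 1)):
            raise UserInputError("weights must lie in [0, 1)")
        self.g = g
        pers = personality.set_index("participant_id")
        self.participants = sorted(data["participant_id"].unique())
        missing = [p for p in self.participants if p not in pers.index]
        if missing:
            raise UserInputError(f"participants without personality scores: {missing}")
        self.images = sorted(data["image_id"].unique())
        subj_pos = {p: i for i, p in enumerate(self.participants)}
        pic_pos = {p: i for i, p in enumerate(self.images)}
        self.i_subj = data["participant_id"].map(subj_pos).to_numpy(dtype=np.int64)
        self.j_pic = data["image_id"].map(pic_pos).to_numpy(dtype=np.int64)
        self.X = pers.loc[data["participant_id"], list(TRAITS)].to_numpy(dtype=float)

    @property
    def n_rows(self) -> int:
        return self.g.size

    @property
    def n_subj(self) -> int:
        return len(self.participants)

    @property
    def n_pic(self) -> int:
        return len(self.images)


def log_posterior(
    params: ZIBParams,
    effects: RandomEffects,
    data: pd.DataFrame,
    personality: pd.DataFrame,
) -> float:
    """Unnormalised log posterior density of one ZIB fit at the given state.

    ``data`` is a single (condition, impression, region) slice of a region
    weight table with columns participant_id, image_id, weight.  Vectorised;
    an independently coded summation oracle verifies it in the test suite.
    """
    if not isinstance(data, ModelData) and len(data) == 0:
        # prior-only evaluation: every random effect named in `effects` is
        # scored against its Normal(0, sigma) prior
        fixed = np.concatenate(
            [[params.alpha_bern], params.beta_bern, [params.alpha_beta], params.beta_beta]
        )
        lp = float(np.sum(_normal_logpdf(fixed, FIXED_EFFECT_PRIOR_SD)))
        lp += float(np.log(PHI_PRIOR_RATE) - PHI_PRIOR_RATE * params.phi)
        for sigma, r in (
            (params.sigma_subj_bern, list(effects.r_subj_bern.values())),
            (params.sigma_pic_bern, list(effects.r_pic_bern.values())),
            (params.sigma_subj_beta, list(effects.r_subj_beta.values())),
            (params.sigma_pic_beta, list(effects.r_pic_beta.values())),
        ):
            lp += float(_gamma_logpdf(sigma, SIGMA_PRIOR_SHAPE, SIGMA_PRIOR_RATE))
            lp += float(np.sum(_normal_logpdf(np.asarray(r, dtype=float), sigma)))
        return lp

    md = data if isinstance(data, ModelData) else ModelData(data, personality)

    r_sb = np.array([effects.r_subj_bern.get(p, 0.0) for p in md.participants])
    r_pb = np.array([effects.r_pic_bern.get(p, 0.0) for p in md.images])
    r_sB = np.array([effects.r_subj_beta.get(p, 0.0) for p in md.participants])
    r_pB = np.array([effects.r_pic_beta.get(p, 0.0) for p in md.images])

    eta_bern = (
        params.alpha_bern + md.X @ params.beta_bern + r_sb[md.i_subj] + r_pb[md.j_pic]
    )
    pos = md.g > 0
    ll = float(np.sum(np.where(pos, log_expit(eta_bern), log_expit(-eta_bern))))

    if pos.any():
        eta_beta = (
            params.alpha_beta
            + md.X[pos] @ params.beta_beta
            + r_sB[md.i_subj[pos]]
            + r_pB[md.j_pic[pos]]
        )
        mu = expit(eta_beta)
        a, b = beta_shapes(params.phi, np.clip(mu, 1e-12, 1 - 1e-12))
        ll += float(np.sum(_beta_logpdf(md.g[pos], a, b)))

    fixed = np.concatenate(
        [[params.alpha_bern], params.beta_bern, [params.alpha_beta], params.beta_beta]
    )
    lp = float(np.sum(_normal_logpdf(fixed, FIXED_EFFECT_PRIOR_SD)))
    lp += float(np.log(PHI_PRIOR_RATE) - PHI_PRIOR_RATE * params.phi)
    for sigma, r in (
        (params.sigma_subj_bern, r_sb),
        (params.sigma_pic_bern, r_pb),
        (params.sigma_subj_beta, r_sB),
        (params.sigma_pic_beta, r_pB),
    ):
        lp += float(_gamma_logpdf(sigma, SIGMA_PRIOR_SHAPE, SIGMA_PRIOR_RATE))
        lp += float(np.sum(_normal_logpdf(r, sigma)))
    return ll + lp
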