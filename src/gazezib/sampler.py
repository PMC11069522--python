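"""Hamiltonian Monte Carlo fitting of the ZIB hierarchical model.

The sampler targets the model's posterior on an unconstrained parameter
vector: precision and random-effect scales are log-transformed (with the
Jacobian included) and the crossed random intercepts use the non-centered
parameterisation r = sigma * u with u ~ Normal(0, 1), which removes the
funnel geometry between the scales and the effects.  Gradients are coded
analytically; no autodiff framework is involved.

Adaptation follows standard practice: dual-averaging step-size tuning toward
a target acceptance rate, with a diagonal mass matrix re-estimated from two
warmup windows.  Trajectory lengths are jittered uniformly up to ``max_leapfrog``
steps to avoid resonance.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, log_expit

from .design import TRAITS, UserInputError
from .model import (
    FIXED_EFFECT_PRIOR_SD,
    N_TRAITS,
    PHI_PRIOR_RATE,
    SIGMA_PRIOR_RATE,
    SIGMA_PRIOR_SHAPE,
    ModelData,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults give 4 chains x (2000 - 1000) = 4000 draws."""

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 32

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise UserInputError("chains must be >= 1")
        if not 0 <= self.warmup < self.iterations:
            raise UserInputError("require 0 <= warmup < iterations")
        if self.thin < 1:
            raise UserInputError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin

    def to_dict(self) -> dict:
        return {
            "chains": self.chains,
            "iterations": self.iterations,
            "warmup": self.warmup,
            "thin": self.thin,
            "seed": self.seed,
            "target_accept": self.target_accept,
            "max_leapfrog": self.max_leapfrog,
        }


@dataclass
class PosteriorSamples:
    """MCMC draws for one (condition, impression, region) fit.

    ``params`` maps parameter names to arrays shaped ``(chains, draws)`` or
    ``(chains, draws, k)`` for vector-valued parameters.  ``subjects`` and
    ``images`` give the id order of the random-effect axes.
    """

    params: dict[str, np.ndarray]
    scope: dict[str, str]
    config: MCMCConfig
    subjects: list[str]
    images: list[str]
    data_digest: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return next(iter(self.params.values())).shape[1]

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.n_draws

    def flat(self):
        """Yield (name, (chains, draws) array) for every scalar component."""
        for name, arr in self.params.items():
            if arr.ndim == 2:
                yield name, arr
            else:
                if name.startswith("beta_"):
                    labels = list(TRAITS)
                elif "subj" in name:
                    labels = self.subjects
                else:
                    labels = self.images
                for k in range(arr.shape[2]):
                    yield f"{name}[{labels[k]}]", arr[:, :, k]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (total_draws,) or (total_draws, k)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])


def _data_digest(md: ModelData) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(md.g).tobytes())
    h.update(np.ascontiguousarray(md.X).tobytes())
    h.update(np.ascontiguousarray(md.i_subj).tobytes())
    h.update(np.ascontiguousarray(md.j_pic).tobytes())
    return h.hexdigest()[:16]


class _Posterior:
    """Unconstrained-space log density and gradient for one ZIB fit.

    Layout of the parameter vector theta:
      [alpha_bern_c, beta_bern(5), alpha_beta_c, beta_beta(5), log phi,
       log sigma_subj_bern, log sigma_pic_bern, log sigma_subj_beta,
       log sigma_pic_beta, u_subj_bern(I), u_pic_bern(J),
       u_subj_beta(I), u_pic_beta(J)]

    Trait predictors are centered at the scale midpoint 4 inside the sampler
    (alpha_c = alpha + 4 * sum(beta)), which removes the strong posterior
    correlation between the raw-scale intercept and the coefficients; priors
    are still evaluated on the raw-scale intercept, so the target density is
    the same posterior under an exact linear change of variables.
    """

    CENTER = 4.0

    def __init__(self, md: ModelData):
        self.md = md
        self.I = md.n_subj
        self.J = md.n_pic
        self.pos = md.g > 0
        self.gp = md.g[self.pos]
        self.log_gp = np.log(self.gp)
        self.log1m_gp = np.log1p(-self.gp)
        self.Xc = md.X - self.CENTER
        self.Xp = self.Xc[self.pos]
        self.ip = md.i_subj[self.pos]
        self.jp = md.j_pic[self.pos]
        self.z = self.pos.astype(float)
        self.dim = 17 + 2 * (self.I + self.J)
        # normalisation constants of the Normal priors, so the density equals
        # the model's posterior under the change of variables exactly
        self.log_const = float(
            -12 * (np.log(FIXED_EFFECT_PRIOR_SD) + 0.5 * np.log(2 * np.pi))
            - (self.I + self.J) * np.log(2 * np.pi)
        )
        o = 17
        self.sl_usb = slice(o, o + self.I)
        self.sl_upb = slice(o + self.I, o + self.I + self.J)
        self.sl_usB = slice(o + self.I + self.J, o + 2 * self.I + self.J)
        self.sl_upB = slice(o + 2 * self.I + self.J, o + 2 * (self.I + self.J))

    def logp_grad(self, th: np.ndarray) -> tuple[float, np.ndarray]:
        # overflow in extreme proposals yields a non-finite lp, which the
        # sampler rejects; silence the transient warnings that produces
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(th)

    def _logp_grad(self, th: np.ndarray) -> tuple[float, np.ndarray]:
        md = self.md
        a_b, beta_b = th[0], th[1:6]
        a_B, beta_B = th[6], th[7:12]
        phi = np.exp(th[12])
        s_sb, s_pb, s_sB, s_pB = np.exp(th[13:17])
        u_sb = th[self.sl_usb]
        u_pb = th[self.sl_upb]
        u_sB = th[self.sl_usB]
        u_pB = th[self.sl_upB]

        grad = np.zeros_like(th)

        # Bernoulli part over all rows (centered design)
        eta_b = a_b + self.Xc @ beta_b + s_sb * u_sb[md.i_subj] + s_pb * u_pb[md.j_pic]
        lp = float(np.sum(np.where(self.pos, log_expit(eta_b), log_expit(-eta_b))))
        d_eta_b = self.z - expit(eta_b)
        grad[0] = d_eta_b.sum()
        grad[1:6] = self.Xc.T @ d_eta_b
        g_usb = s_sb * np.bincount(md.i_subj, weights=d_eta_b, minlength=self.I)
        g_upb = s_pb * np.bincount(md.j_pic, weights=d_eta_b, minlength=self.J)
        grad[13] += s_sb * float(np.dot(d_eta_b, u_sb[md.i_subj]))
        grad[14] += s_pb * float(np.dot(d_eta_b, u_pb[md.j_pic]))

        # Beta part over positive rows
        g_usB = np.zeros(self.I)
        g_upB = np.zeros(self.J)
        if self.gp.size:
            eta_B = a_B + self.Xp @ beta_B + s_sB * u_sB[self.ip] + s_pB * u_pB[self.jp]
            mu = expit(eta_B)
            mu = np.clip(mu, 1e-14, 1 - 1e-14)
            a = phi * mu
            b = phi - a
            lp += float(
                np.sum(
                    gammaln(phi) - gammaln(a) - gammaln(b)
                    + (a - 1.0) * self.log_gp + (b - 1.0) * self.log1m_gp
                )
            )
            dg_a = digamma(a)
            dg_b = digamma(b)
            d_mu = phi * ((self.log_gp - dg_a) - (self.log1m_gp - dg_b))
            d_eta_B = d_mu * mu * (1.0 - mu)
            grad[6] = d_eta_B.sum()
            grad[7:12] = self.Xp.T @ d_eta_B
            g_usB = s_sB * np.bincount(self.ip, weights=d_eta_B, minlength=self.I)
            g_upB = s_pB * np.bincount(self.jp, weights=d_eta_B, minlength=self.J)
            grad[15] += s_sB * float(np.dot(d_eta_B, u_sB[self.ip]))
            grad[16] += s_pB * float(np.dot(d_eta_B, u_pB[self.jp]))
            d_phi = float(
                np.sum(
                    digamma(phi) - mu * dg_a - (1.0 - mu) * dg_b
                    + mu * self.log_gp + (1.0 - mu) * self.log1m_gp
                )
            )
            grad[12] = d_phi * phi

        # Priors (Normal(0, 10) on the raw-scale intercepts and coefficients)
        sd2 = FIXED_EFFECT_PRIOR_SD**2
        c = self.CENTER
        alpha_raw_b = a_b - c * beta_b.sum()
        alpha_raw_B = a_B - c * beta_B.sum()
        lp += float(
            -0.5
            * (
                alpha_raw_b**2
                + alpha_raw_B**2
                + np.sum(beta_b**2)
                + np.sum(beta_B**2)
            )
            / sd2
        )
        grad[0] -= alpha_raw_b / sd2
        grad[1:6] += (c * alpha_raw_b - beta_b) / sd2
        grad[6] -= alpha_raw_B / sd2
        grad[7:12] += (c * alpha_raw_B - beta_B) / sd2

        # phi ~ Exponential(rate), plus log Jacobian of phi = exp(t)
        lp += float(np.log(PHI_PRIOR_RATE) - PHI_PRIOR_RATE * phi + th[12])
        grad[12] += 1.0 - PHI_PRIOR_RATE * phi

        # sigma ~ Gamma(shape, rate) with log Jacobian: shape*log(sigma) - rate*sigma
        sigmas = np.array([s_sb, s_pb, s_sB, s_pB])
        lp += float(
            np.sum(SIGMA_PRIOR_SHAPE * th[13:17] - SIGMA_PRIOR_RATE * sigmas)
            + 4 * (SIGMA_PRIOR_SHAPE * np.log(SIGMA_PRIOR_RATE) - gammaln(SIGMA_PRIOR_SHAPE))
        )
        grad[13:17] += SIGMA_PRIOR_SHAPE - SIGMA_PRIOR_RATE * sigmas

        # u ~ Normal(0, 1)
        for sl, g_u in (
            (self.sl_usb, g_usb),
            (self.sl_upb, g_upb),
            (self.sl_usB, g_usB),
            (self.sl_upB, g_upB),
        ):
            u = th[sl]
            lp += float(-0.5 * np.sum(u * u))
            grad[sl] = g_u - u

        lp += self.log_const
        if not np.isfinite(lp):
            return -np.inf, grad
        return lp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Overdispersed data-informed starting point for one chain."""
        th = np.zeros(self.dim)
        p_pos = float(np.clip(self.z.mean(), 0.05, 0.95))
        th[0] = np.log(p_pos / (1 - p_pos)) + rng.normal(0, 0.5)
        if self.gp.size:
            m = float(np.clip(self.gp.mean(), 0.02, 0.98))
            th[6] = np.log(m / (1 - m)) + rng.normal(0, 0.5)
        th[1:6] = rng.normal(0, 0.05, 5)
        th[7:12] = rng.normal(0, 0.05, 5)
        th[12] = np.log(10.0) + rng.normal(0, 0.3)
        th[13:17] = rng.normal(-0.2, 0.2, 4)
        th[17:] = rng.normal(0, 0.3, self.dim - 17)
        return th


def _find_initial_step(post, th, inv_mass, rng):
    eps = 0.1
    lp, grad = post.logp_grad(th)
    p = rng.normal(0, 1, th.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p * p * inv_mass)
    th1, p1, lp1 = _leapfrog(post, th, p, grad, eps, 1, inv_mass)[:3]
    h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        th1, p1, lp1 = _leapfrog(post, th, p, grad, eps, 1, inv_mass)[:3]
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        if direction == 1.0 and (h1 - h0) <= np.log(0.5):
            break
        if direction == -1.0 and (h1 - h0) > np.log(0.5):
            break
    return float(np.clip(eps, 1e-6, 1.0))


def _leapfrog(post, th, p, grad, eps, n_steps, inv_mass):
    th = th.copy()
    p = p + 0.5 * eps * grad
    lp = -np.inf
    for step in range(n_steps):
        th = th + eps * inv_mass * p
        lp, grad = post.logp_grad(th)
        if not np.isfinite(lp):
            return th, p, -np.inf, grad
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return th, p, lp, grad


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    mu: float
    target: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count**-self.kappa
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))


def _run_chain(post: _Posterior, cfg: MCMCConfig, rng: np.random.Generator) -> np.ndarray:
    th = post.initial_point(rng)
    lp, grad = post.logp_grad(th)
    if not np.isfinite(lp):
        th = np.zeros(post.dim)
        lp, grad = post.logp_grad(th)
    inv_mass = np.ones(post.dim)
    eps = _find_initial_step(post, th, inv_mass, rng)
    da = _DualAveraging(mu=np.log(10 * eps), target=cfg.target_accept)

    w = cfg.warmup
    # mass-matrix re-estimation checkpoints within warmup
    checkpoints = [int(0.5 * w), int(0.85 * w)] if w >= 200 else []
    window_draws: list[np.ndarray] = []

    retained = np.empty((cfg.retained_per_chain, post.dim))
    n_kept = 0
    for it in range(cfg.iterations):
        n_steps = int(rng.integers(1, cfg.max_leapfrog + 1))
        p0 = rng.normal(0, 1, post.dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(p0 * p0 * inv_mass)
        th1, p1, lp1, grad1 = _leapfrog(post, th, p0, grad, eps, n_steps, inv_mass)
        if np.isfinite(lp1):
            h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
            log_accept = min(0.0, h1 - h0)
            accept_prob = float(np.exp(log_accept))
        else:
            accept_prob = 0.0
            log_accept = -np.inf
        if np.log(rng.uniform()) < log_accept:
            th, lp, grad = th1, lp1, grad1

        if it < w:
            eps = da.update(accept_prob)
            if checkpoints:
                window_draws.append(th.copy())
                if it + 1 == checkpoints[0]:
                    draws = np.asarray(window_draws[len(window_draws) // 3 :])
                    if len(draws) >= 10:
                        var = draws.var(axis=0, ddof=1)
                        n = len(draws)
                        inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                        inv_mass = np.clip(inv_mass, 1e-8, 1e8)
                    window_draws = []
                    eps0 = float(np.exp(da.log_eps_bar)) if da.count else eps
                    da = _DualAveraging(mu=np.log(10 * eps0), target=cfg.target_accept)
                    eps = eps0
                    checkpoints.pop(0)
            if it + 1 == w:
                eps = float(np.exp(da.log_eps_bar)) if da.count else eps
        else:
            k = it - w
            if k % cfg.thin == 0 and n_kept < retained.shape[0]:
                retained[n_kept] = th
                n_kept += 1
    return retained[:n_kept]


def fit(
    data: pd.DataFrame,
    personality: pd.DataFrame,
    scope: tuple[str, str, str] | dict | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Fit the ZIB model to one (condition, impression, region) slice by HMC.

    ``data`` is a region weight table; when ``scope`` is given the table is
    filtered to that (condition, impression, region) triple first.  Returns
    ``chains x (iterations - warmup)/thin`` retained draws per parameter,
    reproducible under ``config.seed``.
    """
    config = config or MCMCConfig()
    if scope is not None:
        if isinstance(scope, dict):
            scope = (scope["condition"], scope["impression"], scope["region"])
        cond, impr, region = scope
        mask = np.ones(len(data), dtype=bool)
        for col, val in (("condition", cond), ("impression", impr), ("region", region)):
            if col in data.columns:
                mask &= (data[col] == val).to_numpy()
        data = data.loc[mask]
        scope_dict = {"condition": cond, "impression": impr, "region": region}
    else:
        scope_dict = {
            col: str(data[col].iloc[0]) if col in data.columns and len(data) else ""
            for col in ("condition", "impression", "region")
        }
    if len(data) == 0:
        raise UserInputError("no data in the requested scope")

    md = ModelData(data, personality)
    warnings: list[str] = []
    if not (md.g > 0).any():
        msg = "all weights in slice are zero; Beta part is prior-dominated"
        logger.warning(msg)
        warnings.append(msg)

    post = _Posterior(md)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [
        _run_chain(post, config, np.random.default_rng(s)) for s in seeds
    ]
    draws = np.stack(chains)  # (chains, retained, dim)

    I, J = md.n_subj, md.n_pic
    o = 17
    phi = np.exp(draws[:, :, 12])
    s_sb = np.exp(draws[:, :, 13])
    s_pb = np.exp(draws[:, :, 14])
    s_sB = np.exp(draws[:, :, 15])
    s_pB = np.exp(draws[:, :, 16])
    c = _Posterior.CENTER
    params = {
        "alpha_bern": draws[:, :, 0] - c * draws[:, :, 1:6].sum(axis=2),
        "beta_bern": draws[:, :, 1:6],
        "alpha_beta": draws[:, :, 6] - c * draws[:, :, 7:12].sum(axis=2),
        "beta_beta": draws[:, :, 7:12],
        "phi": phi,
        "sigma_subj_bern": s_sb,
        "sigma_pic_bern": s_pb,
        "sigma_subj_beta": s_sB,
        "sigma_pic_beta": s_pB,
        "r_subj_bern": s_sb[:, :, None] * draws[:, :, o : o + I],
        "r_pic_bern": s_pb[:, :, None] * draws[:, :, o + I : o + I + J],
        "r_subj_beta": s_sB[:, :, None] * draws[:, :, o + I + J : o + 2 * I + J],
        "r_pic_beta": s_pB[:, :, None] * draws[:, :, o + 2 * I + J :],
    }
    return PosteriorSamples(
        params=params,
        scope=scope_dict,
        config=config,
        subjects=list(md.participants),
        images=list(md.images),
        data_digest=_data_digest(md),
        warnings=warnings,
    )
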