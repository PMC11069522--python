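"""Likelihood, link and posterior-density correctness of the ZIB model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.special import expit

import gazezib as gz
from gazezib.design import TRAITS, UserInputError
from gazezib.model import RandomEffects, ZIBParams, log_posterior

MID = [4.0] * 5


def make_params(**kw) -> ZIBParams:
    base = dict(
        alpha_bern=0.0,
        beta_bern=np.zeros(5),
        alpha_beta=0.0,
        beta_beta=np.zeros(5),
        phi=10.0,
    )
    base.update(kw)
    return ZIBParams(**base)


class TestLinks:
    def test_zero_predictor_gives_half(self):
        assert gz.link_q([0, 0, 0, 0, 0], 0.0, np.zeros(5)) == pytest.approx(0.5)
        assert gz.link_mu([0, 0, 0, 0, 0], 0.0, np.zeros(5)) == pytest.approx(0.5)

    def test_single_coefficient_evaluation(self):
        # one unit of the openness score through a coefficient of 1.479
        beta = np.array([0, 0, 0, 0, 1.479])
        q = gz.link_q([0, 0, 0, 0, 1.0], 0.0, beta)
        assert q == pytest.approx(1 / (1 + np.exp(-1.479)))
        assert q == pytest.approx(0.8144, abs=1e-3)

    def test_monotone_in_positive_coefficient(self):
        beta = np.array([0.8, 0, 0, 0, 0])
        qs = [gz.link_q([p, 4, 4, 4, 4], -1.0, beta) for p in range(1, 8)]
        assert np.all(np.diff(qs) > 0)

    def test_logistic_symmetry(self):
        beta = np.array([0.3, -0.2, 0.1, 0.05, -0.4])
        mu_pos = gz.link_mu(MID, 1.2, beta)
        mu_neg = gz.link_mu(MID, -1.2 - 2 * (np.array(MID) @ beta), beta)
        assert mu_pos + mu_neg == pytest.approx(1.0)

    def test_extreme_predictor_saturates_without_underflow(self):
        mu = gz.link_mu(MID, -40.0, np.zeros(5))
        assert 0 < mu < 1e-15

    def test_random_effects_shift_the_predictor(self):
        q0 = gz.link_q(MID, 0.0, np.zeros(5))
        q1 = gz.link_q(MID, 0.0, np.zeros(5), r_subj=1.0, r_pic=0.5)
        assert q1 == pytest.approx(expit(1.5)) and q1 > q0

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(UserInputError):
            gz.link_q([np.inf, 4, 4, 4, 4], 0.0, np.ones(5))


class TestBetaShapes:
    @pytest.mark.parametrize(
        "phi,mu,expected",
        [(10.0, 0.3, (3.0, 7.0)), (1.0, 0.5, (0.5, 0.5)), (30.0, 0.12, (3.6, 26.4))],
    )
    def test_values(self, phi, mu, expected):
        a, b = gz.beta_shapes(phi, mu)
        assert (a, b) == pytest.approx(expected)

    @given(
        phi=st.floats(0.01, 1e4),
        mu=st.floats(1e-6, 1 - 1e-6),
    )
    @settings(max_examples=50, deadline=None)
    def test_mean_precision_identity(self, phi, mu):
        a, b = gz.beta_shapes(phi, mu)
        assert a / (a + b) == pytest.approx(mu, rel=1e-9)
        assert a + b == pytest.approx(phi, rel=1e-12)

    @pytest.mark.parametrize("phi,mu", [(0.0, 0.5), (-1.0, 0.5), (1.0, 0.0), (1.0, 1.0)])
    def test_invalid_params(self, phi, mu):
        with pytest.raises(UserInputError):
            gz.beta_shapes(phi, mu)


class TestZibLogpdf:
    def test_point_mass_branch(self):
        assert gz.zib_logpdf(0.0, 0.25, 1.0, 1.0) == pytest.approx(np.log(0.75))

    def test_uniform_beta_branch(self):
        assert gz.zib_logpdf(0.5, 0.5, 1.0, 1.0) == pytest.approx(np.log(0.5))

    def test_beta_branch_matches_scipy(self):
        g, q, a, b = 0.07, 0.6, 3.6, 26.4
        expected = np.log(q) + stats.beta.logpdf(g, a, b)
        assert gz.zib_logpdf(g, q, a, b) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "q,a,b",
        [(0.3, 2.0, 5.0), (0.7, 0.8, 0.9), (0.5, 1.0, 1.0), (0.9, 3.6, 26.4), (0.1, 5.0, 1.2)],
    )
    def test_total_mass_is_one(self, q, a, b):
        """Discrete zero mass plus the integral over (0,1) must equal 1."""
        integral, err = integrate.quad(
            lambda g: np.exp(gz.zib_logpdf(g, q, a, b)), 0, 1, limit=200, points=[0.0, 1.0]
        )
        assert (1 - q) + integral == pytest.approx(1.0, abs=max(1e-6, 10 * err))

    @pytest.mark.parametrize("g", [-0.1, 1.0, 1.5])
    def test_domain_errors(self, g):
        with pytest.raises(UserInputError):
            gz.zib_logpdf(g, 0.5, 1.0, 1.0)


def brute_force_log_posterior(params, effects, data, personality):
    """Independent re-implementation: pure-Python loops and scipy.stats."""
    pers = personality.set_index("participant_id")
    total = 0.0
    for _, row in data.iterrows():
        p = pers.loc[row["participant_id"], list(TRAITS)].to_numpy(dtype=float)
        eta_q = (
            params.alpha_bern
            + float(p @ params.beta_bern)
            + effects.r_subj_bern.get(row["participant_id"], 0.0)
            + effects.r_pic_bern.get(row["image_id"], 0.0)
        )
        q = 1.0 / (1.0 + np.exp(-eta_q))
        g = row["weight"]
        if g == 0:
            total += np.log(1 - q)
        else:
            eta_mu = (
                params.alpha_beta
                + float(p @ params.beta_beta)
                + effects.r_subj_beta.get(row["participant_id"], 0.0)
                + effects.r_pic_beta.get(row["image_id"], 0.0)
            )
            mu = 1.0 / (1.0 + np.exp(-eta_mu))
            total += np.log(q) + stats.beta.logpdf(g, params.phi * mu, params.phi * (1 - mu))
    for val in [params.alpha_bern, params.alpha_beta, *params.beta_bern, *params.beta_beta]:
        total += stats.norm.logpdf(val, 0, 10)
    total += stats.expon.logpdf(params.phi, scale=10.0)
    for sigma, r in [
        (params.sigma_subj_bern, effects.r_subj_bern),
        (params.sigma_pic_bern, effects.r_pic_bern),
        (params.sigma_subj_beta, effects.r_subj_beta),
        (params.sigma_pic_beta, effects.r_pic_beta),
    ]:
        total += stats.gamma.logpdf(sigma, 10, scale=1 / 10)
        for v in r.values():
            total += stats.norm.logpdf(v, 0, sigma)
    return total


@pytest.fixture()
def twenty_row_fixture(small_bundle):
    data = small_bundle.weights
    slice_ = data[
        (data.condition == "free") & (data.impression == "openness") & (data.region == "eyes")
    ].head(20)
    assert len(slice_) == 20
    rng = np.random.default_rng(5)
    params = make_params(
        alpha_bern=0.4,
        beta_bern=rng.normal(0, 0.2, 5),
        alpha_beta=-2.0,
        beta_beta=rng.normal(0, 0.1, 5),
        phi=25.0,
        sigma_subj_bern=0.7,
        sigma_pic_bern=0.4,
        sigma_subj_beta=0.9,
        sigma_pic_beta=0.6,
    )
    effects = RandomEffects(
        r_subj_bern={p: rng.normal(0, 0.5) for p in slice_["participant_id"].unique()},
        r_pic_bern={j: rng.normal(0, 0.5) for j in slice_["image_id"].unique()},
        r_subj_beta={p: rng.normal(0, 0.5) for p in slice_["participant_id"].unique()},
        r_pic_beta={j: rng.normal(0, 0.5) for j in slice_["image_id"].unique()},
    )
    return params, effects, slice_, small_bundle.personality


class TestLogPosterior:
    def test_matches_brute_force_oracle(self, twenty_row_fixture):
        params, effects, data, personality = twenty_row_fixture
        fast = log_posterior(params, effects, data, personality)
        slow = brute_force_log_posterior(params, effects, data, personality)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_additivity_of_duplicate_row(self, twenty_row_fixture):
        params, effects, data, personality = twenty_row_fixture
        base = log_posterior(params, effects, data, personality)
        row = data.iloc[[0]]
        extended = log_posterior(
            params, effects, pd.concat([data, row], ignore_index=True), personality
        )
        p = personality.set_index("participant_id").loc[
            row["participant_id"].iloc[0], list(TRAITS)
        ].to_numpy(dtype=float)
        q = gz.link_q(
            p,
            params.alpha_bern,
            params.beta_bern,
            effects.r_subj_bern[row["participant_id"].iloc[0]],
            effects.r_pic_bern[row["image_id"].iloc[0]],
        )
        g = row["weight"].iloc[0]
        if g == 0:
            contribution = np.log(1 - q)
        else:
            mu = gz.link_mu(
                p,
                params.alpha_beta,
                params.beta_beta,
                effects.r_subj_beta[row["participant_id"].iloc[0]],
                effects.r_pic_beta[row["image_id"].iloc[0]],
            )
            a, b = gz.beta_shapes(params.phi, mu)
            contribution = gz.zib_logpdf(g, q, a, b)
        assert extended - base == pytest.approx(float(contribution), abs=1e-9)

    def test_empty_slice_is_prior_only_and_finite(self, twenty_row_fixture):
        params, effects, data, personality = twenty_row_fixture
        empty = data.iloc[0:0]
        value = log_posterior(params, effects, empty, personality)
        assert np.isfinite(value)
        oracle = brute_force_log_posterior(params, effects, empty, personality)
        assert value == pytest.approx(oracle, abs=1e-8)

    def test_participant_relabeling_invariance(self, twenty_row_fixture):
        """Permuting participant ids together with their scores and effects
        leaves the posterior density unchanged."""
        params, effects, data, personality = twenty_row_fixture
        base = log_posterior(params, effects, data, personality)
        mapping = {p: f"relabel_{p}" for p in personality["participant_id"]}
        data2 = data.assign(participant_id=data["participant_id"].map(mapping))
        personality2 = personality.assign(
            participant_id=personality["participant_id"].map(mapping)
        )
        effects2 = RandomEffects(
            r_subj_bern={mapping[k]: v for k, v in effects.r_subj_bern.items()},
            r_pic_bern=dict(effects.r_pic_bern),
            r_subj_beta={mapping[k]: v for k, v in effects.r_subj_beta.items()},
            r_pic_beta=dict(effects.r_pic_beta),
        )
        assert log_posterior(params, effects2, data2, personality2) == pytest.approx(
            base, abs=1e-10
        )

    def test_out_of_support_weight_rejected(self, twenty_row_fixture):
        params, effects, data, personality = twenty_row_fixture
        bad = data.copy()
        bad.loc[bad.index[0], "weight"] = 1.0
        with pytest.raises(UserInputError):
            log_posterior(params, effects, bad, personality)
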