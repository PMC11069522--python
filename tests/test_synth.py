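"""Synthetic-experiment generator: design fidelity, determinism, distributions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import gazezib as gz
from gazezib.design import (
    APERTURE_NARROW,
    REGION_CODES,
    REGIONS,
    TRAITS,
    ExperimentConfig,
    TrialDesign,
    UserInputError,
)
from gazezib.model import ZIBParams


class TestGenerateParticipants:
    def test_full_cohort_shape_and_range(self):
        table = gz.generate_participants(42, seed=1)
        assert len(table) == 42
        assert list(table.columns) == ["participant_id", *TRAITS]
        scores = table[list(TRAITS)].to_numpy()
        assert scores.min() >= 1 and scores.max() <= 7
        assert table["participant_id"].is_unique

    def test_minimal_cohort(self):
        table = gz.generate_participants(1, seed=7)
        assert len(table) == 1 and table[list(TRAITS)].shape == (1, 5)

    def test_seeded_determinism(self):
        a = gz.generate_participants(10, seed=3)
        b = gz.generate_participants(10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_continuous_distribution_option(self):
        table = gz.generate_participants(50, seed=9, distribution="continuous-uniform")
        scores = table[list(TRAITS)].to_numpy()
        assert scores.min() >= 1 and scores.max() <= 7
        # continuous draws essentially never land on the integer grid
        assert not np.allclose(scores, np.round(scores))

    @pytest.mark.parametrize("n", [0, -3])
    def test_invalid_count(self, n):
        with pytest.raises(UserInputError):
            gz.generate_participants(n, seed=1)


class TestFaceLayout:
    def test_six_disjoint_nonempty_regions(self):
        masks = gz.generate_face_layout("img000", 412, 558, seed=3)
        areas = {r: masks.region_area(r) for r in REGIONS}
        assert all(a > 0 for a in areas.values())
        # one label per pixel means the region areas sum to the non-background count
        assert sum(areas.values()) == int(np.count_nonzero(masks.labels))

    def test_background_exists(self):
        masks = gz.generate_face_layout("img000", 412, 558, seed=3)
        assert sum(masks.region_area(r) for r in REGIONS) < 412 * 558

    def test_vertical_face_ordering(self):
        masks = gz.generate_face_layout("img001", 412, 558, seed=3)

        def mean_y(region):
            return masks.region_pixels(region)[:, 1].mean()

        assert mean_y("forehead") < mean_y("eyebrows") < mean_y("eyes")
        assert mean_y("eyes") < mean_y("nose") < mean_y("mouth")

    def test_distinct_images_get_jittered_layouts(self):
        a = gz.generate_face_layout("imgA", 412, 558, seed=3)
        b = gz.generate_face_layout("imgB", 412, 558, seed=3)
        assert not np.array_equal(a.labels, b.labels)

    def test_same_image_reproducible(self):
        a = gz.generate_face_layout("imgA", 412, 558, seed=3)
        b = gz.generate_face_layout("imgA", 412, 558, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_canvas_too_small(self):
        with pytest.raises(UserInputError):
            gz.generate_face_layout("imgA", 30, 40, seed=0)


def constant_params(q: float, mu: float = 0.5, phi: float = 2.0) -> ZIBParams:
    """Params whose links are constant at (q, mu) for the mid-scale profile."""
    eps = 1e-9
    q = min(max(q, eps), 1 - eps)
    return ZIBParams(
        alpha_bern=float(logit(q)),
        beta_bern=np.zeros(5),
        alpha_beta=float(logit(mu)),
        beta_beta=np.zeros(5),
        phi=phi,
    )


class TestSampleTrialWeights:
    MID = np.array([4.0] * 5)

    def test_degenerate_never_look(self, rng):
        w = gz.sample_trial_weights(constant_params(1e-12), self.MID, rng=rng)
        assert np.array_equal(w, np.zeros(6))

    def test_degenerate_always_look(self, rng):
        w = gz.sample_trial_weights(constant_params(1 - 1e-12, 0.5, 2.0), self.MID, rng=rng)
        assert np.all((w > 0) & (w < 1))

    def test_bernoulli_rate_recovered(self, rng):
        """Empirical nonzero fraction over 10^4 trials matches q within 3 MC SE."""
        q = 0.7
        params = constant_params(q, 0.3, 10.0)
        n = 10_000
        draws = np.array(
            [gz.sample_trial_weights(params, self.MID, rng=rng) for _ in range(n // 6)]
        ).ravel()
        phat = (draws > 0).mean()
        se = np.sqrt(q * (1 - q) / draws.size)
        assert abs(phat - q) <= 3 * se

    def test_beta_mean_recovered(self, rng):
        mu, phi = 0.3, 10.0
        params = constant_params(0.999999, mu, phi)
        draws = np.array(
            [gz.sample_trial_weights(params, self.MID, rng=rng) for _ in range(2000)]
        ).ravel()
        pos = draws[draws > 0]
        sd = np.sqrt(mu * (1 - mu) / (phi + 1))
        assert abs(pos.mean() - mu) <= 3 * sd / np.sqrt(pos.size)

    def test_effects_shift_rates(self, rng):
        params = constant_params(0.5, 0.5, 5.0)
        n = 4000
        hi = np.array(
            [
                gz.sample_trial_weights(params, self.MID, subject_effect=2.0, rng=rng)
                for _ in range(n // 6)
            ]
        ).ravel()
        assert (hi > 0).mean() > 0.8  # logistic(2) ~ 0.88


@pytest.fixture(scope="module")
def masks():
    return gz.generate_face_layout("img000", 412, 558, seed=3)


class TestGazeStream:
    def trial(self, condition="free"):
        return TrialDesign("p000", "img000", condition, "openness")

    def test_budget_is_duration_times_rate(self, masks):
        stream = gz.generate_gaze_stream(
            self.trial(), np.full(6, 0.1), masks, None, seed=1
        )
        assert len(stream.samples) == 360
        assert stream.trial.n_samples == 360

    def test_zero_weights_all_samples_off_face(self, masks):
        stream = gz.generate_gaze_stream(self.trial(), np.zeros(6), masks, None, seed=2)
        xy = stream.samples[["x", "y"]].to_numpy() - np.array([(1920 - 412) / 2, (1080 - 558) / 2])
        labels = masks.labels[
            np.clip(xy[:, 1].astype(int), 0, 557), np.clip(xy[:, 0].astype(int), 0, 411)
        ]
        assert np.all(labels == 0)

    def test_pure_eyes_allocation_lands_on_eyes(self, masks):
        stream = gz.generate_gaze_stream(
            self.trial(), np.array([1.0, 0, 0, 0, 0, 0]), masks, None, seed=3
        )
        xy = stream.samples[["x", "y"]].to_numpy() - np.array([(1920 - 412) / 2, (1080 - 558) / 2])
        labels = masks.labels[
            np.clip(xy[:, 1].astype(int), 0, 557), np.clip(xy[:, 0].astype(int), 0, 411)
        ]
        assert (labels == REGION_CODES["eyes"]).mean() >= 0.95

    def test_restricted_condition_uses_full_budget(self, masks):
        stream = gz.generate_gaze_stream(
            self.trial("restricted"), np.full(6, 0.12), masks, APERTURE_NARROW, seed=4
        )
        assert len(stream.samples) == 360
        t = stream.samples["t"].to_numpy()
        assert np.all(np.diff(t) > 0) and t[0] >= 0 and t[-1] <= 3.0

    def test_overfull_allocation_rejected(self, masks):
        with pytest.raises(UserInputError):
            gz.generate_gaze_stream(self.trial(), np.full(6, 0.2), masks, None, seed=5)

    def test_aperture_visibility_profile(self):
        ap = APERTURE_NARROW
        assert ap.visibility(0.0) == 1.0 and ap.visibility(40.0) == 1.0
        r = np.array([45.0, 60.0, 90.0, 40 + 3 * 40.0])
        v = ap.visibility(r)
        assert np.all(np.diff(v) < 0) and v[-1] < 0.02


class TestGenerateExperiment:
    def test_default_design_fifty_trials_per_condition(self):
        bundle = gz.generate_experiment(ExperimentConfig(n_participants=2), seed=1)
        per = (
            bundle.weights.drop_duplicates(
                ["participant_id", "image_id", "condition", "impression"]
            )
            .groupby(["participant_id", "condition"])
            .size()
        )
        assert (per == 50).all()

    def test_minimal_single_trial(self):
        cfg = ExperimentConfig(
            n_participants=1,
            images_per_impression=1,
            impressions=("openness",),
            conditions=("free",),
            trials_per_condition=1,
        )
        bundle = gz.generate_experiment(cfg, seed=1)
        assert len(bundle.weights) == 6  # one trial x six regions

    def test_seeded_determinism_bytes(self, small_bundle):
        again = gz.generate_experiment(small_bundle.config, seed=11)
        assert small_bundle.weights.to_csv(index=False) == again.weights.to_csv(index=False)

    def test_inconsistent_config_rejected(self):
        cfg = ExperimentConfig(images_per_impression=9)  # 9 x 5 != 50
        with pytest.raises(UserInputError):
            gz.generate_experiment(cfg, seed=1)

    def test_ground_truth_reproduces_weights(self, small_bundle):
        """The recorded ground truth round-trips to the same weight table."""
        truth = gz.GroundTruth.from_dict(small_bundle.truth.to_dict())
        again = gz.generate_experiment(
            small_bundle.config, seed=11, truth=truth.zib
        )
        pd.testing.assert_frame_equal(small_bundle.weights, again.weights)

    def test_null_effects_plants_zero_coefficients(self):
        cfg = ExperimentConfig(
            n_participants=2,
            images_per_impression=2,
            impressions=("openness",),
            conditions=("free",),
            trials_per_condition=2,
        )
        bundle = gz.generate_experiment(cfg, seed=5, null_effects=True)
        for params in bundle.truth.zib.values():
            assert np.all(params.beta_bern == 0) and np.all(params.beta_beta == 0)

    def test_weights_in_support(self, small_bundle):
        w = small_bundle.weights["weight"].to_numpy()
        assert w.min() >= 0 and w.max() < 1
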