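"""Acoustic standardization, factor retention/rotation, cue correlations."""

import numpy as np
import pandas as pd
import pytest

from _oracles import max_congruence
from vocalappraisal import acoustics as ac
from vocalappraisal import preprocessing as pp
from vocalappraisal.synthetic import (
    AcousticTruth,
    StudyDesign,
    TruthProfile,
    generate_acoustics,
    generate_ratings,
    generate_stimuli,
    orthogonal_factor_scores,
)


def feature_frame(X, speakers=None):
    n = X.shape[0]
    speakers = speakers or [f"spk{i // 4:02d}" for i in range(n)]
    df = pd.DataFrame({"stimulus_id": [f"s{i:03d}" for i in range(n)], "speaker_id": speakers})
    for j in range(X.shape[1]):
        df[f"cue_{j:02d}"] = X[:, j]
    return df


class TestZScoreBySpeaker:
    def test_two_point_speaker(self):
        df = feature_frame(np.array([[10.0], [20.0]]), speakers=["a", "a"])
        z = ac.zscore_by_speaker(df)
        assert np.allclose(sorted(z["cue_00"]), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_location_invariance_per_speaker(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        base = ac.zscore_by_speaker(feature_frame(X))
        shifted = X.copy()
        shifted[:4] += 100.0  # first speaker only
        moved = ac.zscore_by_speaker(feature_frame(shifted))
        pd.testing.assert_frame_equal(base, moved)

    def test_per_speaker_means_zero(self):
        rng = np.random.default_rng(1)
        z = ac.zscore_by_speaker(feature_frame(rng.normal(size=(20, 4))))
        means = z.groupby("speaker_id")[[f"cue_{j:02d}" for j in range(4)]].mean()
        assert np.allclose(means, 0, atol=1e-12)

    def test_singleton_speaker_rejected(self):
        df = feature_frame(np.ones((3, 1)), speakers=["a", "a", "b"])
        with pytest.raises(ValueError, match="b"):
            ac.zscore_by_speaker(df)

    def test_constant_cue_maps_to_zero_with_warning(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        with pytest.warns(UserWarning, match="constant"):
            z = ac.zscore_by_speaker(feature_frame(X))
        assert (z["cue_00"] == 0).all()


class TestParallelAnalysis:
    def test_pure_noise_retains_nothing(self):
        rng = np.random.default_rng(2)
        z = feature_frame(rng.normal(size=(300, 10)))
        assert ac.parallel_analysis(z, n_iterations=200, seed=0) == 0

    def test_three_strong_factors_retained(self):
        design = StudyDesign(n_listeners={"australia": 2, "india": 2}, seed=3)
        L = np.zeros((24, 3))
        L[np.arange(24), np.arange(24) % 3] = 0.9
        truth = AcousticTruth(
            n_cues=24, n_factors=3, loadings=L,
            factor_by_emotion=orthogonal_factor_scores(design.emotions, 3),
            cue_noise_sd=0.3,
        )
        feats = generate_acoustics(design, truth, seed=6)
        z = ac.zscore_by_speaker(feats)
        assert ac.parallel_analysis(z, n_iterations=300, seed=1) == 3

    def test_retained_count_non_increasing_in_quantile(self):
        rng = np.random.default_rng(4)
        latent = rng.normal(size=(100, 2))
        X = latent @ rng.normal(size=(2, 8)) * 0.6 + rng.normal(size=(100, 8)) * 0.8
        z = feature_frame(X)
        counts = [
            ac.parallel_analysis(z, n_iterations=200, quantile=q, seed=5)
            for q in (0.05, 0.5, 0.95, 0.999)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_zero_variance_cue_rejected(self):
        X = np.column_stack([np.ones(32), np.random.default_rng(0).normal(size=32)])
        with pytest.raises(ValueError, match="degenerate"):
            ac.parallel_analysis(feature_frame(X), n_iterations=10)


class TestVarimax:
    def test_rotation_preserves_communalities(self):
        rng = np.random.default_rng(6)
        L = rng.normal(size=(15, 4))
        Lr = ac.varimax(L)
        assert np.allclose((L**2).sum(axis=1), (Lr**2).sum(axis=1), atol=1e-9)

    def test_fixed_point_of_simple_structure(self):
        """A perfectly simple-structure matrix is already varimax-optimal."""
        L = np.zeros((12, 3))
        L[np.arange(12), np.arange(12) % 3] = 0.9
        Lr = ac.varimax(L)
        # allow column permutation / sign flips
        assert np.allclose(np.sort(np.abs(Lr).ravel()), np.sort(np.abs(L).ravel()), atol=1e-9)

    def test_recovers_generating_loadings(self):
        design = StudyDesign(n_listeners={"australia": 2, "india": 2}, seed=3)
        L = np.zeros((24, 3))
        L[np.arange(24), np.arange(24) % 3] = 0.9
        truth = AcousticTruth(
            n_cues=24, n_factors=3, loadings=L,
            factor_by_emotion=orthogonal_factor_scores(design.emotions, 3),
            cue_noise_sd=0.3,
        )
        z = ac.zscore_by_speaker(generate_acoustics(design, truth, seed=6))
        sol = ac.pca_varimax(z, 3)
        congruence = max_congruence(L, sol.rotated_loadings.to_numpy())
        assert (congruence > 0.95).all()

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(7)
        z = feature_frame(rng.normal(size=(60, 6)))
        sol = ac.pca_varimax(z, 2)
        L = sol.rotated_loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_n_factors_beyond_rank_rejected(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(20, 2))
        X = np.column_stack([base, base @ np.array([[1.0, 0.5], [0.5, 1.0]])])
        with pytest.raises(ValueError, match="rank"):
            ac.pca_varimax(feature_frame(X), 4)


@pytest.fixture(scope="module")
def z_ratings(effect_ratings):
    return pp.zscore_by_participant_dimension(effect_ratings)


class TestStimulusMeansAndCorrelations:
    def test_means_average_over_all_listeners(self, z_ratings, small_design):
        means = ac.stimulus_mean_ratings(z_ratings)
        assert (means["n_listeners"] == 12).all()
        assert len(means) == 128 * 6 * 2

    def test_listener_permutation_invariance(self, z_ratings):
        shuffled = z_ratings.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = ac.stimulus_mean_ratings(z_ratings).reset_index(drop=True)
        b = ac.stimulus_mean_ratings(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_uncovered_stimulus_rejected(self, z_ratings):
        pruned = z_ratings[
            ~((z_ratings.stimulus_id == z_ratings.stimulus_id.iloc[0])
              & (z_ratings.listener_culture == "india"))
        ]
        with pytest.raises(ValueError, match="coverage"):
            ac.stimulus_mean_ratings(pruned)

    def test_affine_copy_of_ratings_correlates_perfectly(self, z_ratings, small_design, effect_truth):
        stimuli = generate_stimuli(small_design, effect_truth)
        means = ac.stimulus_mean_ratings(z_ratings)
        urg = means[(means.dimension == "urgency") & (means.listener_culture == "india")]
        urg = urg.set_index("stimulus_id")["mean_rating"]
        feats = stimuli[["stimulus_id", "speaker_id"]].copy()
        feats["cue_00"] = (2.0 * urg.reindex(feats.stimulus_id)).to_numpy()
        feats["cue_01"] = (-1.0 * urg.reindex(feats.stimulus_id)).to_numpy()
        table = ac.correlate_cues(means, feats, ["cue_00", "cue_01"], stimuli)
        sub = table[(table.dimension == "urgency") & (table.listener_culture == "india")]
        assert np.allclose(sub[sub.cue == "cue_00"]["r"], 1.0)
        assert np.allclose(sub[sub.cue == "cue_01"]["r"], -1.0)
        assert (table["n"] == 64).all()

    def test_table_layout_covers_all_combinations(self, z_ratings, small_design, effect_truth):
        stimuli = generate_stimuli(small_design, effect_truth)
        rng = np.random.default_rng(9)
        feats = stimuli[["stimulus_id", "speaker_id"]].copy()
        for j in range(3):
            feats[f"cue_{j:02d}"] = rng.normal(size=len(feats))
        means = ac.stimulus_mean_ratings(z_ratings)
        table = ac.correlate_cues(means, feats, ["cue_00", "cue_01", "cue_02"], stimuli)
        assert len(table) == 3 * 6 * 2 * 2
        assert table["r"].abs().max() <= 1

    def test_zero_variance_cue_reports_nan(self, z_ratings, small_design, effect_truth):
        stimuli = generate_stimuli(small_design, effect_truth)
        feats = stimuli[["stimulus_id", "speaker_id"]].copy()
        feats["cue_00"] = 1.0
        means = ac.stimulus_mean_ratings(z_ratings)
        table = ac.correlate_cues(means, feats, ["cue_00"], stimuli)
        assert table["r"].isna().all()

    def test_injected_correlation_recovered(self):
        """A cue built as 0.6-correlated with urgency latents is recovered
        within sampling error at 64 stimuli per speaker culture."""
        design = StudyDesign(n_listeners={"australia": 40, "india": 40}, seed=55)
        truth = TruthProfile(stimulus_effect_sd=0.8)
        stimuli = generate_stimuli(design, truth)
        sd = truth.stimulus_effect_sd
        target_r = 0.6
        coef = 1.0
        noise_sd = coef * sd * np.sqrt(1 / target_r**2 - 1)
        at = AcousticTruth(
            n_cues=2, n_factors=1, loadings=np.zeros((2, 1)),
            cue_noise_sd=noise_sd, speaker_baseline_sd=0.0,
            appraisal_links={"cue_01": ("urgency", coef)},
        )
        feats = generate_acoustics(design, at, seed=13, stimuli=stimuli)
        merged = feats.merge(
            stimuli[["stimulus_id", "speaker_culture", "latent_urgency"]], on="stimulus_id"
        )
        r_latent_pooled = np.corrcoef(merged["latent_urgency"], merged["cue_01"])[0, 1]
        # the injection hits the population target up to sampling error
        assert r_latent_pooled == pytest.approx(target_r, abs=0.15)
        ratings = generate_ratings(design, truth)
        z = pp.zscore_by_participant_dimension(ratings)
        means = ac.stimulus_mean_ratings(z)
        table = ac.correlate_cues(means, feats, ["cue_01"], stimuli)
        # recovery check: rating-based r tracks the realized cue-latent r
        # within each 64-stimulus speaker culture (mild attenuation from
        # rating noise and 1-5 discretization)
        for sc, grp in merged.groupby("speaker_culture"):
            r_true = np.corrcoef(grp["latent_urgency"], grp["cue_01"])[0, 1]
            sub = table[(table.dimension == "urgency") & (table.speaker_culture == sc)]
            assert np.allclose(sub["r"], r_true, atol=0.15)
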