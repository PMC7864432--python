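"""Feature assembly, PCA truncation, bootstrap/LOO LDA, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest

import rseeg
from rseeg.classifier import (
    assign_quadrants, auc, bootstrap_loo_evaluate, build_features,
    pca_reduce, posterior_probability,
)


def gaussian_features(rng, n_per_class=10, n_feat=12, sep=0.0):
    """Two-class Gaussian feature matrix with mean separation ``sep`` SD."""
    X = rng.standard_normal((2 * n_per_class, n_feat))
    X[:n_per_class, :4] += sep
    idx = [f"S{i:02d}" for i in range(2 * n_per_class)]
    labels = pd.Series(
        ["case"] * n_per_class + ["ctrl"] * n_per_class, index=idx
    )
    return pd.DataFrame(X, index=idx), labels


class TestAuc:
    def test_hand_worked_three_of_four_concordant(self):
        assert auc([0.9, 0.8], [0.7, 0.85]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.9, 0.95], [0.1, 0.2]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestPca:
    def test_rank_two_data_needs_two_components(self, rng):
        basis_vecs = rng.standard_normal((2, 30))
        coeff = rng.standard_normal((15, 2))
        X = coeff @ basis_vecs
        _, basis = pca_reduce(X, 0.98)
        assert basis.n_components == 2

    def test_full_rank_near_one_threshold_keeps_n_minus_1(self, rng):
        X = rng.standard_normal((8, 20))
        _, basis = pca_reduce(X, 1.0 - 1e-12)
        assert basis.n_components == 7

    def test_retained_variance_meets_threshold(self, rng):
        X = rng.standard_normal((25, 10)) * np.linspace(3, 0.1, 10)
        _, basis = pca_reduce(X, 0.98)
        assert basis.explained_variance_fraction >= 0.98

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((2, 5)))


class TestBuildFeatures:
    @pytest.fixture(scope="class")
    def small_epms(self, montage):
        epms = {}
        for i, sid in enumerate(["A", "B"]):
            s = rseeg.generate_subject(
                rseeg.healthy_profile(), montage, duration_s=30.0, seed=60 + i
            )
            epms[sid] = rseeg.epoch_psd(s)
        return epms

    def test_default_layout_has_1530_features(self, small_epms, montage):
        fm = build_features(small_epms, montage)
        assert fm.shape == (2, 1530)  # 30 locations x (40 bins + 11 bands)

    def test_identical_subjects_give_identical_rows(self, small_epms, montage):
        epms = {"X": small_epms["A"], "Y": small_epms["A"]}
        fm = build_features(epms, montage)
        assert np.array_equal(fm.loc["X"].values, fm.loc["Y"].values)

    def test_region_feature_is_mean_of_member_channels(self, small_epms, montage):
        fm = build_features(small_epms, montage)
        members = montage.regions()["temporal_left"]  # T3, T5
        got = fm.loc["A", "temporal_left_bin10"]
        expect = np.mean([fm.loc["A", f"{m}_bin10"] for m in members])
        assert got == pytest.approx(expect)


class TestBootstrapLoo:
    def test_separable_classes_reach_high_auc(self, rng):
        X, y = gaussian_features(rng, sep=4.0)
        art = bootstrap_loo_evaluate(X, y, "case", "ctrl",
                                     n_iterations=30, seed=0)
        assert art.auc >= 0.95
        assert art.accuracy > 0.9

    def test_deterministic_given_seed(self, rng):
        X, y = gaussian_features(rng, sep=1.0)
        a = bootstrap_loo_evaluate(X, y, "case", "ctrl", n_iterations=20, seed=3)
        b = bootstrap_loo_evaluate(X, y, "case", "ctrl", n_iterations=20, seed=3)
        assert a.auc == b.auc
        assert np.array_equal(a.coef, b.coef)
        assert np.array_equal(a.mean_tpr, b.mean_tpr)

    def test_balanced_undersampling_uses_every_minority_subject(self, rng):
        X = pd.DataFrame(rng.standard_normal((18, 6)),
                         index=[f"S{i}" for i in range(18)])
        y = pd.Series(["case"] * 6 + ["ctrl"] * 12, index=X.index)
        art = bootstrap_loo_evaluate(X, y, "case", "ctrl",
                                     n_iterations=10, seed=1)
        # every minority (case) subject received a LOO posterior each time
        assert (art.per_subject_posterior.index[:6] == X.index[:6]).all()

    def test_small_class_rejected(self, rng):
        X, y = gaussian_features(rng, n_per_class=4)
        with pytest.raises(ValueError, match="at least 5"):
            bootstrap_loo_evaluate(X, y, "case", "ctrl")

    def test_apparent_auc_at_least_cross_validated(self, rng):
        """Training-set ROC dominates the LOO ROC (optimism) across
        twenty simulated feature sets of moderate signal."""
        for k in range(20):
            X, y = gaussian_features(rng, n_per_class=8, sep=1.0)
            art = bootstrap_loo_evaluate(X, y, "case", "ctrl",
                                         n_iterations=15, seed=k)
            assert art.apparent_auc >= art.auc


class TestPosterior:
    def test_posteriors_of_the_two_classes_sum_to_one(self, rng):
        X, y = gaussian_features(rng, sep=2.0)
        art = bootstrap_loo_evaluate(X, y, "case", "ctrl",
                                     n_iterations=10, seed=0)
        p_case = posterior_probability(art, X)
        # the control-class posterior is the complement by construction
        assert ((p_case >= 0) & (p_case <= 1)).all()
        z = art.pca.transform(X.to_numpy())
        from rseeg.classifier import _posterior

        p_again = _posterior(art.coef, art.intercept, z)
        assert np.allclose(p_case.values + (1 - p_again), 1.0)

    def test_control_centroid_scores_below_half(self, rng):
        X, y = gaussian_features(rng, sep=3.0)
        art = bootstrap_loo_evaluate(X, y, "case", "ctrl",
                                     n_iterations=10, seed=0)
        centroid = X[y == "ctrl"].mean().to_frame().T
        assert posterior_probability(art, centroid).iloc[0] < 0.5

    def test_feature_layout_mismatch_rejected(self, rng):
        X, y = gaussian_features(rng)
        art = bootstrap_loo_evaluate(X, y, "case", "ctrl",
                                     n_iterations=5, seed=0)
        with pytest.raises(ValueError, match="layout mismatch"):
            posterior_probability(art, X.iloc[:, :-1])

    def test_artifact_json_round_trip(self, rng):
        from rseeg.classifier import ClassifierArtifact

        X, y = gaussian_features(rng, sep=1.5)
        art = bootstrap_loo_evaluate(X, y, "case", "ctrl",
                                     n_iterations=5, seed=0)
        art2 = ClassifierArtifact.from_dict(art.to_dict())
        p1 = posterior_probability(art, X)
        p2 = posterior_probability(art2, X)
        assert np.allclose(p1.values, p2.values)

    def test_quadrant_assignment_convention(self):
        p_mci = pd.Series({"a": 0.2, "b": 0.8, "c": 0.9, "d": 0.1})
        p_ad = pd.Series({"a": 0.1, "b": 0.2, "c": 0.9, "d": 0.7})
        q = assign_quadrants(p_mci, p_ad)
        assert q.to_dict() == {"a": "Q2", "b": "Q3", "c": "Q4", "d": "Q1"}
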