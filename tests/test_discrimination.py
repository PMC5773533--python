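"""Clustering score, strain classifier, PCA ellipsoids and overlap."""

from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import actistate as a
from actistate.discrimination import (
    ClassifierResult,
    StrainEllipsoid,
    all_pairwise_scores,
    overlap_matrix,
)


def score_oracle(T, L):
    """Direct Counter-based evaluation of S_in, S_out, S."""
    t = len(T)
    I = sum(
        max(Counter(l for tt, l in zip(T, L) if tt == g).values(), default=0)
        for g in (1, 2)
    )
    O = sum(
        max(Counter(tt for tt, l in zip(T, L) if l == g).values(), default=0)
        for g in (1, 2)
    )
    return (I / t + O / t) / 2


class TestClusteringScore:
    def test_perfect_separation_scores_one(self):
        for T in ([1, 1, 2, 2], [1, 2, 1, 2, 2]):
            assert a.clustering_score(T, T)["S"] == 1.0

    def test_worked_example(self):
        out = a.clustering_score([1, 1, 2, 2], [1, 2, 2, 2])
        assert out["S_in"] == 0.75 and out["S_out"] == 0.75 and out["S"] == 0.75

    def test_matches_enumeration_oracle_exhaustively(self):
        T = [1, 1, 1, 2, 2, 2]
        for L in product((1, 2), repeat=6):
            assert a.clustering_score(T, list(L))["S"] == score_oracle(T, list(L))

    @given(st.lists(st.sampled_from([1, 2]), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_under_group_relabeling(self, L):
        T = [1 if i < len(L) // 2 else 2 for i in range(len(L))]
        s1 = a.clustering_score(T, L)["S"]
        s2 = a.clustering_score(T, [3 - l for l in L])["S"]
        assert s1 == s2
        assert 0.0 <= s1 <= 1.0

    def test_random_labels_approach_half(self):
        rng = np.random.default_rng(0)
        T = np.repeat([1, 2], 5000)
        scores = [
            a.clustering_score(T, rng.integers(1, 3, size=10000))["S"] for _ in range(50)
        ]
        assert abs(np.mean(scores) - 0.5) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            a.clustering_score([1, 2], [1, 2, 2])


def labelled_blobs(centers, n_mice, days, noise, seed, dim=11):
    rng = np.random.default_rng(seed)
    X, strains, mice = [], [], []
    for s, c in enumerate(centers):
        for m in range(n_mice):
            for d in range(days):
                X.append(np.asarray(c, float) + rng.normal(0, noise, dim))
                strains.append(f"S{s}")
                mice.append(f"S{s}m{m}")
    return np.asarray(X), np.asarray(strains), np.asarray(mice)


class TestPairwiseClustering:
    def test_separable_strains_score_one(self):
        X, strains, mice = labelled_blobs(
            [np.zeros(11), np.full(11, 5.0)], n_mice=3, days=4, noise=0.1, seed=1
        )
        res = a.pairwise_cluster_accuracy(X, strains, mice, trials=5, seed=2)
        assert res.test_mean == 1.0 and res.train_mean == 1.0

    def test_exchangeable_strains_score_near_chance(self):
        X, strains, mice = labelled_blobs(
            [np.zeros(11), np.zeros(11)], n_mice=4, days=6, noise=1.0, seed=3
        )
        res = a.pairwise_cluster_accuracy(X, strains, mice, trials=10, seed=4)
        assert 0.45 <= res.test_mean <= 0.80  # exchangeability band

    def test_needs_exactly_two_strains(self):
        X, strains, mice = labelled_blobs([np.zeros(11)], 3, 4, 0.1, 0)
        with pytest.raises(ValueError):
            a.pairwise_cluster_accuracy(X, strains, mice)

    def test_all_pairs_enumerated(self):
        X, strains, mice = labelled_blobs(
            [np.zeros(11), np.full(11, 3.0), np.full(11, -3.0)], 2, 4, 0.2, 5
        )
        table = all_pairwise_scores(X, strains, mice, trials=3, seed=6)
        assert len(table) == 3  # C(3, 2)


class TestStrainClassifier:
    def test_exchangeable_strains_near_half(self):
        X, strains, mice = labelled_blobs(
            [np.zeros(11), np.zeros(11)], n_mice=6, days=6, noise=1.0, seed=7
        )
        res = a.strain_classifier(X, strains, mice, trials=10, seed=8)
        assert isinstance(res, ClassifierResult)
        assert 0.30 <= res.md_mean <= 0.70
        assert 0.25 <= res.mouse_mean <= 0.75

    def test_separable_strains_classified(self):
        X, strains, mice = labelled_blobs(
            [np.zeros(11), np.full(11, 4.0), np.full(11, -4.0)], 4, 4, 0.3, 9
        )
        res = a.strain_classifier(X, strains, mice, trials=5, seed=10)
        assert res.md_mean > 0.95 and res.mouse_mean > 0.95

    def test_single_strain_rejected(self):
        X, strains, mice = labelled_blobs([np.zeros(11)], 4, 4, 0.3, 11)
        with pytest.raises(ValueError):
            a.strain_classifier(X, strains, mice)

    def test_too_few_days_for_split_rejected(self):
        X, strains, mice = labelled_blobs([np.zeros(11), np.ones(11)], 3, 1, 0.3, 12)
        with pytest.raises(ValueError):
            a.strain_classifier(X, strains, mice, trials=2, seed=0)


class TestPCA:
    def test_projected_columns_have_unit_variance(self):
        rng = np.random.default_rng(13)
        M = rng.normal(size=(40, 11)) * np.linspace(3, 0.5, 11)
        model = a.pca_projection(M)
        assert np.allclose(model.projected.var(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_reconstruction_from_full_projection(self):
        rng = np.random.default_rng(14)
        M = rng.normal(size=(30, 8))
        model = a.pca_projection(M)
        Mc = M - M.mean(axis=0)
        N = model.full_projection(Mc)
        back = N @ np.diag(np.sqrt(model.eigenvalues)) @ model.eigenvectors.T
        assert np.allclose(back, Mc, atol=1e-8)

    def test_axis_aligned_data_recovers_dominant_axis(self):
        rng = np.random.default_rng(15)
        scales = np.array([2.0, 1.0, 0.5, 0.25, 0.1])
        M = rng.normal(size=(5000, 5)) * scales
        model = a.pca_projection(M)
        lead = np.abs(model.eigenvectors[:, 0])
        assert lead[0] > 0.99
        trace = model.eigenvalues.sum()
        assert abs(model.explained_fraction - model.eigenvalues[:3].sum() / trace) < 1e-12

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(16)
        M = rng.normal(size=(20, 5))
        M[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = a.pca_projection(M)
        assert len(model.kept_features) == 4

    def test_too_few_mice_rejected(self):
        with pytest.raises(ValueError):
            a.pca_projection(np.zeros((3, 11)))


class TestEllipsoids:
    def test_per_strain_center_and_axes(self):
        rng = np.random.default_rng(17)
        M = np.vstack([rng.normal(-2, 1, (30, 11)), rng.normal(2, 1, (30, 11))])
        labels = ["A"] * 30 + ["B"] * 30
        model = a.pca_projection(M)
        ells = a.strain_ellipsoids(model, labels)
        assert [e.label for e in ells] == ["A", "B"]
        ca, cb = np.array(ells[0].center), np.array(ells[1].center)
        assert np.allclose(ca, -cb, atol=0.3)  # symmetric groups project symmetrically

    def test_identical_mice_strain_is_an_error(self):
        model = a.pca_projection(np.random.default_rng(18).normal(size=(20, 5)))
        labels = ["A"] * 2 + ["B"] * 18
        model.projected[:2] = model.projected[0]  # strain A collapses to a point
        with pytest.raises(ValueError):
            a.strain_ellipsoids(model, labels)

    def test_overlap_of_identical_ellipsoids_is_one(self):
        e = StrainEllipsoid("A", (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        f = StrainEllipsoid("B", (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        assert a.ellipsoid_overlap(e, f, n_points=2000, seed=0) == 1.0

    def test_contained_ellipsoid_fully_overlaps(self):
        small = StrainEllipsoid("w", (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        big = StrainEllipsoid("v", (0.0, 0.0, 0.0), (3.0, 3.0, 3.0))
        assert a.ellipsoid_overlap(small, big, n_points=4000, seed=1) == 1.0

    def test_disjoint_ellipsoids_do_not_overlap(self):
        e = StrainEllipsoid("A", (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        f = StrainEllipsoid("B", (10.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        assert a.ellipsoid_overlap(e, f, n_points=4000, seed=2) == 0.0

    def test_unit_sphere_lens_closed_form(self):
        # two unit spheres with centers 1 apart: overlap = 5/16
        e = StrainEllipsoid("A", (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        f = StrainEllipsoid("B", (1.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        n = 10000
        est = a.ellipsoid_overlap(e, f, n_points=n, seed=3)
        hits = n * np.pi / 6  # expected points inside the sampled sphere
        mc_sd = np.sqrt(5 / 16 * (1 - 5 / 16) / hits)
        assert abs(est - 5 / 16) <= 3 * mc_sd

    def test_overlap_matrix_symmetric_unit_diagonal(self):
        ells = [
            StrainEllipsoid("A", (0.0, 0.0, 0.0), (1.0, 1.0, 1.0)),
            StrainEllipsoid("B", (0.5, 0.0, 0.0), (1.0, 1.0, 1.0)),
            StrainEllipsoid("C", (9.0, 9.0, 9.0), (1.0, 1.0, 1.0)),
        ]
        m = overlap_matrix(ells, n_points=2000, seed=4)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            StrainEllipsoid("A", (0.0, 0.0, 0.0), (1.0, 0.0, 1.0))
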