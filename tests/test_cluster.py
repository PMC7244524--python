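"""Sample QC, hierarchical clustering vs a brute-force agglomerator,
profile scaling, PCA reconstruction and SOTA behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lfqdiff.cluster import (
    flag_outlier_samples,
    hierarchical_cluster,
    pca_scores,
    scale_profiles,
    sota_cluster,
)
from lfqdiff.simulate import SimulationTruth, simulate_peptide_intensities


class TestFlagOutliers:
    def make_table(self, design, shift_sample=None, shift=0.0, seed=0):
        truth = SimulationTruth(sigma_theta=0.05, sigma_eps=0.1, seed=seed)
        tab = simulate_peptide_intensities(truth, design, 30, 3)
        if shift_sample:
            mask = tab["sample_id"] == shift_sample
            tab.loc[mask, "log10_intensity"] += shift
        return tab

    def test_no_flags_when_homogeneous(self, design):
        tab = self.make_table(design)
        out = flag_outlier_samples(tab, design, min_peptides=1)
        assert not out["flagged"].any()

    def test_shifted_sample_flagged(self, design):
        sid = design["sample_id"].iloc[0]
        tab = self.make_table(design, shift_sample=sid, shift=3.0)
        out = flag_outlier_samples(tab, design, min_peptides=1)
        flagged = set(out.loc[out["flagged"], "sample_id"])
        assert sid in flagged

    def test_low_count_flagged(self, design):
        tab = self.make_table(design)
        sid = design["sample_id"].iloc[5]
        thin = tab[~((tab.sample_id == sid) & (tab.peptide != "P01_pep1"))]
        out = flag_outlier_samples(thin, design, min_peptides=10, pca_sd_mult=1e9)
        row = out[out.sample_id == sid].iloc[0]
        assert row["flag_low_count"] and row["flagged"]


def brute_force_agglomerate(X, method="complete"):
    """O(n^3) reference agglomerator; returns merge heights and the
    partition sequence (as sets of frozensets)."""
    clusters = {i: frozenset([i]) for i in range(len(X))}
    partitions = [set(clusters.values())]
    heights = []

    def dist(a, b):
        pair = [
            np.linalg.norm(X[i] - X[j]) for i in a for j in b
        ]
        if method == "complete":
            return max(pair)
        if method == "single":
            return min(pair)
        if method == "average":
            return float(np.mean(pair))
        raise ValueError(method)

    while len(clusters) > 1:
        keys = list(clusters)
        best = min(
            itertools.combinations(keys, 2),
            key=lambda ab: (dist(clusters[ab[0]], clusters[ab[1]]), ab),
        )
        h = dist(clusters[best[0]], clusters[best[1]])
        heights.append(h)
        merged = clusters[best[0]] | clusters[best[1]]
        del clusters[best[0]], clusters[best[1]]
        clusters[max(keys) + 1] = merged
        partitions.append(set(clusters.values()))
    return heights, partitions


def replay_partitions(Z, n):
    """Partition sequence implied by a linkage matrix."""
    clusters = {i: frozenset([i]) for i in range(n)}
    parts = [set(clusters.values())]
    for row_idx, (a, b, _h, _c) in enumerate(Z):
        merged = clusters.pop(int(a)) | clusters.pop(int(b))
        clusters[n + row_idx] = merged
        parts.append(set(clusters.values()))
    return parts


class TestHierarchical:
    def test_identical_rows_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = hierarchical_cluster(X, n_clusters=2)
        assert res.linkage[0, 2] == 0.0
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_line_example_matches_brute_force(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        res = hierarchical_cluster(X, method="complete")
        heights, _parts = brute_force_agglomerate(X, "complete")
        np.testing.assert_allclose(sorted(res.linkage[:, 2]), sorted(heights))
        # first merge must be one of the tied unit-distance pairs
        first = replay_partitions(res.linkage, len(X))[1]
        assert frozenset({0, 1}) in first or frozenset({3, 4}) in first

    @pytest.mark.parametrize("method", ["complete", "single", "average"])
    def test_random_instances_match_brute_force(self, method):
        rng = np.random.default_rng(7)
        for n in (4, 6, 8):
            for _ in range(5):
                X = rng.normal(size=(n, 3))
                res = hierarchical_cluster(X, method=method)
                heights, parts = brute_force_agglomerate(X, method)
                np.testing.assert_allclose(
                    sorted(res.linkage[:, 2]), sorted(heights), rtol=1e-10
                )
                assert replay_partitions(res.linkage, n) == parts

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[1.0, 2.0]]))

    def test_labels_contiguous(self):
        rng = np.random.default_rng(1)
        res = hierarchical_cluster(rng.normal(size=(10, 4)), n_clusters=3)
        assert sorted(set(res.labels)) == [1, 2, 3]


class TestScaleProfiles:
    def test_zscore_arithmetic(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=list("abc"))
        z = scale_profiles(m)
        np.testing.assert_allclose(z.loc["p"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_row_dropped(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"], columns=list("abc")
        )
        z = scale_profiles(m)
        assert list(z.index) == ["ok"]

    def test_rows_centered(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(20, 6)))
        z = scale_profiles(m)
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=0) - 1).max() < 1e-12


def test_pca_full_rank_reconstruction():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 7))
    scores, loadings, _ = pca_scores(X)
    recon = scores @ loadings + X.mean(axis=0, keepdims=True)
    assert np.abs(recon - X).max() < 1e-8


def rand_index(a, b):
    from itertools import combinations

    pairs = list(combinations(range(len(a)), 2))
    agree = sum(
        1 for i, j in pairs if (a[i] == a[j]) == (b[i] == b[j])
    )
    return agree / len(pairs)


class TestSota:
    def make_two_groups(self, seed=0):
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0, 0.1, size=(20, 6)) + np.array([1, 1, 1, -1, -1, -1])
        g2 = rng.normal(0, 0.1, size=(20, 6)) + np.array([-1, -1, -1, 1, 1, 1])
        X = np.vstack([g1, g2])
        labels = np.array([0] * 20 + [1] * 20)
        return X, labels

    def test_two_groups_recovered(self):
        X, truth = self.make_two_groups()
        res = sota_cluster(X, max_clusters=2, seed=0)
        assert rand_index(res.labels, truth) == 1.0

    def test_single_cluster(self):
        X, _ = self.make_two_groups()
        res = sota_cluster(X, max_clusters=1, seed=0)
        assert set(res.labels) == {1}

    def test_determinism(self):
        X, _ = self.make_two_groups()
        a = sota_cluster(X, max_clusters=4, seed=3)
        b = sota_cluster(X, max_clusters=4, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 5))
        res = sota_cluster(X, max_clusters=8, seed=1)
        trace = res.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_growth_threshold_stops_splitting(self):
        X, _ = self.make_two_groups()
        res = sota_cluster(X, max_clusters=10, growth_threshold=1e6, seed=0)
        assert set(res.labels) == {1}

    def test_invalid_max_clusters(self):
        with pytest.raises(ValueError):
            sota_cluster(np.zeros((3, 2)), max_clusters=0, seed=0)
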