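"""Two-level consensus clustering against brute-force and planted oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from radphen import phenotyping as ph


class TestZScore:
    def test_hand_example(self):
        z = ph.zscore_features(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z.values["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            z = ph.zscore_features(df)
        assert z.dropped == ["b"]
        assert list(z.values.columns) == ["a"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((20, 5)))
        once = ph.zscore_features(df).values
        twice = ph.zscore_features(once).values
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ph.zscore_features(pd.DataFrame({"a": [1.0]}))


class TestCorrelationDistance:
    def test_duplicate_and_negated_features_at_zero(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        df = pd.DataFrame({"f": base, "g": 2.0 * base, "h": -base})
        d = ph.correlation_distance(ph.zscore_features(df))
        assert d.loc["f", "g"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["f", "h"] == pytest.approx(0.0, abs=1e-12)

    def test_sample_orthogonal_features_at_one(self):
        df = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        d = ph.correlation_distance(df)
        assert d.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((25, 6)))
        d1 = ph.correlation_distance(df)
        scaled = df * rng.uniform(0.1, 5.0, 6) + rng.uniform(-3, 3, 6)
        d2 = ph.correlation_distance(scaled)
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-10)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        d = ph.correlation_distance(pd.DataFrame(rng.standard_normal((15, 8)))).to_numpy()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()


def _brute_force_complete_linkage(d):
    """Naive agglomeration: merge the pair of clusters with smallest max-distance."""
    d = np.asarray(d, dtype=float)
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestHierarchicalCut:
    def test_singletons_at_k_equals_n(self):
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.standard_normal((6, 2))))
        labels = ph.hierarchical_cut(d, 6)
        assert len(set(labels)) == 6

    def test_separated_blocks_recovered(self):
        pts = np.vstack([np.zeros((5, 2)), 100.0 + np.zeros((4, 2))])
        pts += np.random.default_rng(5).normal(0, 0.1, pts.shape)
        d = squareform(pdist(pts))
        labels = ph.hierarchical_cut(d, 2)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_brute_force(self, seed):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(seed)
        d = squareform(pdist(rng.standard_normal((6, 3))))
        Z = linkage(squareform(d, checks=False), method="complete")
        assert np.allclose(sorted(Z[:, 2]), sorted(_brute_force_complete_linkage(d)), atol=1e-12)

    def test_k_out_of_range(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            ph.hierarchical_cut(d, 4)


class TestConsensus:
    def test_perfectly_separated_blobs_fully_stable(self):
        pts = np.vstack([np.zeros((6, 2)), 1e6 + np.zeros((6, 2))])
        pts += np.random.default_rng(6).normal(0, 1e-3, pts.shape)
        d = squareform(pdist(pts))
        res = ph.consensus_cluster(d, [2, 3], n_resamples=50, seed=0)
        M = res.consensus[2]
        same_blob = np.zeros((12, 12), bool)
        same_blob[:6, :6] = same_blob[6:, 6:] = True
        observed = res.consensus[2][np.triu_indices(12, 1)]
        assert np.all((observed == 0.0) | (observed == 1.0))
        assert np.all(M[:6, :6][np.triu_indices(6, 1)] == 1.0)

    def test_noise_items_unstable_at_k2(self):
        rng = np.random.default_rng(7)
        d = squareform(pdist(rng.standard_normal((30, 10))))
        res = ph.consensus_cluster(d, [2, 3], n_resamples=100, seed=1)
        mean_entry = res.consensus[2][np.triu_indices(30, 1)].mean()
        assert 0.2 < mean_entry < 0.8

    def test_single_full_resample_collapses_to_cut(self):
        rng = np.random.default_rng(8)
        d = squareform(pdist(rng.standard_normal((10, 3))))
        res = ph.consensus_cluster(d, [3, 4], n_resamples=1, subsample_frac=1.0, seed=2)
        labels = ph.hierarchical_cut(d, 3)
        expected = (labels[:, None] == labels[None, :]).astype(float)
        np.testing.assert_array_equal(res.consensus[3], expected)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        d = squareform(pdist(rng.standard_normal((15, 3))))
        a = ph.consensus_cluster(d, [2, 3, 4], n_resamples=20, seed=5)
        b = ph.consensus_cluster(d, [2, 3, 4], n_resamples=20, seed=5)
        for k in a.ks:
            np.testing.assert_array_equal(a.consensus[k], b.consensus[k])

    def test_rejects_non_consecutive_k(self):
        d = np.zeros((10, 10))
        with pytest.raises(ValueError):
            ph.consensus_cluster(d, [2, 4], n_resamples=5, seed=0)


class TestSelectK:
    def test_worked_arithmetic_example(self):
        res = ph.ConsensusResult(
            ks=[2, 3, 4, 5],
            consensus={},
            cdf_grid=np.linspace(0, 1, 100),
            cdfs={},
            areas={2: 0.50, 3: 0.80, 4: 0.84, 5: 0.85},
            relative_change={2: 0.6, 3: 0.05, 4: 0.85 / 0.84 - 1.0},
        )
        assert ph.select_k_by_cdf(res) == 3

    def test_fallback_to_max_with_warning(self):
        res = ph.ConsensusResult(
            ks=[2, 3, 4],
            consensus={},
            cdf_grid=np.linspace(0, 1, 100),
            cdfs={},
            areas={2: 0.3, 3: 0.5, 4: 0.8},
            relative_change={2: 0.66, 3: 0.6},
        )
        with pytest.warns(UserWarning, match="falling back"):
            assert ph.select_k_by_cdf(res) == 4


class TestSignatures:
    def test_singleton_cluster_returns_feature(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"a": rng.standard_normal(20), "b": rng.standard_normal(20)})
        z = ph.zscore_features(df)
        sig = ph.derive_signatures(z, pd.Series({"a": 1, "b": 2}))
        np.testing.assert_allclose(
            sig.values["signature_01"], z.values["a"], atol=1e-10
        )

    def test_identical_columns_explain_everything(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal(15)
        df = pd.DataFrame({"a": base, "b": base.copy()})
        z = pd.DataFrame({"a": base - base.mean(), "b": base - base.mean()})
        sig = ph.derive_signatures(z, pd.Series({"a": 1, "b": 1}))
        assert sig.explained_variance["signature_01"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.standard_normal((30, 6)))
        z = ph.zscore_features(df)
        sig = ph.derive_signatures(z, pd.Series(1, index=z.values.columns))
        X = z.values.to_numpy()
        Xc = X - X.mean(axis=0)
        w, v = np.linalg.eigh(np.cov(Xc, rowvar=False))
        pc_oracle = Xc @ v[:, -1]
        score = sig.values.iloc[:, 0].to_numpy()
        agreement = min(
            np.abs(score - pc_oracle).max(), np.abs(score + pc_oracle).max()
        )
        assert agreement < 1e-8

    def test_sign_aligned_with_cluster_mean(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.standard_normal((40, 5)) + rng.standard_normal((40, 1)))
        z = ph.zscore_features(df)
        sig = ph.derive_signatures(z, pd.Series(1, index=z.values.columns))
        mean_feature = z.values.mean(axis=1)
        assert np.corrcoef(sig.values.iloc[:, 0], mean_feature)[0, 1] >= 0

    def test_unlabeled_feature_rejected(self):
        df = pd.DataFrame(
            np.random.default_rng(13).standard_normal((10, 2)), columns=["a", "b"]
        )
        z = ph.zscore_features(df)
        with pytest.raises(ValueError):
            ph.derive_signatures(z, pd.Series({"a": 1}))


class TestAssignPhenotypes:
    def test_duplicated_tumors_share_labels(self):
        rng = np.random.default_rng(14)
        sig = pd.DataFrame(rng.standard_normal((10, 3)))
        doubled = pd.concat([sig, sig], ignore_index=True)
        asg = ph.assign_phenotypes(doubled, k_range=(2, 3), n_resamples=100, seed=0)
        lab = asg.labels.to_numpy()
        assert (lab[:10] == lab[10:]).all()

    def test_label_one_is_largest_cluster(self, small_cohort):
        z = ph.zscore_features(small_cohort.features)
        d = ph.correlation_distance(z)
        labels = ph.hierarchical_cut(d.to_numpy(), 3)
        sig = ph.derive_signatures(z, pd.Series(labels, index=z.values.columns))
        asg = ph.assign_phenotypes(sig, k_range=range(2, 5), n_resamples=100, seed=1)
        counts = asg.labels.value_counts()
        assert counts.loc[1] == counts.max()

    def test_planted_phenotypes_recovered_at_known_m(self, small_cohort):
        """With the phenotype count fixed at the planted two, the consensus
        2-cut recovers the planted labels exactly (the automatic CDF rule
        overestimates m on balanced Gaussian blobs; see the methods note)."""
        z = ph.zscore_features(small_cohort.features)
        d = ph.correlation_distance(z)
        res = ph.consensus_cluster(d.to_numpy(), range(2, 9), n_resamples=200, seed=3)
        kf = ph.select_k_by_cdf(res)
        labels = ph.hierarchical_cut(1 - res.consensus[kf], kf)
        sig = ph.derive_signatures(z, pd.Series(labels, index=z.values.columns))
        tres = ph.consensus_cluster(
            squareform(pdist(sig.values.to_numpy())), [2, 3], n_resamples=200, seed=4
        )
        two_cut = ph.hierarchical_cut(1 - tres.consensus[2], 2)
        ari = adjusted_rand_score(small_cohort.true_phenotype.to_numpy(), two_cut)
        assert ari >= 0.9


def test_feature_cluster_recovery_degrades_with_correlation():
    """Planted-block recovery at the true k: near-perfect at rho = 0.8 and
    monotonically worse as the within-cluster correlation weakens."""
    from radphen.synthetic_cohort import CohortConfig, generate_feature_matrix

    mean_ari = []
    for rho in (0.8, 0.4, 0.1):
        aris = []
        for seed in range(5):
            cfg = CohortConfig(
                n_tumors=100, n_features=50, k_feature_clusters=5,
                within_cluster_corr=rho, phenotype_shift=0.0, seed=seed,
            )
            x, truth, _ = generate_feature_matrix(cfg)
            z = ph.zscore_features(x)
            d = ph.correlation_distance(z)
            labels = ph.hierarchical_cut(d.to_numpy(), 5)
            aris.append(adjusted_rand_score(truth.to_numpy(), labels))
        mean_ari.append(float(np.mean(aris)))
    assert mean_ari[0] >= 0.9
    # non-increasing in noise, and clearly broken by rho = 0.1
    assert all(b <= a + 0.05 for a, b in zip(mean_ari, mean_ari[1:]))
    assert mean_ari[2] < mean_ari[0] - 0.5


class TestSigClust:
    def test_strong_separation_significant(self):
        rng = np.random.default_rng(15)
        a = rng.standard_normal((25, 3))
        b = rng.standard_normal((25, 3)) + 10.0
        X = np.vstack([a, b])
        labels = np.repeat([0, 1], 25)
        p = ph.sigclust_test(X, labels, n_sim=200, seed=0)
        assert p <= 0.01

    def test_invalid_inputs(self):
        X = np.random.default_rng(16).standard_normal((10, 2))
        with pytest.raises(ValueError):
            ph.sigclust_test(X, np.zeros(10, int), n_sim=10, seed=0)
        with pytest.raises(ValueError):
            ph.sigclust_test(X, np.repeat([0, 1], 5), n_sim=0, seed=0)
        with pytest.raises(ValueError):  # cluster with a single member
            ph.sigclust_test(X, np.array([0] * 9 + [1]), n_sim=10, seed=0)

    def test_two_means_splits_obvious_blobs(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.standard_normal((15, 2)), rng.standard_normal((15, 2)) + 8])
        labels = ph.two_means(X)
        assert len(set(labels[:15])) == 1 and labels[0] != labels[-1]
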