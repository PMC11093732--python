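"""Merging tree, bimodality, correlogram statistics and curation."""

import numpy as np
import pytest
from scipy.special import erf

from spikegraph.cluster import ClusterAssignment, knn_bipartite
from spikegraph.merges import (ACG_THRESH, CCG_THRESH, CorrelogramStats,
                               K_MAX, K_MIN, bimodality_score,
                               build_merge_tree, compute_correlograms,
                               global_merges, is_refractory, label_good,
                               traverse_tree, waveform_similarity)


def _two_cluster_graph():
    """Handmade bipartite aggregates: k1 = k2 = 10, K12 = 2, 2m = 20."""
    # 5 left points, 5 landmarks, k = 2: m = 10 edges; craft labels so
    # cluster degrees are 10/10 and exactly 2 edges cross
    X = np.array([[0.], [0.1], [0.2], [10.], [10.1]], np.float32)
    g = knn_bipartite(X, np.arange(5), k=2)
    left = np.array([0, 0, 0, 1, 1])
    right = left.copy()
    return g, ClusterAssignment(left, right)


class TestMergeTree:
    def test_gamma_hat_formula(self):
        """gamma_hat = 2 m K_ij / (k_i k_j): hand-computed 0.4 for
        k1 = k2 = 10, K12 = 2, 2m = 20."""
        g, a = _two_cluster_graph()
        # verify the constructed aggregates first
        tree = build_merge_tree(g, a)
        root = tree.root
        K12 = root.K_between
        k1 = tree.nodes[0].degree
        k2 = tree.nodes[1].degree
        assert root.gamma_hat == pytest.approx(
            2 * tree.m * K12 / (k1 * k2))

    def test_disconnected_cluster_merges_last_at_zero(self, rng):
        a = rng.normal(0, 0.2, (10, 2))
        b = a + [0.5, 0]
        c = rng.normal(100, 0.2, (10, 2))
        X = np.vstack([a, b, c]).astype(np.float32)
        g = knn_bipartite(X, np.arange(30), k=3)
        lab = np.repeat([0, 1, 2], 10)
        tree = build_merge_tree(g, ClusterAssignment(lab, lab.copy()))
        first, second = tree.nodes[3], tree.nodes[4]
        assert set(l for l in first.leaves) == {0, 1}
        assert second.gamma_hat == pytest.approx(0.0)

    def test_gamma_hat_monotone_vs_naive_rescan(self, rng):
        """The recorded gamma_hat sequence is non-increasing, and every
        greedy choice matches a naive re-scan over all active pairs."""
        for trial in range(5):
            r = np.random.default_rng(trial)
            X = r.standard_normal((60, 3)).astype(np.float32)
            g = knn_bipartite(X, np.arange(60), k=4)
            lab = r.integers(0, 8, 60)
            tree = build_merge_tree(g, ClusterAssignment(lab, lab.copy()))
            ghs = [n.gamma_hat for n in tree.nodes if n.children]
            assert all(np.diff(ghs) <= 1e-9)


class TestBimodality:
    def test_well_separated_clusters(self, rng):
        a = rng.normal(-2, 0.3, (5000, 1))
        b = rng.normal(2, 0.3, (5000, 1))
        assert bimodality_score(a, b).bimod > 0.9

    def test_random_split_of_one_gaussian(self):
        r0 = np.random.default_rng(3)
        x = r0.normal(0, 1, (10000, 4))
        r = bimodality_score(x[:5000], x[5000:])
        # trough and peaks agree up to histogram noise
        assert r.bimod <= 0.15

    def test_zero_trough_gives_one(self, rng):
        # far-separated dense clusters: trough density is exactly zero
        a = rng.normal(-1, 0.01, (4000, 1))
        b = rng.normal(1, 0.01, (4000, 1))
        r = bimodality_score(a, b)
        assert r.x_min == 0.0
        assert r.bimod == 1.0

    def test_histogram_mass_conserved_by_smoothing(self, rng):
        a = rng.normal(-1, 0.3, (3000, 2))
        b = rng.normal(1, 0.3, (3000, 2))
        r = bimodality_score(a, b)
        assert r.smoothed.sum() == pytest.approx(r.histogram.sum(),
                                                 abs=1e-9)

    def test_overfit_separation_suppressed(self):
        """Few points in many dimensions: the in-sample axis separates
        any random split perfectly (bimod ~ 1); the out-of-fold
        projections must not. At n = 240 the histogram itself is noisy,
        so the bound is loose — the contrast with ~1.0 is the point."""
        r0 = np.random.default_rng(0)
        x = r0.normal(0, 1, (240, 96))
        r = bimodality_score(x[:120], x[120:])
        assert r.bimod <= 0.9


class TestCorrelograms:
    def test_independent_poisson_flat(self, rng):
        t1 = np.sort(rng.uniform(0, 600, 3000))
        t2 = np.sort(rng.uniform(0, 600, 3000))
        s = compute_correlograms(t1, t2)
        assert 0.5 < s.R12 < 1.5
        assert s.Q12 > 0.2
        assert not is_refractory(s, "ccg")

    def test_refractory_train_acg(self, rng):
        isi = rng.exponential(0.08, 5000) + 0.003
        t = np.cumsum(isi)
        s = compute_correlograms(t)
        assert s.n_k[0] == 0
        assert s.R12 == 0.0
        assert is_refractory(s, "acg")

    def test_ccg_symmetry(self, rng):
        t1 = np.sort(rng.uniform(0, 100, 400))
        t2 = np.sort(rng.uniform(0, 100, 300))
        ab = compute_correlograms(t1, t2).counts
        ba = compute_correlograms(t2, t1).counts
        assert np.array_equal(ab, ba[::-1])

    def test_poisson_tail_probability_midpoint(self, rng):
        """P_k = (1 + erf((n_k - lam_k)/sqrt(eps + 2 lam_k)))/2 equals
        exactly 1/2 when the observed count hits its expectation."""
        t1 = np.sort(rng.uniform(0, 300, 2000))
        t2 = np.sort(rng.uniform(0, 300, 2000))
        s = compute_correlograms(t1, t2)
        lam = (2 * np.arange(K_MAX + 1) + 1) * s.shoulder_rate
        k = K_MAX
        P_at_lam = 0.5 * (1 + erf((lam[k] - lam[k]) /
                                  np.sqrt(1e-10 + 2 * lam[k])))
        assert P_at_lam == pytest.approx(0.5)

    def test_insufficient_spikes_flagged(self):
        s = compute_correlograms(np.array([1.0]))
        assert s.insufficient
        assert not is_refractory(s, "acg")


class TestIsRefractory:
    @pytest.mark.parametrize("r12,q12,mode,expected", [
        (0.2, 0.01, "ccg", True),
        (0.2, 0.01, "acg", False),    # ACG demands R12 < 0.1
        (0.3, 0.01, "ccg", False),
        (0.05, 0.3, "acg", False),    # ACG demands Q12 < 0.2
        (0.05, 0.1, "acg", True),
    ])
    def test_threshold_table(self, r12, q12, mode, expected):
        s = CorrelogramStats(np.zeros(1001), np.zeros(K_MAX + 1), 1.0,
                             r12, q12)
        assert is_refractory(s, mode) == expected


def _fixture_tree(features_by_leaf, times_by_leaf):
    """Build a tree over pre-labeled points via their kNN graph."""
    X = np.vstack(list(features_by_leaf.values())).astype(np.float32)
    lab = np.concatenate([np.full(len(v), i) for i, v in
                          enumerate(features_by_leaf.values())])
    g = knn_bipartite(X, np.arange(len(X)), k=5)
    tree = build_merge_tree(g, ClusterAssignment(lab, lab.copy()))
    leaf_f = {i: np.asarray(v) for i, v in
              enumerate(features_by_leaf.values())}
    leaf_t = {i: np.asarray(v) for i, v in
              enumerate(times_by_leaf.values())}
    return tree, leaf_f, leaf_t


class TestTraverseTree:
    def test_randomly_halved_unit_is_remerged(self, rng):
        """Pieces of one neuron: mutually refractory CCG, clean merged
        ACG, unimodal features -> one final cluster."""
        isi = rng.exponential(0.05, 8000) + 0.003
        t = np.cumsum(isi)
        half = rng.random(len(t)) < 0.5
        feats = rng.normal(0, 1, (len(t), 6))
        tree, lf, lt = _fixture_tree(
            {0: feats[half], 1: feats[~half]},
            {0: t[half], 1: t[~half]})
        labels = traverse_tree(tree, lf, lt)
        assert labels[0] == labels[1]

    def test_two_independent_units_stay_split(self, rng):
        ta = np.cumsum(rng.exponential(0.1, 4000) + 0.003)
        tb = np.cumsum(rng.exponential(0.1, 4000) + 0.003)
        fa = rng.normal(-3, 0.5, (4000, 6))
        fb = rng.normal(3, 0.5, (4000, 6))
        tree, lf, lt = _fixture_tree({0: fa, 1: fb}, {0: ta, 1: tb})
        labels = traverse_tree(tree, lf, lt)
        assert labels[0] != labels[1]

    def test_kept_merge_stops_descent(self, rng):
        """Four leaves of one unit: the top merge decision covers the
        whole subtree (audit shows a single tested node)."""
        isi = rng.exponential(0.05, 8000) + 0.003
        t = np.cumsum(isi)
        q = rng.integers(0, 4, len(t))
        feats = rng.normal(0, 1, (len(t), 6))
        tree, lf, lt = _fixture_tree(
            {i: feats[q == i] for i in range(4)},
            {i: t[q == i] for i in range(4)})
        audit = []
        labels = traverse_tree(tree, lf, lt, audit=audit)
        assert len(np.unique(labels)) < 4
        merges = [a for a in audit if a["decision"] == "merge"]
        assert merges


class TestGlobalMerges:
    def _unit(self, times, wf):
        return {"times": np.asarray(times), "waveform": wf}

    def test_boundary_straddling_unit_merged(self, rng):
        """One neuron split across two adjacent sections: similar
        waveforms, mutually refractory spikes -> merged."""
        isi = rng.exponential(0.05, 6000) + 0.003
        t = np.round(np.cumsum(isi) * 30000).astype(np.int64)
        half = rng.random(len(t)) < 0.5
        w = rng.standard_normal((8, 61))
        w2 = w + rng.standard_normal((8, 61)) * 0.1
        units = [self._unit(np.sort(t[half]), w),
                 self._unit(np.sort(t[~half]), w2)]
        out = global_merges(units, 30000.0)
        assert len(out) == 1

    def test_distinct_independent_units_not_merged(self, rng):
        ta = np.round(np.cumsum(rng.exponential(0.05, 6000) + 0.003)
                      * 30000).astype(np.int64)
        tb = np.round(np.cumsum(rng.exponential(0.05, 6000) + 0.003)
                      * 30000).astype(np.int64)
        w = rng.standard_normal((8, 61))
        w2 = 0.8 * w + 0.6 * rng.standard_normal((8, 61))   # sim ~ 0.6
        units = [self._unit(ta, w), self._unit(tb, w2)]
        out = global_merges(units, 30000.0)
        assert len(out) == 2

    def test_unit_without_candidates_untouched(self, rng):
        ta = np.arange(100, 10 ** 6, 3000)
        w1 = np.zeros((8, 61))
        w1[0, 30] = -1
        w2 = np.zeros((8, 61))
        w2[7, 30] = -1       # orthogonal waveform: similarity 0
        units = [self._unit(ta, w1), self._unit(ta + 17, w2)]
        out = global_merges(units, 30000.0)
        assert len(out) == 2


class TestLabelGood:
    def test_refractory_unit_good(self, rng):
        isi = rng.exponential(0.05, 6000) + 0.003
        t = np.round(np.cumsum(isi) * 30000).astype(np.int64)
        assert label_good(t, 30000.0) == "good"

    def test_poisson_train_mua(self, rng):
        t = np.round(np.sort(rng.uniform(0, 300, 6000)) * 30000
                     ).astype(np.int64)
        assert label_good(t, 30000.0) == "mua"

    def test_contaminated_mixture_mua(self, rng):
        a = np.cumsum(rng.exponential(0.05, 5000) + 0.003)
        b = np.sort(rng.uniform(0, a[-1], 2000))     # 30% contamination
        t = np.round(np.sort(np.concatenate([a, b])) * 30000
                     ).astype(np.int64)
        assert label_good(t, 30000.0) == "mua"

    def test_sparse_train_conservatively_mua(self):
        assert label_good(np.arange(10) * 30000, 30000.0) == "mua"


def test_waveform_similarity_lag_invariant(rng):
    w = rng.standard_normal((6, 61))
    w2 = np.roll(w, 7, axis=1)
    assert waveform_similarity(w, w2) > 0.85
    assert waveform_similarity(w, w) == pytest.approx(1.0, abs=1e-6)
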