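"""Embedding, batch correction, graph clustering and DE-based merging."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from scstage import cluster


def _two_blobs(rng, n=100, d=6, sep=20.0):
    a = rng.normal(size=(n, d))
    b = rng.normal(size=(n, d))
    b[:, 0] += sep
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


class TestPcaEmbed:
    def test_variance_non_increasing(self, rng):
        X = rng.normal(size=(80, 30))
        emb = cluster.pca_embed(X, d=10)
        assert np.all(np.diff(emb.explained_variance) <= 1e-9)

    def test_two_blob_separation_on_pc1(self, rng):
        X, lab = _two_blobs(rng)
        emb = cluster.pca_embed(X, d=3)
        pc1 = emb.coords[:, 0]
        centroids = [pc1[lab == i].mean() for i in (0, 1)]
        within = max(pc1[lab == i].std() for i in (0, 1))
        assert abs(centroids[0] - centroids[1]) > 5 * within

    def test_deterministic_sign(self, rng):
        X = rng.normal(size=(60, 20))
        e1 = cluster.pca_embed(X, d=5)
        e2 = cluster.pca_embed(X.copy(), d=5)
        assert np.allclose(e1.coords, e2.coords)
        # largest-|loading| entry positive in every component
        for comp in e1.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_d_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            cluster.pca_embed(rng.normal(size=(10, 5)), d=8)


class TestMnnCorrect:
    def test_identical_batches_nearly_unchanged(self, rng):
        X = rng.normal(size=(100, 5))
        coords = np.vstack([X, X])
        batches = np.array(["a"] * 100 + ["b"] * 100)
        emb = cluster.Embedding(coords=coords, batches=batches)
        out = cluster.mnn_correct(emb, k=10)
        scale = np.abs(coords).max()
        assert np.abs(out.coords - coords).max() < 1e-6 * scale

    def test_constant_orthogonal_shift_removed(self, rng):
        """A batch shift orthogonal to the data manifold (the method's
        stated working regime) is removed almost entirely."""
        X = np.hstack([rng.normal(size=(150, 3)),
                       rng.normal(scale=0.01, size=(150, 2))])
        shift = np.array([0.0, 0, 0, 5, -2])
        coords = np.vstack([X, X + shift])
        batches = np.array(["a"] * 150 + ["b"] * 150)
        emb = cluster.Embedding(coords=coords, batches=batches)
        out = cluster.mnn_correct(emb, k=15)
        ca = out.coords[:150].mean(axis=0)
        cb = out.coords[150:].mean(axis=0)
        assert np.linalg.norm(ca - cb) < 0.1 * np.linalg.norm(shift)

    def test_reference_batch_untouched(self, rng):
        X = rng.normal(size=(120, 4))
        coords = np.vstack([X, X[:60] + 5])  # first batch larger -> reference
        batches = np.array(["big"] * 120 + ["small"] * 60)
        emb = cluster.Embedding(coords=coords, batches=batches)
        out = cluster.mnn_correct(emb, k=10)
        assert np.allclose(out.coords[:120], coords[:120])

    def test_three_batches_within_type_distance_shrinks(self, rng):
        base = np.vstack([rng.normal(size=(60, 4)),
                          rng.normal(size=(60, 4)) + 15])
        types = np.array([0] * 60 + [1] * 60)
        coords, batches, labels = [], [], []
        for bi in range(3):
            shift = rng.normal(scale=4.0, size=4)
            coords.append(base + shift)
            batches += [f"b{bi}"] * 120
            labels.append(types)
        coords = np.vstack(coords)
        labels = np.concatenate(labels)
        batches = np.array(batches)

        def cross_batch_dist(c):
            tot = []
            for t in (0, 1):
                cents = [c[(batches == b) & (labels == t)].mean(axis=0)
                         for b in ("b0", "b1", "b2")]
                for i in range(3):
                    for j in range(i + 1, 3):
                        tot.append(np.linalg.norm(cents[i] - cents[j]))
            return np.mean(tot)

        emb = cluster.Embedding(coords=coords, batches=batches)
        out = cluster.mnn_correct(emb, k=15)
        assert cross_batch_dist(out.coords) < 0.5 * cross_batch_dist(coords)

    def test_single_batch_rejected(self, rng):
        emb = cluster.Embedding(coords=rng.normal(size=(50, 3)),
                                batches=np.zeros(50))
        with pytest.raises(ValueError):
            cluster.mnn_correct(emb)


class TestSnnGraph:
    def test_two_blobs_two_components(self, rng):
        X, _ = _two_blobs(rng, n=100, sep=50)
        g = cluster.snn_graph(X, k=10)
        comps = g.connected_components()
        assert len(comps) == 2

    def test_symmetric_no_self_loops(self, rng):
        X = rng.normal(size=(60, 4))
        g = cluster.snn_graph(X, k=8)
        assert not g.is_directed()
        assert all(e.source != e.target for e in g.es)

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            cluster.snn_graph(rng.normal(size=(10, 3)), k=10)


class TestCommunityCluster:
    def test_disconnected_cliques_exact(self):
        import igraph
        g = igraph.Graph.Full(10) + igraph.Graph.Full(12)
        g.es["weight"] = 1.0
        asg = cluster.community_cluster(g, steps=4)
        truth = [0] * 10 + [1] * 12
        assert adjusted_rand_score(truth, asg.labels) == 1.0
        assert asg.params["steps"] == 4

    def test_two_blob_embedding_recovered(self, rng):
        X, lab = _two_blobs(rng, n=150, sep=12)
        g = cluster.snn_graph(X, k=15)
        asg = cluster.community_cluster(g, steps=7)
        assert adjusted_rand_score(lab, asg.labels) >= 0.95

    def test_empty_graph_raises(self):
        import igraph
        with pytest.raises(ValueError):
            cluster.community_cluster(igraph.Graph(n=0))


class TestMergeByDe:
    def _expr(self, rng, shifts, n_per=150, g=400):
        """Clusters drawn from a base profile with per-cluster gene shifts."""
        blocks, labels = [], []
        for ci, shift in enumerate(shifts):
            X = rng.normal(0, 1, size=(n_per, g)) + shift
            blocks.append(X)
            labels += [f"c{ci}"] * n_per
        return sp.csr_matrix(np.vstack(blocks)), pd.Series(labels)

    def test_null_clusters_merge(self, rng):
        X, labels = self._expr(rng, [np.zeros(400), np.zeros(400)])
        asg = cluster.ClusterAssignment(labels=labels)
        merged = cluster.merge_by_de(X, asg, min_de=10)
        assert merged.labels.nunique() == 1
        assert len(merged.merge_history) == 1

    def test_separated_clusters_survive(self, rng):
        shift = np.zeros(400)
        shift[:50] = 2.0  # 50 genes at LFC 2
        X, labels = self._expr(rng, [np.zeros(400), shift])
        asg = cluster.ClusterAssignment(labels=labels)
        merged = cluster.merge_by_de(X, asg, min_de=10)
        assert merged.labels.nunique() == 2

    def test_protected_pair_never_merges(self, rng):
        X, labels = self._expr(rng, [np.zeros(400), np.zeros(400)])
        asg = cluster.ClusterAssignment(labels=labels)
        merged = cluster.merge_by_de(X, asg, min_de=10,
                                     protected_pairs={("c0", "c1")})
        assert merged.labels.nunique() == 2

    def test_terminates_within_bound(self, rng):
        X, labels = self._expr(rng, [np.zeros(300)] * 4, n_per=80, g=300)
        asg = cluster.ClusterAssignment(labels=labels)
        merged = cluster.merge_by_de(X, asg, min_de=10)
        assert len(merged.merge_history) <= 3


class TestSubcluster:
    def test_refines_only_target_cluster(self, rng):
        X, lab = _two_blobs(rng, n=120, sep=30)
        labels = pd.Series(np.where(lab == 0, "left", "right"))
        out = cluster.subcluster(X, labels, "left", k=10, steps=4)
        assert (out[labels == "right"] == "right").all()
        assert all(l.startswith("left") for l in out[labels == "left"])
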