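"""SOM read clustering: encoding, training, cohesion, subclustering and
representative selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from microfast import som
from microfast.records import ReadSet


def seqs_to_encoded(seqs, length=None):
    length = length or len(seqs[0])
    return som.encode_reads(seqs, length=length)


class TestHamming:
    def test_identical(self):
        assert som.hamming("ACGT", "ACGT") == 0

    def test_substitutions(self):
        assert som.hamming("AAAA", "AATT") == 2

    def test_fully_divergent(self):
        assert som.hamming("A" * 200, "C" * 200) == 200

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            som.hamming("ACG", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=50))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_zero_on_self(self, s):
        assert som.hamming(s, s) == 0
        t = s[::-1]
        assert som.hamming(s, t) == som.hamming(t, s)


class TestEncodeReads:
    def test_block_identity(self):
        enc = seqs_to_encoded(["ACGT"], length=4)
        oh = enc.onehot().reshape(4, 5)
        assert (oh.sum(axis=1) == 1).all()
        assert (oh[:, :4] == np.eye(4)).all()

    def test_short_reads_discarded_long_truncated(self):
        enc = som.encode_reads(["A" * 150, "A" * 250, "C" * 200], length=200)
        assert len(enc) == 2
        assert enc.n_discarded == 1
        assert enc.codes.shape == (2, 200)

    def test_n_gets_its_own_indicator(self):
        enc = seqs_to_encoded(["ANGT"], length=4)
        assert enc.codes[0, 1] == 4  # the N code
        oh = enc.onehot().reshape(4, 5)
        assert oh[1, 4] == 1

    def test_empty_input_errors(self):
        with pytest.raises(som.EmptyInputError):
            som.encode_reads([], length=200)

    def test_accepts_readset(self):
        rs = ReadSet("s", "16S", ["r1"], ["ACGTACGT"])
        enc = som.encode_reads(rs, length=8)
        assert enc.ids == ["r1"]


class TestSoftHamming:
    def test_equals_integer_hamming_for_onehot_codebook(self):
        """Distance to a one-hot node profile is the Hamming distance to
        its consensus sequence."""
        rng = np.random.default_rng(0)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 60))
                for _ in range(12)]
        enc = seqs_to_encoded(seqs)
        # codebook nodes = one-hot encodings of the first 4 reads
        weights = enc.onehot()[:4].astype(np.float32)
        cb = som.SOMCodebook(grid=(2, 2), length=60, weights=weights,
                             rounds=0, seed=None)
        d = cb.distances(enc)
        for i, s in enumerate(seqs):
            for node in range(4):
                assert d[i, node] == pytest.approx(
                    som.hamming(s, cb.consensus(node)), abs=1e-4
                )


class TestTrainSom:
    def test_deterministic(self):
        rng = np.random.default_rng(1)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 50))
                for _ in range(30)]
        enc = seqs_to_encoded(seqs)
        cb1 = som.train_som(enc, grid=(4, 4), rounds=500, seed=9)
        cb2 = som.train_som(enc, grid=(4, 4), rounds=500, seed=9)
        assert np.array_equal(cb1.weights, cb2.weights)

    def test_rounds_validation(self):
        enc = seqs_to_encoded(["ACGT"], length=4)
        with pytest.raises(ValueError):
            som.train_som(enc, rounds=0)

    def test_single_read_converges_to_onehot(self):
        enc = seqs_to_encoded(["ACGTAGCTTG" * 20])  # L=200
        cb = som.train_som(enc, grid=(3, 3), rounds=2000, seed=0)
        d = cb.distances(enc)
        assert d.min() < 0.01 * enc.length

    def test_node_position_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 40))
                for _ in range(20)]
        cb = som.train_som(seqs_to_encoded(seqs), grid=(3, 3), rounds=300, seed=1)
        sums = cb.weights.reshape(9, 40, 5).sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-5)

    def test_two_divergent_species_never_share_a_node(self, tiny_reference):
        """Reads of species at divergence ~0.5 with zero error map to
        disjoint nodes (oracle: nearest-template assignment, purity 1)."""
        t = list(tiny_reference.templates.values())[:2]
        seqs = [t[0]] * 100 + [t[1]] * 100
        enc = seqs_to_encoded(seqs)
        cb = som.train_som(enc, grid=(6, 6), rounds=3000, seed=4)
        bmus = cb.distances(enc).argmin(axis=1)
        assert set(bmus[:100]).isdisjoint(set(bmus[100:]))


class TestAssignToNodes:
    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(3)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 30))
                for _ in range(40)]
        enc = seqs_to_encoded(seqs)
        cb = som.train_som(enc, grid=(3, 3), rounds=400, seed=5)
        cs = som.assign_to_nodes(enc, cb)
        assert sum(c.size for c in cs.clusters) == 40
        labels = cs.labels()
        assert (labels >= 0).all()
        # permuted read order gives the same multiset of cluster contents
        perm = rng.permutation(40)
        enc_p = enc.subset(perm)
        cs_p = som.assign_to_nodes(enc_p, cb)
        sets = sorted(frozenset(enc.ids[i] for i in c.members)
                      for c in cs.clusters)
        sets_p = sorted(frozenset(enc_p.ids[i] for i in c.members)
                        for c in cs_p.clusters)
        assert sets == sets_p

    def test_width_mismatch_errors(self):
        enc = seqs_to_encoded(["ACGT"], length=4)
        enc2 = seqs_to_encoded(["ACGTAA"], length=6)
        cb = som.train_som(enc, grid=(2, 2), rounds=10, seed=0)
        with pytest.raises(ValueError):
            cb.distances(enc2)


class TestCohesion:
    def test_identical_members(self):
        enc = seqs_to_encoded(["ACGT" * 10] * 5)
        assert som.cluster_cohesion(np.arange(5), enc) == pytest.approx(1.0)

    def test_fully_divergent_pair_is_minus_one_third(self):
        enc = seqs_to_encoded(["A" * 200, "C" * 200])
        assert som.cluster_cohesion(np.arange(2), enc) == pytest.approx(
            -1 / 3, abs=1e-5
        )

    def test_singleton_convention(self):
        enc = seqs_to_encoded(["ACGT"])
        assert som.cluster_cohesion(np.array([0]), enc) == 1.0

    def test_subsampled_close_to_exhaustive(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 4, 100)
        seqs = []
        for _ in range(80):
            s = base.copy()
            pos = rng.choice(100, 5, replace=False)
            s[pos] = (s[pos] + rng.integers(1, 4, 5)) % 4
            seqs.append("".join("ACGT"[b] for b in s))
        enc = seqs_to_encoded(seqs)
        full = som.cluster_cohesion(np.arange(80), enc, max_pairs=10**9)
        sub = som.cluster_cohesion(np.arange(80), enc, max_pairs=500, seed=1)
        assert sub == pytest.approx(full, abs=0.02)


class TestRepresentative:
    def test_singleton(self):
        enc = seqs_to_encoded(["ACGT"])
        cl = som.ReadCluster("c", np.array([0]), (0, 0))
        assert som.select_representative(cl, enc) == 0

    def test_identical_members_tie_breaks_to_smallest(self):
        enc = seqs_to_encoded(["ACGT" * 5] * 4)
        cl = som.ReadCluster("c", np.array([2, 1, 3]), (0, 0))
        assert som.select_representative(cl, enc) == 1

    def test_noisy_member_not_selected(self):
        rng = np.random.default_rng(4)
        tpl = rng.integers(0, 4, 100)
        noisy = tpl.copy()
        noisy[:5] = (noisy[:5] + 1) % 4
        seqs = ["".join("ACGT"[b] for b in tpl)] * 9 + [
            "".join("ACGT"[b] for b in noisy)
        ]
        enc = seqs_to_encoded(seqs)
        cl = som.ReadCluster("c", np.arange(10), (0, 0))
        assert som.select_representative(cl, enc) < 9


class TestSubcluster:
    def _clusterset_with_cohesion(self, enc, grid=(2, 2), seed=0):
        cb = som.train_som(enc, grid=grid, rounds=300, seed=seed)
        cs = som.assign_to_nodes(enc, cb)
        for c in cs.clusters:
            c.cohesion = som.cluster_cohesion(c.members, enc, seed=seed)
        return cs

    def test_tight_clusters_pass_through(self):
        enc = seqs_to_encoded(["ACGT" * 25] * 20)
        cs = self._clusterset_with_cohesion(enc)
        out = som.subcluster_loose(cs, enc, seed=1)
        assert [c.cluster_id for c in out.clusters] == [
            c.cluster_id for c in cs.clusters
        ]

    def test_mixed_cluster_splits_by_species(self, tiny_reference):
        t = list(tiny_reference.templates.values())[:2]
        seqs = [t[0]] * 30 + [t[1]] * 30
        enc = seqs_to_encoded(seqs)
        # force everything into one loose cluster
        cs = som.ReadClusterSet(
            clusters=[som.ReadCluster("c0", np.arange(60), (0, 0),
                                      cohesion=0.0)],
            n_reads=60,
        )
        out = som.subcluster_loose(cs, enc, subgrid=(4, 4), rounds=2000, seed=2)
        assert len(out.clusters) >= 2
        truth = np.array([0] * 30 + [1] * 30)
        for c in out.clusters:
            _, counts = np.unique(truth[c.members], return_counts=True)
            assert counts.max() / c.size >= 0.95
        assert sum(c.size for c in out.clusters) == 60

    def test_requires_cohesion(self):
        enc = seqs_to_encoded(["ACGT"] * 3)
        cs = som.ReadClusterSet(
            [som.ReadCluster("c", np.arange(3), (0, 0))], n_reads=3
        )
        with pytest.raises(ValueError):
            som.subcluster_loose(cs, enc)


class TestEstimators:
    def test_amplicon_clusterer_sklearn_api(self, tiny_reference):
        t = list(tiny_reference.templates.values())[:2]
        est = som.AmpliconClusterer(
            grid=(4, 4), rounds=600, subrounds=600, length=120, random_state=0
        )
        cloned = clone(est)
        assert cloned.get_params()["rounds"] == 600
        fitted = est.fit([t[0]] * 20 + [t[1]] * 20)
        assert len(fitted.labels_) == 40
        assert fitted.clusters_.n_reads == 40
        reps = [c.representative for c in fitted.clusters_.clusters]
        assert all(r is not None for r in reps)

    def test_full_pipeline_deterministic(self, tiny_reference):
        t = list(tiny_reference.templates.values())
        seqs = [t[i % 4] for i in range(60)]
        enc = som.encode_reads(seqs, length=120)
        a = som.cluster_sample(enc, grid=(4, 4), rounds=500, subrounds=500, seed=21)
        b = som.cluster_sample(enc, grid=(4, 4), rounds=500, subrounds=500, seed=21)
        assert [list(c.members) for c in a.clusters] == [
            list(c.members) for c in b.clusters
        ]
        assert [c.cohesion for c in a.clusters] == [c.cohesion for c in b.clusters]
        assert [c.representative for c in a.clusters] == [
            c.representative for c in b.clusters
        ]
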