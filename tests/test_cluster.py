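import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from conftest import as_single_genome, mini_params, random_protein
from homclust.cluster import (
    ClusteringConfig,
    HomologyClusterer,
    IntervalSet,
    add_interval,
    build_clusters,
    cluster_statistics,
    is_fully_covered,
    order_sequences,
)
from homclust.io_formats import GenomeSet, ProteinSequence
from homclust.synthdata import generate_dataset


class TestIntervalSet:
    def test_overlap_merge(self):
        cov = IntervalSet(100)
        cov.add(0, 40)
        cov.add(30, 80)
        assert cov.intervals == [(0, 80)]
        assert cov.covered_length == 80

    def test_idempotent(self):
        cov = IntervalSet(100)
        cov.add(10, 50)
        before = list(cov.intervals)
        cov = add_interval(cov, (10, 50))
        assert cov.intervals == before

    def test_disjoint_kept_separate(self):
        cov = IntervalSet(100)
        cov.add(20, 30)
        cov.add(0, 10)
        assert cov.intervals == [(0, 10), (20, 30)]
        assert cov.covered_length == 20

    def test_touching_intervals_merge(self):
        cov = IntervalSet(100)
        cov.add(0, 10)
        cov.add(10, 20)
        assert cov.intervals == [(0, 20)]

    def test_out_of_bounds_rejected(self):
        cov = IntervalSet(50)
        with pytest.raises(ValueError):
            cov.add(0, 51)
        with pytest.raises(ValueError):
            cov.add(-1, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 99), st.integers(1, 100)), max_size=12))
    def test_union_invariants(self, raw):
        intervals = [(min(a, b), max(a, b)) for a, b in raw if a != b]
        cov = IntervalSet(100)
        mask = np.zeros(100, dtype=bool)
        for s, e in intervals:
            cov.add(s, e)
            mask[s:e] = True
        assert cov.covered_length == int(mask.sum())
        # sorted, disjoint, non-empty, non-touching
        for (s1, e1), (s2, e2) in zip(cov.intervals, cov.intervals[1:]):
            assert e1 < s2
        assert all(e > s for s, e in cov.intervals)


class TestCoverage:
    def test_within_tolerance(self):
        cov = IntervalSet(110)
        cov.add(0, 100)
        assert is_fully_covered(cov, 110, 20)

    def test_fusion_half_not_covered(self):
        cov = IntervalSet(400)
        cov.add(0, 200)
        assert not is_fully_covered(cov, 400, 20)

    def test_short_sequence_trivially_covered(self):
        assert is_fully_covered(IntervalSet(15), 15, 20)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            is_fully_covered(IntervalSet(10), 10, -1)


class TestOrderSequences:
    def _genome(self, gid, n, rng):
        return (gid, [random_protein(rng, 60, f"{gid}_{i}", gid) for i in range(n)])

    def test_descending_by_size(self, rng):
        gs = GenomeSet([self._genome("G1", 3, rng), self._genome("G2", 5, rng), self._genome("G3", 4, rng)])
        order = [s.genome_id for s in order_sequences(gs)]
        assert order == ["G2"] * 5 + ["G3"] * 4 + ["G1"] * 3

    def test_single_genome_keeps_file_order(self, rng):
        gs = GenomeSet([self._genome("G1", 4, rng)])
        assert [s.seq_id for s in order_sequences(gs)] == [f"G1_{i}" for i in range(4)]

    def test_equal_sizes_keep_input_order(self, rng):
        gs = GenomeSet([self._genome("GB", 3, rng), self._genome("GA", 3, rng)])
        order = [s.genome_id for s in order_sequences(gs)]
        assert order == ["GB"] * 3 + ["GA"] * 3


class TestBuildClusters:
    def test_single_sequence(self, scheme, rng):
        gs = as_single_genome([random_protein(rng, 100, "A")])
        clusters, n_aln = build_clusters(gs, scheme, ClusteringConfig())
        assert n_aln == 0
        (c,) = clusters.clusters
        assert c.members == ["A"] and c.representatives == ["A"]

    def test_empty_input(self, scheme):
        clusters, n_aln = build_clusters(GenomeSet([]), scheme, ClusteringConfig())
        assert clusters.n_clusters == 0 and n_aln == 0

    def test_representative_stands_in_for_members(self, scheme, rng):
        # A-B and A-C significant; B-C found without ever being aligned
        a = random_protein(rng, 120, "A")
        b = ProteinSequence("B", "g1", a.residues)
        c = ProteinSequence("C", "g1", a.residues)
        est = HomologyClusterer(max_representatives=1, scheme=scheme).fit(
            as_single_genome([a, b, c])
        )
        (cl,) = est.clusters_.clusters
        assert cl.members == ["A", "B", "C"] and cl.representatives == ["A"]
        assert est.n_alignments_ == 2
        assert ("B", "C") not in est.score_cache_

    def test_unrelated_singletons_alignment_count(self, scheme, rng):
        seqs = [random_protein(rng, 80, f"s{i}") for i in range(4)]
        clusters, n_aln = build_clusters(as_single_genome(seqs), scheme, ClusteringConfig())
        assert clusters.n_clusters == 4
        assert n_aln == 6  # every sequence aligned to all previous representatives

    def test_fusion_founds_additional_cluster_only_with_subsequence(self, scheme, rng):
        fam = random_protein(rng, 200, "A")
        fusion = ProteinSequence("C", "g1", fam.residues + random_protein(rng, 200).residues)
        for subseq, expected_clusters in ((True, 2), (False, 1)):
            est = HomologyClusterer(
                max_representatives=1, use_subsequence_homology=subseq, scheme=scheme
            ).fit(as_single_genome([fam, fusion]))
            assert est.clusters_.n_clusters == expected_clusters
            assert est.clusters_.clusters[0].members == ["A", "C"]
            if subseq:
                assert est.clusters_.clusters[1].members == ["C"]
                assert est.clusters_.clusters[1].representatives == ["C"]

    def test_totality_every_sequence_clustered(self, scheme, mini_dataset):
        genomes, _ = mini_dataset
        clusters, _ = build_clusters(genomes, scheme, ClusteringConfig())
        membership = clusters.membership()
        assert set(membership) == {s.seq_id for s in genomes.sequences()}

    def test_coverage_guarantee(self, scheme, mini_dataset):
        genomes, _ = mini_dataset
        est = HomologyClusterer(max_representatives=1, scheme=scheme).fit(genomes)
        reps = {sid for c in est.clusters_.clusters for sid in c.representatives}
        for seq in genomes.sequences():
            if seq.seq_id not in reps:
                assert est.coverage_[seq.seq_id].uncovered() <= est.tolerance_

    def test_representative_cap_and_join_order(self, scheme, mini_dataset):
        genomes, _ = mini_dataset
        est = HomologyClusterer(max_representatives=3, scheme=scheme).fit(genomes)
        for c in est.clusters_.clusters:
            assert len(c.representatives) <= 3
            assert c.representatives == c.members[: len(c.representatives)]

    def test_shuffled_order_keeps_invariants(self, scheme, rng):
        genomes, _ = generate_dataset(mini_params(seed=11))
        all_seqs = list(genomes.sequences())
        tol = scheme.coverage_tolerance
        for trial in range(10):
            perm = rng.permutation(len(all_seqs))
            half = len(all_seqs) // 2
            shuffled = GenomeSet(
                [
                    ("gA", [all_seqs[i] for i in perm[:half]]),
                    ("gB", [all_seqs[i] for i in perm[half:]]),
                ]
            )
            est = HomologyClusterer(max_representatives=1, scheme=scheme).fit(shuffled)
            membership = est.clusters_.membership()
            assert set(membership) == {s.seq_id for s in all_seqs}
            reps = {sid for c in est.clusters_.clusters for sid in c.representatives}
            for s in all_seqs:
                assert s.seq_id in reps or est.coverage_[s.seq_id].uncovered() <= tol

    def test_deterministic(self, scheme, mini_dataset):
        genomes, _ = mini_dataset
        c1, n1 = build_clusters(genomes, scheme, ClusteringConfig())
        c2, n2 = build_clusters(genomes, scheme, ClusteringConfig())
        assert c1 == c2 and n1 == n2


class TestEstimatorInterface:
    def test_get_set_params_and_clone(self, scheme):
        est = HomologyClusterer(max_representatives=3, use_subsequence_homology=False)
        params = est.get_params()
        assert params["max_representatives"] == 3
        est2 = clone(est).set_params(max_representatives=1)
        assert est2.get_params()["max_representatives"] == 1
        assert est.get_params()["max_representatives"] == 3

    def test_fit_validates_input(self, scheme):
        with pytest.raises(TypeError):
            HomologyClusterer(scheme=scheme).fit([1, 2, 3])
        with pytest.raises(ValueError):
            HomologyClusterer(max_representatives=0, scheme=scheme).fit(GenomeSet([]))

    def test_fit_predict_returns_membership(self, scheme, rng):
        a = random_protein(rng, 100, "A")
        b = ProteinSequence("B", "g1", a.residues)
        membership = HomologyClusterer(scheme=scheme).fit_predict(as_single_genome([a, b]))
        assert membership == {"A": [0], "B": [0]}


class TestClusterStatistics:
    def test_single_cluster(self, scheme, rng):
        a = random_protein(rng, 100, "A")
        gs = as_single_genome([a, ProteinSequence("B", "g", a.residues), ProteinSequence("C", "g", a.residues)])
        clusters, _ = build_clusters(gs, scheme, ClusteringConfig())
        stats = cluster_statistics(clusters)
        assert stats == {
            "n_clusters": 1,
            "size_histogram": {3: 1},
            "n_multi_membership": 0,
            "clusters_per_sequence": {1: 3},
        }

    def test_shared_sequence_counts_as_multi_membership(self, scheme, rng):
        from homclust.cluster import Cluster, ClusterSet

        cs = ClusterSet([Cluster(0, ["A"], ["A", "X"]), Cluster(1, ["B"], ["B", "X"])])
        stats = cluster_statistics(cs)
        assert stats["n_multi_membership"] == 1
        assert stats["clusters_per_sequence"] == {1: 2, 2: 1}

    def test_empty(self):
        from homclust.cluster import ClusterSet

        stats = cluster_statistics(ClusterSet([]))
        assert stats["n_clusters"] == 0 and stats["size_histogram"] == {}
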