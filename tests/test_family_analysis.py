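import numpy as np
import pytest

from packtype.family_analysis import (
    TIRDistanceMatrix,
    chi2_one_sided,
    cluster_tir_matrix,
    find_local_pairs,
    kmer_jaccard_distance,
    local_hopping_test,
    orientation_concordance,
    tir_distance_matrix,
    tsd_composition,
    LocalPair,
)
from packtype.genome_io import AnnotationRecord

from _oracles import chi2_one_sided_oracle, kmer_distance_oracle


def _rand(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _rec(start, end, cluster=1, strand="+", contig="c1", eid=None):
    return AnnotationRecord(contig, start, end, strand,
                            element_id=eid or f"{contig}:{start}", cluster_id=cluster)


class TestKmerDistance:
    def test_identical_prefixes(self):
        assert kmer_jaccard_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_disjoint_kmer_sets(self):
        assert kmer_jaccard_distance("AAAAAAAA", "CCCCCCCC") == 1.0

    def test_matches_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(50)
        for _ in range(30):
            a, b = _rand(rng, 80), _rand(rng, 80)
            assert kmer_jaccard_distance(a, b, 5) == pytest.approx(
                kmer_distance_oracle(a, b, 5)
            )

    def test_matrix_properties_and_short_sequence_warning(self, caplog):
        import logging

        rng = np.random.default_rng(51)
        seqs = {"a": _rand(rng, 200), "b": _rand(rng, 200), "c": _rand(rng, 40)}
        with caplog.at_level(logging.WARNING):
            m = tir_distance_matrix(seqs, prefix_len=80)
        assert any("shorter" in r.message for r in caplog.records)
        assert m.d.shape == (3, 3)
        assert np.allclose(m.d, m.d.T) and np.all(np.diag(m.d) == 0)


class TestClusterTirMatrix:
    def _two_superfamily_seqs(self, rng, n_per=5):
        tir_a, tir_b = _rand(rng, 40), _rand(rng, 40)
        seqs = {}
        for i in range(n_per):
            seqs[f"A{i}"] = tir_a + _rand(rng, 60)
            seqs[f"B{i}"] = tir_b + _rand(rng, 60)
        return seqs

    def test_superfamilies_separate_at_two_groups(self):
        rng = np.random.default_rng(52)
        m = tir_distance_matrix(self._two_superfamily_seqs(rng), prefix_len=80)
        groups, _ = cluster_tir_matrix(m, n_groups=2)
        a_groups = {groups[k] for k in groups if k.startswith("A")}
        b_groups = {groups[k] for k in groups if k.startswith("B")}
        assert len(a_groups) == 1 and len(b_groups) == 1 and a_groups != b_groups

    def test_n_groups_equals_n(self):
        rng = np.random.default_rng(53)
        m = tir_distance_matrix({f"s{i}": _rand(rng, 90) for i in range(4)})
        groups, _ = cluster_tir_matrix(m, n_groups=4)
        assert sorted(groups.values()) == [1, 2, 3, 4]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(54)
        seqs = self._two_superfamily_seqs(rng, 3)
        m1 = tir_distance_matrix(dict(sorted(seqs.items())))
        m2 = tir_distance_matrix(dict(sorted(seqs.items(), reverse=True)))
        g1, _ = cluster_tir_matrix(m1, 2)
        g2, _ = cluster_tir_matrix(m2, 2)
        part = lambda g: sorted(sorted(k for k in g if g[k] == v) for v in set(g.values()))
        assert part(g1) == part(g2)

    def test_too_many_groups_rejected(self):
        m = TIRDistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            cluster_tir_matrix(m, n_groups=3)


class TestLocalPairs:
    def test_pair_within_window(self):
        recs = [_rec(1000, 1500), _rec(51_500, 52_000)]
        (pair,) = find_local_pairs(recs, window=100_000)
        assert pair.same_cluster and pair.distance == 49_999

    def test_pair_beyond_window_excluded(self):
        recs = [_rec(1000, 1500), _rec(152_000, 152_500)]
        assert find_local_pairs(recs, window=100_000) == []

    def test_four_mutually_local_elements_give_six_pairs(self):
        recs = [_rec(1 + 10_000 * i, 500 + 10_000 * i) for i in range(4)]
        assert len(find_local_pairs(recs)) == 6

    def test_different_contigs_not_paired(self):
        recs = [_rec(1000, 1500, contig="c1"), _rec(2000, 2500, contig="c2")]
        assert find_local_pairs(recs) == []

    def test_overlapping_elements_distance_zero(self):
        recs = [_rec(1000, 2000), _rec(1500, 2500)]
        (pair,) = find_local_pairs(recs)
        assert pair.distance == 0


class TestChiSquared:
    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(60)
        for _ in range(100):
            t = rng.integers(0, 60, size=(2, 2)).astype(float)
            assert chi2_one_sided(t) == pytest.approx(chi2_one_sided_oracle(t), abs=1e-12)

    def test_equal_proportions_not_significant(self):
        assert chi2_one_sided(np.array([[10, 10], [20, 20]])) >= 0.5

    def test_degenerate_margin_gives_one(self):
        assert chi2_one_sided(np.array([[0, 0], [5, 10]])) == 1.0

    def test_strong_enrichment_significant(self):
        # all 10 members local to each other, none of 1000 outsiders local
        p = chi2_one_sided(np.array([[10, 0], [0, 1000]]))
        assert p < 1e-4

    def test_wrong_direction_not_significant(self):
        p = chi2_one_sided(np.array([[1, 19], [30, 10]]))
        assert p > 0.5


class TestLocalHopping:
    def test_clustered_members_enriched(self):
        # cluster 1: five members within 40 kb; many distant unrelated elements
        recs = [_rec(1 + 10_000 * i, 500 + 10_000 * i, cluster=1) for i in range(5)]
        recs += [_rec(1_000_000 + 300_000 * i, 1_000_500 + 300_000 * i, cluster=2 + i)
                 for i in range(20)]
        p = local_hopping_test(recs, cluster_id=1)
        assert p < 1e-3

    def test_pooled_aggregate_runs_over_all_clusters(self):
        recs = [_rec(1 + 10_000 * i, 500 + 10_000 * i, cluster=1) for i in range(4)]
        recs += [_rec(2_000_000 + 10_000 * i, 2_000_500 + 10_000 * i, cluster=2)
                 for i in range(4)]
        recs += [_rec(5_000_000 + 400_000 * i, 5_000_500 + 400_000 * i, cluster=3 + i)
                 for i in range(10)]
        p = local_hopping_test(recs)
        assert p < 1e-3

    def test_too_small_cluster_rejected(self):
        recs = [_rec(1000, 1500, cluster=1), _rec(900_000, 900_500, cluster=2)]
        with pytest.raises(ValueError):
            local_hopping_test(recs, cluster_id=1)


class TestOrientationConcordance:
    def _pairs(self, n_same, n_opp):
        mk = lambda i, same: LocalPair(f"a{i}", f"b{i}", 100, True, same)
        return [mk(i, True) for i in range(n_same)] + [
            mk(100 + i, False) for i in range(n_opp)
        ]

    def test_twelve_of_fifteen(self):
        assert orientation_concordance(self._pairs(12, 3)) == pytest.approx(0.80)

    def test_twelve_of_thirteen(self):
        assert orientation_concordance(self._pairs(12, 1)) == pytest.approx(0.923, abs=5e-4)

    def test_all_concordant(self):
        assert orientation_concordance(self._pairs(4, 0)) == 1.0

    def test_no_same_cluster_pairs_undefined(self):
        pairs = [LocalPair("a", "b", 10, False, True)]
        assert orientation_concordance(pairs) is None


class TestTsdComposition:
    def _recs(self, tsds):
        return [
            AnnotationRecord("c1", 1 + 1000 * i, 500 + 1000 * i, "+",
                             element_id=f"e{i}", tsd_seq_5=t)
            for i, t in enumerate(tsds)
        ]

    def test_all_match(self):
        frac, table = tsd_composition(self._recs(["TA"] * 4), "TA")
        assert frac == 1.0 and table == {"TA": 4}

    def test_half_match(self):
        frac, _ = tsd_composition(self._recs(["TA", "TC", "TA", "TC"]), "TA")
        assert frac == 0.5

    def test_known_proportions_recovered(self):
        tsds = ["TTA"] * 6 + ["TAA"] * 3 + ["GGC"] * 1
        frac, table = tsd_composition(self._recs(tsds), "TTA")
        assert frac == pytest.approx(0.6)
        assert table == {"TTA": 6, "TAA": 3, "GGC": 1}
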