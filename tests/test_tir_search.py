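import numpy as np
import pytest

from packtype.genome_io import GenomeSequences, reverse_complement
from packtype.tir_search import (
    CandidateElement,
    TIRMatch,
    TIRQuery,
    check_tsd,
    deduplicate,
    find_tir_matches,
    levenshtein,
    pair_candidates,
    scan_genome,
)

from _oracles import collapse_overlapping, window_levenshtein_all


def _genome(seq: str) -> GenomeSequences:
    return GenomeSequences(contigs={"c1": seq})


def _query(**kw) -> TIRQuery:
    defaults = dict(superfamily="T", forward_tir="CACTACAA", width_min=300, width_max=15000)
    defaults.update(kw)
    return TIRQuery(**defaults)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [("", "", 0), ("A", "", 1), ("TA", "TC", 1), ("CACTACAA", "CACTACAA", 0),
         ("ACGT", "AGT", 1), ("N", "N", 1), ("AN", "AN", 1)],
    )
    def test_examples_including_n_rule(self, a, b, d):
        assert levenshtein(a, b) == d


class TestFindTirMatches:
    def test_exact_substring(self):
        matches = find_tir_matches(_genome("TTCACTACAATT"), "CACTACAA", 0)
        assert matches == [TIRMatch("c1", 3, 10, "forward-seed", 0)]

    def test_single_mismatch_found_at_budget_one(self):
        matches = find_tir_matches(_genome("TTCACTGCAATT"), "CACTACAA", 1)
        assert len(matches) == 1
        assert matches[0].edit_distance == 1

    def test_short_seed_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            find_tir_matches(_genome("ACGTACGT"), "ACGTA", 0)

    def test_exact_count_matches_substring_count_on_random_sequence(self):
        rng = np.random.default_rng(42)
        genome_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        seed = "CACTACAATTGGC"  # 13 nt
        expected = sum(
            1 for i in range(len(genome_seq) - 12) if genome_seq[i : i + 13] == seed
        )
        got = find_tir_matches(_genome(genome_seq), seed, 0)
        assert len(got) == expected

    @pytest.mark.parametrize("budget", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, budget):
        """Semi-global matcher == exhaustive per-window global DP + the
        stated collapse rule, on random 500 bp sequences."""
        rng = np.random.default_rng(1000 + budget)
        seed = "GGCCATAGGTTCA"
        for _ in range(10):
            text = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
            expected = collapse_overlapping(window_levenshtein_all(text, seed, budget))
            got = [(m.start, m.end, m.edit_distance)
                   for m in find_tir_matches(_genome(text), seed, budget)]
            assert got == expected

    def test_span_length_within_budget_of_seed(self):
        rng = np.random.default_rng(7)
        text = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        for m in find_tir_matches(_genome(text), "GGCCATAGGTTCA", 3):
            assert 10 <= m.width <= 16


class TestPairCandidates:
    def _matches(self, spans, seed_len=8):
        return [TIRMatch("c1", s, e, "forward-seed", 0) for s, e in spans]

    def test_width_below_window_rejected(self):
        f = self._matches([(1, 8)])
        r = self._matches([(193, 200)])
        assert pair_candidates(f, r, _query()) == []

    def test_width_at_window_accepted(self):
        f = self._matches([(1, 8)])
        r = self._matches([(493, 500)])
        (cand,) = pair_candidates(f, r, _query())
        assert (cand.start, cand.end, cand.width) == (1, 500, 500)

    def test_all_compatible_pairs_emitted(self):
        f = self._matches([(1, 8), (11, 18), (21, 28)])
        r = self._matches([(493, 500), (593, 600)])
        cands = pair_candidates(f, r, _query())
        assert len(cands) == 6

    def test_different_contigs_not_paired(self):
        f = [TIRMatch("c1", 1, 8, "forward-seed", 0)]
        r = [TIRMatch("c2", 493, 500, "forward-seed", 0)]
        assert pair_candidates(f, r, _query()) == []


class TestCheckTsd:
    def _candidate(self, genome, start, end, **qkw):
        q = _query(**qkw)
        return CandidateElement(
            contig_id="c1", start=start, end=end,
            fwd_tir=TIRMatch("c1", start, start + 7, "forward-seed", 0),
            rev_tir=TIRMatch("c1", end - 7, end, "reverse-seed", 0),
            query=q,
        )

    def test_identical_flanks_kept(self):
        seq = "ACGTACGT" + "G" * 400 + "ACGTACGT"
        g = _genome(seq)
        cand = self._candidate(g, 9, 408, tsd_length=8, max_tsd_mismatch=0)
        kept = check_tsd(g, cand)
        assert kept is not None
        assert (kept.tsd_5, kept.tsd_3, kept.tsd_distance) == ("ACGTACGT", "ACGTACGT", 0)

    def test_mismatching_flanks_rejected_at_zero_budget(self):
        seq = "TA" + "G" * 400 + "TC"
        g = _genome(seq)
        cand = self._candidate(g, 3, 402, tsd_length=2, max_tsd_mismatch=0)
        assert check_tsd(g, cand) is None

    def test_contig_edge_rejected(self):
        g = _genome("G" * 400 + "ACGTACGT")
        cand = self._candidate(g, 1, 400, tsd_length=8, max_tsd_mismatch=0)
        assert check_tsd(g, cand) is None

    def test_motif_recorded_but_not_filtered_on(self):
        seq = "GG" + "C" * 400 + "GG"
        g = _genome(seq)
        cand = self._candidate(g, 3, 402, tsd_motif="TA", max_tsd_mismatch=0)
        kept = check_tsd(g, cand)
        assert kept is not None  # flanks agree even though motif differs
        assert kept.tsd_motif_match is False


class TestDeduplicate:
    def _cand(self, start, end, qidx=0):
        return CandidateElement(
            contig_id="c1", start=start, end=end,
            fwd_tir=TIRMatch("c1", start, start + 7, "forward-seed", 0),
            rev_tir=TIRMatch("c1", end - 7, end, "reverse-seed", 0),
            query=_query(), query_index=qidx,
        )

    def test_identical_candidates_collapse(self):
        out = deduplicate([self._cand(100, 900, 0), self._cand(100, 900, 1)])
        assert len(out) == 1
        assert out[0].query_index == 0  # query order breaks the tie

    def test_nested_candidates_widest_wins(self):
        out = deduplicate([self._cand(300, 700), self._cand(100, 900)])
        assert [(c.start, c.end) for c in out] == [(100, 900)]

    def test_disjoint_candidates_both_survive(self):
        out = deduplicate([self._cand(100, 900), self._cand(2000, 2800)])
        assert len(out) == 2

    def test_transitive_overlap_single_survivor(self):
        # a-b overlap, b-c overlap, a-c disjoint: still one group
        out = deduplicate([self._cand(100, 600), self._cand(500, 1100), self._cand(1000, 1500)])
        assert [(c.start, c.end) for c in out] == [(500, 1100)]


class TestScanGenome:
    # distinct TSDs per element: neighbouring same-seed elements sit closer
    # than the width window here, so a shared TSD would let cross-element
    # TIR pairs through the (correctly behaving) TSD check
    _TSDS = ("ACGTA", "GGTAC", "TTACG", "CAGTT")

    def _planted_genome(self, rng, n_elements=4, seed="CACTACAATTGGC"):
        bases = np.array(list("ACGT"))
        parts, truth, pos = [], [], 1
        for i in range(n_elements):
            tsd = self._TSDS[i % len(self._TSDS)]
            gap = "".join(bases[rng.integers(0, 4, 500)])
            internal = "".join(bases[rng.integers(0, 4, 380)])
            element = seed + internal + reverse_complement(seed)
            parts.extend([gap, tsd, element, tsd])
            pos += len(gap) + len(tsd)
            truth.append((pos, pos + len(element) - 1))
            pos += len(element) + len(tsd)
        parts.append("".join(bases[rng.integers(0, 4, 500)]))
        return _genome("".join(parts)), truth

    def test_planted_elements_recovered_exactly(self):
        g, truth = self._planted_genome(np.random.default_rng(5))
        q = _query(forward_tir="CACTACAATTGGC", tsd_length=5)
        cands = scan_genome(g, [q])
        assert [(c.start, c.end) for c in cands] == truth
        for c in cands:
            assert c.tsd_distance <= q.max_tsd_mismatch
            assert q.width_min <= c.width <= q.width_max
            assert c.fwd_tir.start < c.rev_tir.start

    def test_outward_facing_search_misses_planted_elements(self):
        g, _ = self._planted_genome(np.random.default_rng(5))
        q = _query(forward_tir="CACTACAATTGGC", tsd_length=5)
        assert scan_genome(g, [q.swapped()]) == []

    def test_empty_genome_scan(self):
        assert scan_genome(_genome(""), [_query()]) == []

    def test_no_queries_rejected(self):
        with pytest.raises(ValueError):
            scan_genome(_genome("ACGT"), [])

    def test_strand_symmetry(self):
        """Scanning the reverse complement of the genome yields the
        mirror-coordinate candidate set."""
        g, _ = self._planted_genome(np.random.default_rng(9))
        q = _query(forward_tir="CACTACAATTGGC", tsd_length=5)
        n = len(g.contigs["c1"])
        fwd = scan_genome(g, [q])
        rev = scan_genome(_genome(reverse_complement(g.contigs["c1"])), [q])
        mirrored = sorted((n - c.end + 1, n - c.start + 1) for c in rev)
        assert sorted((c.start, c.end) for c in fwd) == mirrored

    def test_deterministic(self):
        g, _ = self._planted_genome(np.random.default_rng(13))
        q = _query(forward_tir="CACTACAATTGGC", tsd_length=5, max_tir_mismatch=1)
        a = [(c.start, c.end) for c in scan_genome(g, [q])]
        b = [(c.start, c.end) for c in scan_genome(g, [q])]
        assert a == b


class TestTIRQueryValidation:
    def test_default_reverse_is_reverse_complement(self):
        q = _query(forward_tir="CACTACAA")
        assert q.reverse_tir == "TTGTAGTG"

    def test_motif_sets_tsd_length(self):
        q = _query(tsd_motif="TA")
        assert q.tsd_length == 2

    @pytest.mark.parametrize(
        "kw", [dict(width_min=500, width_max=400), dict(max_tir_mismatch=8),
               dict(forward_tir="CACT")],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            _query(**kw)
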