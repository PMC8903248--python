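"""Approximate TIR search, candidate pairing, TSD verification, deduplication.

This is the first pipeline stage.  A short TIR seed (8-30 nt) is matched
against the genome under a Levenshtein (unit-cost substitution/insertion/
deletion) budget with *semi-global* semantics: the seed must be consumed in
full while the genomic ends of the alignment are free, so hits stay anchored
to roughly seed length.  Forward-seed and reverse-seed hits are then paired
into inward-facing candidates whose total width falls in the superfamily
window (default 300-15,000 bp), candidates are kept only if the flanks
immediately outside the TIRs look like a target-site duplication (flank
Levenshtein distance within budget), and duplicated/overlapping candidates
arising from multiple queries are collapsed.

N is treated as matching nothing (cost 1 against every symbol, including N)
in both TIR and TSD comparisons; genuinely N-rich elements are additionally
removed by the downstream N-fraction filter.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

from packtype.genome_io import GenomeSequences, reverse_complement

logger = logging.getLogger(__name__)

MIN_SEED_LENGTH = 6

# base -> code; N gets its own code and never matches anything (cost 1 even
# against N), so encoded comparison implements the mismatch rule directly.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class TIRQuery:
    """Search parameters for one superfamily.

    Parameters
    ----------
    superfamily : str
        Label used in element ids (e.g. ``CACTA``, ``Mariner``).
    forward_tir : str
        TIR seed as read on the element's 5' end, 8-30 nt.
    reverse_tir : str, optional
        Seed expected at the 3' end on the plus strand; defaults to the
        reverse complement of ``forward_tir``.
    max_tir_mismatch : int
        Levenshtein budget for each TIR match.
    tsd_length : int
        Length of the expected target-site duplication; ``0`` disables the
        TSD filter.  If ``tsd_motif`` is given, its length is used.
    tsd_motif : str, optional
        Superfamily-characteristic TSD motif (e.g. ``TA`` for Mariner);
        recorded for composition summaries, not used as a filter.
    max_tsd_mismatch : int
        Levenshtein budget between the 5' and 3' flanks.
    width_min, width_max : int
        Allowed total element width (outermost TIR bounds), inclusive.
    """

    superfamily: str
    forward_tir: str
    reverse_tir: str = ""
    max_tir_mismatch: int = 0
    tsd_length: int = 0
    tsd_motif: str = ""
    max_tsd_mismatch: int = 0
    width_min: int = 300
    width_max: int = 15000

    def __post_init__(self):
        object.__setattr__(self, "forward_tir", self.forward_tir.upper())
        rev = self.reverse_tir.upper() or reverse_complement(self.forward_tir)
        object.__setattr__(self, "reverse_tir", rev)
        object.__setattr__(self, "tsd_motif", self.tsd_motif.upper())
        if self.tsd_motif and self.tsd_length == 0:
            object.__setattr__(self, "tsd_length", len(self.tsd_motif))
        if len(self.forward_tir) < MIN_SEED_LENGTH:
            raise ValueError(
                f"TIR seed {self.forward_tir!r} shorter than {MIN_SEED_LENGTH} nt"
            )
        if not self.width_min < self.width_max:
            raise ValueError("width_min must be < width_max")
        if not 0 <= self.max_tir_mismatch < len(self.forward_tir):
            raise ValueError("max_tir_mismatch must be in [0, len(seed))")
        if self.max_tsd_mismatch < 0 or self.tsd_length < 0:
            raise ValueError("TSD parameters must be non-negative")

    def swapped(self) -> "TIRQuery":
        """Query with forward and reverse seeds exchanged (outward-facing
        search, used for decoy-based false-positive estimation)."""
        return replace(self, forward_tir=self.reverse_tir, reverse_tir=self.forward_tir)


@dataclass(frozen=True)
class TIRMatch:
    """One approximate TIR hit (1-based inclusive span)."""

    contig_id: str
    start: int
    end: int
    orientation: str  # "forward-seed" | "reverse-seed"
    edit_distance: int

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class CandidateElement:
    """An inward-facing TIR pair with verified flanking TSD."""

    contig_id: str
    start: int
    end: int
    fwd_tir: TIRMatch
    rev_tir: TIRMatch
    query: TIRQuery
    sequence: str = ""
    tsd_5: str = ""
    tsd_3: str = ""
    tsd_distance: int = -1  # -1 until checked
    tsd_motif_match: bool = False
    query_index: int = 0  # order of the generating query, dedup tie-break

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance with N counting as a mismatch against
    everything (including another N)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        a_is_n = ca == "N"
        for j, cb in enumerate(b, 1):
            cost = 0 if (ca == cb and not a_is_n and cb != "N") else 1
            cur.append(min(prev[j - 1] + cost, prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _CODE["N"], dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _semiglobal_end_distances(text: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Sellers DP: minimal edit distance of the full pattern against any
    window of ``text`` ending at each position (1-based end j -> D[j]).

    Row-wise numpy evaluation; the in-row horizontal dependency
    ``D[i][j] <- D[i][j-1] + 1`` is resolved with the cumulative-minimum
    identity ``D[i][j] = j + cummin_k<=j (E[k] - k)`` where E holds the
    diagonal/vertical candidates.
    """
    n = text.size
    js = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int32)  # D[0][j] = 0: free start in text
    n_code = _CODE["N"]
    for i, p in enumerate(pattern, 1):
        cand = np.empty(n + 1, dtype=np.int32)
        cand[0] = i
        if p == n_code:
            cost = np.ones(n, dtype=np.int32)
        else:
            cost = ((text != p) | (text == n_code)).astype(np.int32)
        cand[1:] = np.minimum(prev[:-1] + cost, prev[1:] + 1)
        prev = js + np.minimum.accumulate(cand - js)
    return prev


def _window_distance(window: str, seed: str) -> int:
    return levenshtein(window, seed)


@dataclass(order=True)
class _RawHit:
    start: int
    end: int
    distance: int = field(compare=False)


def _collapse_hits(hits: list[_RawHit]) -> list[_RawHit]:
    """Collapse each connected component of mutually/transitively overlapping
    hits to one survivor: minimum distance, then leftmost start, then
    shortest span."""
    if not hits:
        return []
    hits = sorted(hits)
    out: list[_RawHit] = []
    group: list[_RawHit] = [hits[0]]
    group_end = hits[0].end
    for h in hits[1:]:
        if h.start <= group_end:  # overlaps the running component
            group.append(h)
            group_end = max(group_end, h.end)
        else:
            out.append(min(group, key=lambda g: (g.distance, g.start, g.end - g.start)))
            group = [h]
            group_end = h.end
    out.append(min(group, key=lambda g: (g.distance, g.start, g.end - g.start)))
    return out


def find_tir_matches(
    genome: GenomeSequences, seed: str, budget: int
) -> list[TIRMatch]:
    """Every genomic locus where some substring matches ``seed`` within the
    semi-global Levenshtein ``budget``.

    All windows with edit distance <= budget are enumerated; overlapping
    windows at one locus are collapsed to the minimum-distance, then
    leftmost, then shortest representative.  Results sorted by
    (contig, start).
    """
    seed = seed.upper()
    if len(seed) < MIN_SEED_LENGTH:
        raise ValueError(f"seed {seed!r} shorter than {MIN_SEED_LENGTH} nt: uninformative")
    if not 0 <= budget < len(seed):
        raise ValueError("budget must satisfy 0 <= budget < len(seed)")
    pattern = _encode(seed)
    m = len(seed)
    matches: list[TIRMatch] = []
    for contig_id in genome.contigs:
        text_str = genome.contigs[contig_id]
        n = len(text_str)
        if n == 0:
            continue
        end_dist = _semiglobal_end_distances(_encode(text_str), pattern)
        raw: list[_RawHit] = []
        # sparse verification: enumerate candidate windows only at promising ends
        for j in np.nonzero(end_dist[1:] <= budget)[0] + 1:
            j = int(j)
            lo = max(1, j - m - budget + 1)
            hi = min(j, j - m + budget + 1)
            if j < m - budget:  # window shorter than m-budget cannot reach distance<=budget
                continue
            for s in range(lo, max(lo, hi) + 1):
                if s > j:
                    continue
                wlen = j - s + 1
                if not (m - budget <= wlen <= m + budget):
                    continue
                d = _window_distance(text_str[s - 1 : j], seed)
                if d <= budget:
                    raw.append(_RawHit(start=s, end=j, distance=d))
        for h in _collapse_hits(raw):
            matches.append(
                TIRMatch(
                    contig_id=contig_id,
                    start=h.start,
                    end=h.end,
                    orientation="forward-seed",
                    edit_distance=h.distance,
                )
            )
    matches.sort(key=lambda t: (t.contig_id, t.start))
    return matches


def pair_candidates(
    fwd: list[TIRMatch], rev: list[TIRMatch], query: TIRQuery, query_index: int = 0
) -> list[CandidateElement]:
    """All inward-facing (forward-hit, reverse-hit) pairs on one contig whose
    outermost span width lies in the query window.  Nested and overlapping
    pairings are all emitted; resolution happens in :func:`deduplicate`."""
    by_contig: dict[str, list[TIRMatch]] = {}
    for r in rev:
        by_contig.setdefault(r.contig_id, []).append(r)
    for contig_rev in by_contig.values():
        contig_rev.sort(key=lambda t: t.end)
    out: list[CandidateElement] = []
    for f in fwd:
        revs = by_contig.get(f.contig_id)
        if not revs:
            continue
        ends = [r.end for r in revs]
        lo = bisect_left(ends, f.start + query.width_min - 1)
        hi = bisect_right(ends, f.start + query.width_max - 1)
        for r in revs[lo:hi]:
            if r.start <= f.start:
                continue
            out.append(
                CandidateElement(
                    contig_id=f.contig_id,
                    start=f.start,
                    end=r.end,
                    fwd_tir=f,
                    rev_tir=replace(r, orientation="reverse-seed"),
                    query=query,
                    query_index=query_index,
                )
            )
    out.sort(key=lambda c: (c.contig_id, c.start, c.end))
    return out


def check_tsd(genome: GenomeSequences, cand: CandidateElement) -> CandidateElement | None:
    """Verify the target-site duplication flanking a candidate.

    The TSD is read flush to the element boundaries: ``tsd_length`` bases
    immediately 5' of the start and immediately 3' of the end.  The candidate
    is kept iff the Levenshtein distance between the two flanks is within
    the query budget.  Elements flush with a contig edge are rejected (the
    TSD filter is mandatory).  When the query names a fixed motif, whether
    the 5' flank equals it is recorded for composition summaries only.
    """
    q = cand.query
    L = q.tsd_length
    if L == 0:
        cand.tsd_distance = 0
        cand.sequence = genome.slice(cand.contig_id, cand.start, cand.end)
        return cand
    clen = len(genome.contigs[cand.contig_id])
    if cand.start - L < 1 or cand.end + L > clen:
        logger.debug(
            "rejecting %s:%d-%d: no room for %d nt TSD flank",
            cand.contig_id, cand.start, cand.end, L,
        )
        return None
    tsd_5 = genome.slice(cand.contig_id, cand.start - L, cand.start - 1)
    tsd_3 = genome.slice(cand.contig_id, cand.end + 1, cand.end + L)
    d = levenshtein(tsd_5, tsd_3)
    if d > q.max_tsd_mismatch:
        return None
    cand.tsd_5, cand.tsd_3, cand.tsd_distance = tsd_5, tsd_3, d
    cand.tsd_motif_match = bool(q.tsd_motif) and tsd_5 == q.tsd_motif
    cand.sequence = genome.slice(cand.contig_id, cand.start, cand.end)
    return cand


def deduplicate(cands: list[CandidateElement]) -> list[CandidateElement]:
    """Among each set of candidates with overlapping genomic spans keep
    exactly one: the widest, ties broken by leftmost start, then by query
    order.  Output sorted by (contig, start)."""
    out: list[CandidateElement] = []
    by_contig: dict[str, list[CandidateElement]] = {}
    for c in cands:
        by_contig.setdefault(c.contig_id, []).append(c)
    for contig_id in sorted(by_contig):
        group: list[CandidateElement] = []
        group_end = -1
        for c in sorted(by_contig[contig_id], key=lambda c: (c.start, c.end)):
            if group and c.start > group_end:
                out.append(min(group, key=lambda g: (-g.width, g.start, g.query_index)))
                group = []
                group_end = -1
            group.append(c)
            group_end = max(group_end, c.end)
        if group:
            out.append(min(group, key=lambda g: (-g.width, g.start, g.query_index)))
    out.sort(key=lambda c: (c.contig_id, c.start))
    return out


def scan_genome(
    genome: GenomeSequences, queries: list[TIRQuery]
) -> list[CandidateElement]:
    """Stage 1 orchestration: per query, approximate-match both TIR seeds,
    pair inward-facing hits, verify TSDs and deduplicate; then merge all
    queries and deduplicate again.  Deterministic for fixed inputs."""
    if not queries:
        raise ValueError("at least one TIRQuery is required")
    merged: list[CandidateElement] = []
    for qi, q in enumerate(queries):
        fwd = find_tir_matches(genome, q.forward_tir, q.max_tir_mismatch)
        rev = find_tir_matches(genome, q.reverse_tir, q.max_tir_mismatch)
        cands = pair_candidates(fwd, rev, q, query_index=qi)
        checked = [c for c in (check_tsd(genome, c) for c in cands) if c is not None]
        merged.extend(deduplicate(checked))
    return deduplicate(merged)
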