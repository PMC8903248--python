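"""Family building: N filter, greedy centroid clustering, orientation.

Candidates are first screened for wildcard content (>10% N removed), then
grouped into families by greedy centroid clustering at 60% global identity:
candidates are processed in decreasing width order and each either joins the
first existing centroid it matches at or above the identity threshold (on
either strand) or founds a new centroid.  Identity is matching columns over
alignment length of the edit-distance-optimal global alignment.  Singleton
families are removed on the assumption that real transposons are repeated in
the genome, and each surviving family is oriented by declaring its largest
member forward and aligning the rest against it on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from packtype.genome_io import reverse_complement
from packtype.tir_search import CandidateElement

_CIGAR_LEN = re.compile(r"(\d+)")

DEFAULT_IDENTITY = 0.60
DEFAULT_MAX_N_FRACTION = 0.10


def global_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the edit-distance-optimal global
    alignment of ``a`` and ``b`` (matches / alignment length)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    aln_len = sum(int(x) for x in _CIGAR_LEN.findall(res["cigar"]))
    return 1.0 - res["editDistance"] / aln_len


def best_strand_identity(a: str, b: str) -> tuple[float, str]:
    """Max global identity of ``a`` vs ``b`` over both strands of ``a``.

    Returns (identity, strand) with strand "+" for as-given, "-" for
    reverse complement; exact ties resolve to "+".
    """
    plus = global_identity(a, b)
    minus = global_identity(reverse_complement(a), b)
    return (plus, "+") if plus >= minus else (minus, "-")


@dataclass
class Cluster:
    """A family of candidate elements.

    The representative is the maximum-width member and is forward ("+") by
    convention; other members carry the strand on which they best align to
    it.  Member ids are positional indices into the candidate list handed to
    :func:`cluster_elements`.
    """

    cluster_id: int
    member_ids: list[int] = field(default_factory=list)
    representative_id: int = -1
    member_orientation: dict[int, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def filter_n_content(
    cands: list[CandidateElement], max_frac: float = DEFAULT_MAX_N_FRACTION
) -> list[CandidateElement]:
    """Keep candidates whose N fraction is at most ``max_frac`` (default:
    sequences with >10% wildcard nucleotides are removed)."""
    out = []
    for c in cands:
        if not c.sequence:
            raise ValueError("candidate has no attached sequence")
        if c.sequence.count("N") / c.width <= max_frac:
            out.append(c)
    return out


def _processing_order(cands: list[CandidateElement]) -> list[int]:
    return sorted(
        range(len(cands)),
        key=lambda i: (-cands[i].width, cands[i].contig_id, cands[i].start),
    )


def cluster_elements(
    cands: list[CandidateElement], identity_threshold: float = DEFAULT_IDENTITY
) -> list[Cluster]:
    """Greedy centroid clustering of candidate sequences.

    Width-descending processing (ties by contig, then start) makes the
    outcome independent of input order; each candidate joins the first
    centroid, in founding order, reaching ``identity_threshold`` on either
    strand, else founds a new cluster.  Cluster ids here are provisional
    founding indices; :func:`remove_singletons` renumbers survivors.
    """
    clusters: list[Cluster] = []
    centroid_seq: list[str] = []
    for idx in _processing_order(cands):
        seq = cands[idx].sequence
        for k, cl in enumerate(clusters):
            ident, _ = best_strand_identity(seq, centroid_seq[k])
            if ident >= identity_threshold:
                cl.member_ids.append(idx)
                break
        else:
            clusters.append(Cluster(cluster_id=len(clusters) + 1, member_ids=[idx]))
            centroid_seq.append(seq)
    for cl in clusters:
        cl.representative_id = cl.member_ids[0]  # first member = widest
    return clusters


def remove_singletons(
    clusters: list[Cluster], cands: list[CandidateElement] | None = None
) -> list[Cluster]:
    """Drop size-1 clusters and renumber survivors 1..K in decreasing size,
    ties by first genomic occurrence of any member (requires ``cands``;
    falls back to founding order when not given)."""
    surviving = [cl for cl in clusters if cl.size >= 2]

    def first_occurrence(cl: Cluster):
        if cands is None:
            return (cl.cluster_id,)
        return min((cands[i].contig_id, cands[i].start) for i in cl.member_ids)

    surviving.sort(key=lambda cl: (-cl.size, first_occurrence(cl)))
    out = []
    for new_id, cl in enumerate(surviving, 1):
        out.append(
            Cluster(
                cluster_id=new_id,
                member_ids=list(cl.member_ids),
                representative_id=cl.representative_id,
                member_orientation=dict(cl.member_orientation),
            )
        )
    return out


def assign_orientation(
    cluster: Cluster, sequences: dict[int, str]
) -> dict[int, str]:
    """Orient cluster members relative to the representative.

    The representative (largest member) is "+" by convention; every other
    member takes the strand on which its global alignment to the
    representative has the higher identity, exact ties resolving to "+".
    """
    if cluster.size < 2:
        raise ValueError("orientation is defined for clusters of size >= 2")
    rep = cluster.representative_id
    rep_seq = sequences[rep]
    orientation = {rep: "+"}
    for mid in cluster.member_ids:
        if mid == rep:
            continue
        _, strand = best_strand_identity(sequences[mid], rep_seq)
        orientation[mid] = strand
    cluster.member_orientation = orientation
    return orientation


def build_families(
    cands: list[CandidateElement],
    identity_threshold: float = DEFAULT_IDENTITY,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> tuple[list[CandidateElement], list[Cluster]]:
    """Stage 2 orchestration: N filter -> cluster -> drop singletons ->
    orient.  Returns the filtered candidate list (which cluster member ids
    index into) and the final clusters."""
    kept = filter_n_content(cands, max_n_fraction)
    clusters = remove_singletons(cluster_elements(kept, identity_threshold), kept)
    seqs = {i: c.sequence for i, c in enumerate(kept)}
    for cl in clusters:
        assign_orientation(cl, seqs)
    return kept, clusters
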