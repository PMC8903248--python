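"""Post-annotation family statistics.

Four analyses of an annotated element set:

* TIR relatedness — alignment-free k-mer (k=5) distances between the first
  80 bp (the forward TIR side) of all elements, with complete-linkage
  hierarchical grouping; recovers superfamily structure without alignment.
* Local hopping — Class II transposons tend to reinsert near their donor
  locus, so members of one family should lie within 100 kb of each other
  more often than unrelated elements do; tested per cluster with a
  one-sided chi-squared on the 2x2 proportion table, pooled across the
  clusters of a superfamily.
* Orientation concordance — the fraction of local same-family pairs
  inserted in the same orientation.
* TSD composition — frequency table of 5' TSD sequences, e.g. the "TA"
  hallmark of Mariner elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from packtype.genome_io import AnnotationRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000  # bp
DEFAULT_TIR_PREFIX = 80  # bp
DEFAULT_KMER = 5


@dataclass(frozen=True)
class LocalPair:
    """An unordered pair of elements on one contig within the window.

    ``distance`` is the gap between the closest ends of the two elements
    (0 when they overlap).
    """

    element_a: str
    element_b: str
    distance: int
    same_cluster: bool
    same_orientation: bool


@dataclass
class TIRDistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        self.d = d


def kmer_set(seq: str, k: int = DEFAULT_KMER) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_jaccard_distance(a: str, b: str, k: int = DEFAULT_KMER) -> float:
    """1 - |shared distinct k-mers| / |union of distinct k-mers|."""
    sa, sb = kmer_set(a, k), kmer_set(b, k)
    union = sa | sb
    if not union:
        return 0.0
    return 1.0 - len(sa & sb) / len(union)


def tir_distance_matrix(
    sequences: dict[str, str],
    prefix_len: int = DEFAULT_TIR_PREFIX,
    k: int = DEFAULT_KMER,
) -> TIRDistanceMatrix:
    """Pairwise k-mer distances between element TIR prefixes.

    ``sequences`` maps element id to its *oriented* (forward per cluster
    convention) sequence; the first ``prefix_len`` bases represent the
    forward TIR side.  Elements shorter than the prefix are used whole with
    a warning.
    """
    ids = sorted(sequences)
    prefixes = {}
    for eid in ids:
        seq = sequences[eid]
        if len(seq) < prefix_len:
            logger.warning(
                "element %s shorter than %d bp; using full sequence", eid, prefix_len
            )
        prefixes[eid] = seq[:prefix_len]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_jaccard_distance(prefixes[ids[i]], prefixes[ids[j]], k)
    return TIRDistanceMatrix(ids=ids, d=d)


def cluster_tir_matrix(
    m: TIRDistanceMatrix, n_groups: int = 6
) -> tuple[dict[str, int], list[str]]:
    """Complete-linkage hierarchical clustering of the TIR distance matrix,
    cut into ``n_groups``.  Returns id -> group label (1..n_groups) and the
    dendrogram leaf order.  Ids are pre-sorted, making the outcome invariant
    to the caller's input ordering."""
    n = len(m.ids)
    if n_groups > n:
        raise ValueError("n_groups cannot exceed the number of elements")
    if n == 1:
        return {m.ids[0]: 1}, list(m.ids)
    Z = linkage(squareform(m.d, checks=False), method="complete")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    leaf_order = [m.ids[i] for i in dendrogram(Z, no_plot=True)["leaves"]]
    return dict(zip(m.ids, (int(x) for x in labels))), leaf_order


def _gap(a: AnnotationRecord, b: AnnotationRecord) -> int:
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


def find_local_pairs(
    records: list[AnnotationRecord], window: int = DEFAULT_WINDOW
) -> list[LocalPair]:
    """All unordered same-contig element pairs whose gap is at most
    ``window``, flagged for family and orientation agreement."""
    by_contig: dict[str, list[AnnotationRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    pairs: list[LocalPair] = []
    for contig_records in by_contig.values():
        contig_records.sort(key=lambda r: (r.start, r.end))
        for i, a in enumerate(contig_records):
            for b in contig_records[i + 1 :]:
                if b.start - a.end - 1 > window and b.start > a.end:
                    break  # sorted by start: later b only farther
                gap = _gap(a, b)
                if gap > window:
                    continue
                pairs.append(
                    LocalPair(
                        element_a=a.element_id,
                        element_b=b.element_id,
                        distance=gap,
                        same_cluster=(
                            a.cluster_id is not None and a.cluster_id == b.cluster_id
                        ),
                        same_orientation=(
                            a.strand in "+-" and a.strand == b.strand
                        ),
                    )
                )
    return pairs


def chi2_one_sided(table: np.ndarray) -> float:
    """One-sided chi-squared test that the first row's success proportion
    exceeds the second's, on a 2x2 count table [[a, b], [c, d]] with
    successes in the first column.  No continuity correction.  The one-sided
    p is half the two-sided p when the observed direction is positive, else
    one minus that half.  Degenerate margins give p = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        logger.debug("degenerate 2x2 margins; returning p=1")
        return 1.0
    stat = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p_two = float(chi2.sf(stat, df=1))
    p1, p2 = a / row1, c / row2
    return p_two / 2 if p1 > p2 else 1 - p_two / 2


def local_hopping_counts(
    records: list[AnnotationRecord],
    cluster_id: int,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """2x2 table for one cluster: members with/without a cluster-mate within
    the window (row 1) versus non-members with/without a *member of this
    cluster* within the window (row 2)."""
    members = [r for r in records if r.cluster_id == cluster_id]
    others = [r for r in records if r.cluster_id != cluster_id]
    if len(members) < 2:
        raise ValueError("cluster must have at least 2 members")
    if not others:
        raise ValueError("at least one non-member element is required")

    def near(r: AnnotationRecord, pool: list[AnnotationRecord]) -> bool:
        return any(
            p is not r and p.contig_id == r.contig_id and _gap(r, p) <= window
            for p in pool
        )

    a = sum(near(r, members) for r in members)
    c = sum(near(r, members) for r in others)
    return np.array([[a, len(members) - a], [c, len(others) - c]], dtype=float)


def local_hopping_test(
    records: list[AnnotationRecord],
    cluster_id: int | None = None,
    window: int = DEFAULT_WINDOW,
) -> float:
    """One-sided p-value for local-hopping enrichment.

    With ``cluster_id`` given, tests that single cluster; with ``None``,
    pools the 2x2 counts over every cluster present in ``records`` that has
    >= 2 members (the superfamily-level aggregate), then applies one test.
    """
    if cluster_id is not None:
        return chi2_one_sided(local_hopping_counts(records, cluster_id, window))
    cluster_ids = sorted(
        {r.cluster_id for r in records if r.cluster_id is not None}
    )
    pooled = np.zeros((2, 2))
    tested = 0
    for cid in cluster_ids:
        try:
            pooled += local_hopping_counts(records, cid, window)
            tested += 1
        except ValueError:
            continue
    if tested == 0:
        raise ValueError("no testable cluster (need >=2 members and >=1 non-member)")
    return chi2_one_sided(pooled)


def orientation_concordance(pairs: list[LocalPair]) -> float | None:
    """Fraction of same-cluster local pairs inserted in the same
    orientation; ``None`` when there are no such pairs."""
    same_cluster = [p for p in pairs if p.same_cluster]
    if not same_cluster:
        return None
    return sum(p.same_orientation for p in same_cluster) / len(same_cluster)


def tsd_composition(
    records: list[AnnotationRecord], motif: str
) -> tuple[float, dict[str, int]]:
    """Fraction of elements whose 5' TSD equals ``motif`` exactly, plus the
    full TSD frequency table."""
    table: dict[str, int] = {}
    for r in records:
        table[r.tsd_seq_5] = table.get(r.tsd_seq_5, 0) + 1
    n = len(records)
    frac = (table.get(motif.upper(), 0) / n) if n else 0.0
    return frac, dict(sorted(table.items(), key=lambda kv: (-kv[1], kv[0])))
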