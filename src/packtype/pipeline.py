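"""End-to-end annotation: scan -> families -> classification -> records.

Ties the three pipeline stages together and converts the result into
:class:`~packtype.genome_io.AnnotationRecord` objects with stable
identifiers (``<genome prefix>-<superfamily>-<N>``, N counting in genomic
order per superfamily).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from packtype.classify import CDS_MIN_ALIGN, classify_all
from packtype.clustering import Cluster, build_families
from packtype.genome_io import AnnotationRecord, GenomeSequences, reverse_complement
from packtype.tir_search import CandidateElement, TIRQuery, scan_genome


@dataclass
class AnnotationResult:
    """Everything the pipeline produced: final records, the clusters (member
    ids index ``candidates``), and the post-filter candidate list."""

    records: list[AnnotationRecord] = field(default_factory=list)
    clusters: list[Cluster] = field(default_factory=list)
    candidates: list[CandidateElement] = field(default_factory=list)

    def oriented_sequence(self, record: AnnotationRecord, genome: GenomeSequences) -> str:
        seq = genome.slice(record.contig_id, record.start, record.end)
        return reverse_complement(seq) if record.strand == "-" else seq


def annotate(
    genome: GenomeSequences,
    queries: list[TIRQuery],
    transposase_db: dict[str, str] | None = None,
    cds_db: dict[str, str] | None = None,
    genome_prefix: str = "Gx",
    identity_threshold: float = 0.60,
    max_n_fraction: float = 0.10,
    backend: str = "internal",
    cds_min_len: int = CDS_MIN_ALIGN,
) -> AnnotationResult:
    """Run the full pipeline and return annotated records.

    Classification needs both reference sets; with either missing every
    element is categorised from the hits that are available (no transposase
    set => nothing can be autonomous, etc.).
    """
    cands = scan_genome(genome, queries)
    kept, clusters = build_families(
        cands, identity_threshold=identity_threshold, max_n_fraction=max_n_fraction
    )

    member_info: dict[int, tuple[int, str]] = {}  # cand idx -> (cluster_id, strand)
    for cl in clusters:
        for mid in cl.member_ids:
            member_info[mid] = (cl.cluster_id, cl.member_orientation[mid])

    keys = sorted(member_info, key=lambda i: (kept[i].contig_id, kept[i].start))
    seqs = {}
    for i in keys:
        c = kept[i]
        strand = member_info[i][1]
        seqs[f"cand{i}"] = reverse_complement(c.sequence) if strand == "-" else c.sequence
    categories = classify_all(
        seqs,
        transposase_db or {},
        cds_db or {},
        backend=backend,
        cds_min_len=cds_min_len,
    )

    records: list[AnnotationRecord] = []
    counters: dict[str, int] = {}
    for i in keys:
        c = kept[i]
        cluster_id, strand = member_info[i]
        sf = c.query.superfamily
        counters[sf] = counters.get(sf, 0) + 1
        records.append(
            AnnotationRecord(
                contig_id=c.contig_id,
                start=c.start,
                end=c.end,
                strand=strand,
                element_id=f"{genome_prefix}-{sf}-{counters[sf]}",
                superfamily=sf,
                category=categories[f"cand{i}"],
                cluster_id=cluster_id,
                tsd_seq_5=c.tsd_5,
                tsd_seq_3=c.tsd_3,
            )
        )
    return AnnotationResult(records=records, clusters=clusters, candidates=kept)
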