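"""Genome and annotation input/output.

All coordinates in this package are 1-based and inclusive on both ends
(GFF3 convention); any half-open arithmetic is converted at the boundary
of this module.  Sequences are stored uppercase over the alphabet
``A C G T N``; IUPAC ambiguity codes other than N are masked to N on read
(the pipeline has a downstream N-fraction filter, so masking is safer than
rejecting real reference genomes).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Fixed column order of the annotation TSV mirror.
TSV_COLUMNS = [
    "element_id", "contig_id", "start", "end", "strand", "superfamily",
    "category", "cluster_id", "tsd_seq_5", "tsd_seq_3",
]


@dataclass
class GenomeSequences:
    """An in-memory genome: ordered mapping of contig id to sequence.

    Attributes
    ----------
    contigs : dict of str -> str
        Contig id to uppercase nucleotide string (A/C/G/T/N only).
    """

    contigs: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}

    def __len__(self) -> int:
        return len(self.contigs)

    def slice(self, contig_id: str, start: int, end: int) -> str:
        """Return the sequence of ``contig_id`` between 1-based inclusive bounds."""
        seq = self.contigs[contig_id]
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"span {contig_id}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]


@dataclass
class AnnotationRecord:
    """One annotated element: coordinates plus pipeline metadata.

    ``strand`` is meaningful only after cluster orientation has been
    assigned; by convention the largest element of each cluster is "+".
    """

    contig_id: str
    start: int
    end: int
    strand: str = "."
    element_id: str = ""
    superfamily: str = ""
    category: str = ""
    cluster_id: int | None = None
    tsd_seq_5: str = ""
    tsd_seq_3: str = ""

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def validate(self, genome: GenomeSequences) -> None:
        if self.contig_id not in genome.contigs:
            raise ValueError(f"unknown contig {self.contig_id!r}")
        clen = len(genome.contigs[self.contig_id])
        if not (1 <= self.start <= self.end <= clen):
            raise ValueError(
                f"record {self.element_id or '?'} at {self.contig_id}:"
                f"{self.start}-{self.end} outside contig bounds (1..{clen})"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (N maps to N).

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(raw: str, contig_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(_NON_ACGTN.findall(seq))
    if bad:
        logger.warning(
            "contig %s: masking %d non-ACGTN symbol(s) %s to N",
            contig_id, sum(seq.count(b) for b in bad), sorted(bad),
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def read_fasta(path: str | Path) -> GenomeSequences:
    """Read a FASTA file into :class:`GenomeSequences`.

    Sequences are uppercased; ambiguity codes other than N are masked to N
    with a logged warning.  An empty file or a duplicate header is an error.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        contigs[rec.id] = _clean_sequence(str(rec.seq), rec.id)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequences(contigs=contigs)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write a mapping of id -> sequence as FASTA (60-column wrapped)."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def element_sequence(record: AnnotationRecord, genome: GenomeSequences) -> str:
    """Oriented sequence of an element: minus-strand records are reverse-complemented."""
    s = genome.slice(record.contig_id, record.start, record.end)
    return reverse_complement(s) if record.strand == "-" else s


# -- GFF3 ------------------------------------------------------------------

_GFF_SOURCE = "packtype"
_GFF_TYPE = "terminal_inverted_repeat_element"  # SO:0000208


def _gff_attributes(r: AnnotationRecord) -> str:
    parts = []
    if r.element_id:
        parts.append(f"ID={r.element_id}")
    if r.superfamily:
        parts.append(f"superfamily={r.superfamily}")
    if r.category:
        parts.append(f"category={r.category}")
    if r.cluster_id is not None:
        parts.append(f"cluster={r.cluster_id}")
    if r.tsd_seq_5:
        parts.append(f"tsd_5={r.tsd_seq_5}")
    if r.tsd_seq_3:
        parts.append(f"tsd_3={r.tsd_seq_3}")
    return ";".join(parts) or "."


def write_gff3(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            strand = r.strand if r.strand in "+-" else "."
            fh.write(
                "\t".join(
                    [
                        r.contig_id, _GFF_SOURCE, _GFF_TYPE,
                        str(r.start), str(r.end), ".", strand, ".",
                        _gff_attributes(r),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Read flat element features from a GFF3 file written by this package
    (or any GFF3 whose features are flat records with compatible attributes)."""
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs: dict[str, str] = {}
            for kv in cols[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip()] = v.strip()
            records.append(
                AnnotationRecord(
                    contig_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else ".",
                    element_id=attrs.get("ID", ""),
                    superfamily=attrs.get("superfamily", ""),
                    category=attrs.get("category", ""),
                    cluster_id=int(attrs["cluster"]) if "cluster" in attrs else None,
                    tsd_seq_5=attrs.get("tsd_5", ""),
                    tsd_seq_3=attrs.get("tsd_3", ""),
                )
            )
    return records


def write_outputs(
    records: list[AnnotationRecord],
    genome: GenomeSequences,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write the three standard outputs for a set of annotated elements.

    ``<prefix>.gff3``  one feature per element with ID/superfamily/category/
    cluster/TSD attributes; ``<prefix>.tsv``  the same fields as a flat
    table; ``<prefix>.fasta``  element sequences oriented per strand.

    Records out of contig bounds raise before anything is written.
    """
    import pandas as pd

    for r in records:
        r.validate(genome)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": out_prefix.with_suffix(".gff3"),
        "tsv": out_prefix.with_suffix(".tsv"),
        "fasta": out_prefix.with_suffix(".fasta"),
    }
    write_gff3(records, paths["gff3"])
    pd.DataFrame(
        [
            {
                "element_id": r.element_id,
                "contig_id": r.contig_id,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "superfamily": r.superfamily,
                "category": r.category,
                "cluster_id": "" if r.cluster_id is None else r.cluster_id,
                "tsd_seq_5": r.tsd_seq_5,
                "tsd_seq_3": r.tsd_seq_3,
            }
            for r in records
        ],
        columns=TSV_COLUMNS,
    ).to_csv(paths["tsv"], sep="\t", index=False)
    write_fasta(
        {(r.element_id or f"{r.contig_id}:{r.start}-{r.end}"): element_sequence(r, genome)
         for r in records},
        paths["fasta"],
    )
    return paths
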