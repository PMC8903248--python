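"""Synthetic genomes with planted ground truth.

The generator emulates the sequence structures the pipeline assumes, at desk
scale: an i.i.d. background at a configurable GC content into which it
plants

* family members — inward-facing TIR pairs flanked by a target-site
  duplication, sharing a mutated copy of a family "master" internal
  sequence (optionally carrying a captured fragment from a CDS or
  transposase reference, which fixes the family's true category);
* outward-facing decoys — the same construction with the TIR orientations
  swapped, detectable only by a reversed-TIR search;
* singleton families — structurally valid one-off elements that the
  singleton filter should remove;
* N-rich elements — structurally valid elements whose internal sequence
  exceeds the wildcard threshold, removed by the N filter.

Same-seed insertions are spaced further apart than the pairing window's
upper width bound so that TIRs of *different* planted elements can never
pair into a spurious candidate; deliberate "local hop" placements put
family mates within 100 kb (but beyond the width window) in the same
orientation, giving the family statistics a planted signal.

Everything is driven by one integer seed: identical config + seed gives a
byte-identical genome and truth set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from packtype.genome_io import AnnotationRecord, GenomeSequences, reverse_complement
from packtype.tir_search import TIRQuery

_BASES = np.array(list("ACGT"))

FRAGMENT_SOURCES = ("none", "cds_db", "transposase_db")


@dataclass(frozen=True)
class FamilySpec:
    """One planted family: its TIR/TSD character and member structure.

    ``tir_divergence`` edits (substitution/insertion/deletion, uniform) are
    applied independently to each TIR copy of each member, so a scan budget
    of at least ``tir_divergence`` recovers every member.  ``fragment_length``
    bases from the named reference are spliced near the start of the family
    master's internal sequence; with ``none`` the family is truly non-Pack.
    """

    superfamily: str
    tir_seed: str
    n_members: int
    tsd_length: int = 5
    tsd_motif: str = ""
    tsd_motif_fraction: float = 1.0  # members whose TSD is exactly the motif
    width_min: int = 520
    width_max: int = 640
    tir_divergence: int = 0
    tsd_divergence: int = 0
    captured_fragment_source: str = "none"
    fragment_length: int = 0
    local_hop_fraction: float = 0.0
    n_reverse: int = 0  # members inserted reverse-complemented (never the widest)

    def __post_init__(self):
        if self.captured_fragment_source not in FRAGMENT_SOURCES:
            raise ValueError(f"captured_fragment_source must be one of {FRAGMENT_SOURCES}")
        if self.tir_seed == reverse_complement(self.tir_seed):
            raise ValueError("palindromic TIR seed: forward and reverse hits coincide")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not self.width_min < self.width_max:
            raise ValueError("width_min must be < width_max")

    @property
    def effective_tsd_length(self) -> int:
        return len(self.tsd_motif) if self.tsd_motif else self.tsd_length

    @property
    def category(self) -> str:
        if self.captured_fragment_source == "transposase_db" and self.fragment_length > 250:
            return "autonomous"
        if self.captured_fragment_source != "none" and self.fragment_length > 50:
            return "pack"
        return "non_pack"


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic genome; ``seed`` is mandatory."""

    seed: int
    families: tuple[FamilySpec, ...]
    genome_length: int = 1_000_000
    gc_content: float = 0.40
    n_outward_decoys: int = 0
    n_singletons: int = 0
    n_n_rich: int = 0
    decoy_divergence: tuple[int, ...] = ()  # cycled over decoys; default: family divergence
    n_rich_fraction: float = 0.15  # N fraction inside N-rich elements
    edge_margin: int = 5000
    min_insert_gap: int = 1000  # background-coordinate gap between any two insertions
    hop_window: int = 100_000

    def __post_init__(self):
        if not self.families:
            raise ValueError("at least one family is required")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")

    def queries(
        self,
        tir_budget: int | None = None,
        tsd_budget: int | None = None,
        width_min: int = 300,
        width_max: int = 15000,
    ) -> list[TIRQuery]:
        """TIR queries matching the planted families (singleton pseudo-family
        queries included).  Budgets default to each family's own divergence."""
        out = []
        for fam in self.families:
            out.append(
                TIRQuery(
                    superfamily=fam.superfamily,
                    forward_tir=fam.tir_seed,
                    max_tir_mismatch=fam.tir_divergence if tir_budget is None else tir_budget,
                    tsd_length=fam.effective_tsd_length,
                    tsd_motif=fam.tsd_motif,
                    max_tsd_mismatch=fam.tsd_divergence if tsd_budget is None else tsd_budget,
                    width_min=width_min,
                    width_max=width_max,
                )
            )
        for i, seed in enumerate(_singleton_seeds(self), 1):
            out.append(
                TIRQuery(
                    superfamily=f"single{i}",
                    forward_tir=seed,
                    max_tir_mismatch=0 if tir_budget is None else tir_budget,
                    tsd_length=5,
                    max_tsd_mismatch=0 if tsd_budget is None else tsd_budget,
                    width_min=width_min,
                    width_max=width_max,
                )
            )
        return out

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["families"] = [asdict(f) for f in self.families]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        d["families"] = tuple(FamilySpec(**f) for f in d["families"])
        for key in ("decoy_divergence",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthSet:
    """Planted ground truth.  ``planted`` are the compliant family members
    (cluster_id = 1-based family index, category = family category);
    ``singletons`` and ``n_rich`` are structurally valid elements the
    pipeline should find and then discard; ``decoys`` are outward-facing."""

    planted: list[AnnotationRecord] = field(default_factory=list)
    decoys: list[AnnotationRecord] = field(default_factory=list)
    singletons: list[AnnotationRecord] = field(default_factory=list)
    n_rich: list[AnnotationRecord] = field(default_factory=list)

    def all_detectable(self) -> list[AnnotationRecord]:
        """Everything an inward-facing scan should report before filtering."""
        return self.planted + self.singletons + self.n_rich


# -- low-level helpers ------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _apply_edits(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_edits`` uniform random edits (substitution to a
    different base / insertion / deletion)."""
    s = list(seq)
    for _ in range(n_edits):
        kind = rng.integers(3)
        if kind == 0 or len(s) <= 1:  # substitution
            i = int(rng.integers(len(s)))
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
        elif kind == 1:  # insertion
            i = int(rng.integers(len(s) + 1))
            s.insert(i, str(rng.choice(list("ACGT"))))
        else:  # deletion
            del s[int(rng.integers(len(s)))]
    return "".join(s)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point-mutate each base independently (substitutions only)."""
    s = list(seq)
    for i in np.nonzero(rng.random(len(s)) < rate)[0]:
        s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    return "".join(s)


def _singleton_seeds(config: SimulationConfig) -> list[str]:
    """Deterministic TIR seeds for singleton pseudo-families, derived from
    the config seed (independent of the main placement RNG)."""
    rng = np.random.default_rng((config.seed, 0x51A6))
    seeds = []
    while len(seeds) < config.n_singletons:
        s = _random_dna(rng, 13)
        if s != reverse_complement(s) and s not in seeds:
            seeds.append(s)
    return seeds


def _distinct_master(
    rng: np.random.Generator, length: int, accepted: list[str], max_identity: float = 0.55
) -> str:
    """Rejection-sample a family master internal sequence whose global
    identity to every previously accepted master is at most ``max_identity``
    (the random-DNA baseline under edit-distance alignment is ~0.53)."""
    from packtype.clustering import global_identity

    for _ in range(200):
        cand = _random_dna(rng, length)
        if all(global_identity(cand, m) <= max_identity for m in accepted):
            return cand
    raise RuntimeError("could not sample a sufficiently distinct family master")


@dataclass
class _Insert:
    bg_pos: int = 0
    insert_seq: str = ""
    element_offset: int = 0  # offset of element start within insert_seq
    element_len: int = 0
    record: AnnotationRecord | None = None
    kind: str = "planted"  # planted | decoy | singleton | n_rich
    seed_group: str = ""
    hop_mate: int | None = None  # index into the insert list


def _place(
    rng: np.random.Generator,
    inserts: list[_Insert],
    config: SimulationConfig,
    same_group_gap: int,
) -> None:
    """Assign background positions respecting the global minimum gap, the
    same-seed-group separation, and local-hop adjacency."""
    lo, hi = config.edge_margin, config.genome_length - config.edge_margin
    if hi <= lo:
        raise ValueError("genome too short for the configured edge margin")
    placed: list[int] = []

    def ok(p: int, group: str) -> bool:
        for q, ins in zip(placed, inserts):
            if abs(p - q) < config.min_insert_gap:
                return False
            if ins.seed_group == group and abs(p - q) < same_group_gap:
                return False
        return True

    for idx, ins in enumerate(inserts):
        for _ in range(20_000):
            if ins.hop_mate is not None:
                mate_p = inserts[ins.hop_mate].bg_pos
                gap = int(rng.integers(same_group_gap, min(config.hop_window - 10_000,
                                                           same_group_gap + 60_000)))
                p = mate_p + gap if rng.random() < 0.5 else mate_p - gap
                if not lo <= p <= hi:
                    continue
            else:
                p = int(rng.integers(lo, hi))
            if ok(p, ins.seed_group):
                ins.bg_pos = p
                placed.append(p)
                break
        else:
            raise RuntimeError(
                f"infeasible packing: could not place insertion {idx} "
                f"({ins.kind}, group {ins.seed_group})"
            )


def _build_tsds(
    fam: FamilySpec, rng: np.random.Generator
) -> tuple[str, str]:
    if fam.tsd_motif and rng.random() < fam.tsd_motif_fraction:
        tsd = fam.tsd_motif
    else:
        tsd = _random_dna(rng, fam.effective_tsd_length)
    tsd3 = _apply_edits(tsd, fam.tsd_divergence, rng) if fam.tsd_divergence else tsd
    return tsd, tsd3


_PAD = 12  # context bases simulated on each side when verifying compliance


def _build_compliant_insert(
    rng: np.random.Generator,
    fam: FamilySpec,
    internal: str,
    start_seed: str,
    end_seed_rc: str,
    divergence: int,
    strand: str = "+",
    max_tries: int = 60,
) -> tuple[str, str, str, str]:
    """Construct ``tsd5 + element + tsd3`` whose planted bounds are exactly
    what the matcher recovers at a scan budget equal to ``divergence``.

    Edits applied to terminal TIR copies can interact with the flanking TSD
    (e.g. a deleted terminal base coincidentally restored by the TSD),
    shifting the optimal match boundary and invalidating the flush TSD
    check.  Terminals and TSDs are therefore resampled until a search over
    the padded insert context yields a forward hit starting at the element
    start and a reverse hit ending at the element end.  Returns
    (insert_seq, element, tsd5, tsd3).
    """
    from packtype.tir_search import find_tir_matches

    for _ in range(max_tries):
        t5 = _apply_edits(start_seed, divergence, rng)
        t3 = _apply_edits(end_seed_rc, divergence, rng)
        element = t5 + internal + t3
        tsd5, tsd3 = _build_tsds(fam, rng)
        insert = tsd5 + element + tsd3
        if strand == "-":
            # inverted-repeat structure is strand-symmetric, so the scan
            # still recognises the element; verify the orientation actually
            # planted because match collapsing tie-breaks are not mirror-
            # symmetric at equal distance
            insert = reverse_complement(insert)
            tsd5, tsd3 = reverse_complement(tsd3), reverse_complement(tsd5)
        pad5, pad3 = _random_dna(rng, _PAD), _random_dna(rng, _PAD)
        ctx = GenomeSequences(contigs={"c": pad5 + insert + pad3})
        elem_start = len(pad5) + len(tsd5) + 1
        elem_end = elem_start + len(element) - 1
        fwd = find_tir_matches(ctx, start_seed, divergence)
        rev = find_tir_matches(ctx, end_seed_rc, divergence)
        fwd_ok = any(m.start == elem_start for m in fwd) and all(
            m.start >= elem_start for m in fwd
        )
        rev_ok = any(m.end == elem_end for m in rev) and all(
            m.end <= elem_end for m in rev
        )
        if fwd_ok and rev_ok:
            return insert, element, tsd5, tsd3
    raise RuntimeError(
        f"could not construct a compliant element for {fam.superfamily} "
        f"at divergence {divergence}"
    )


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequences, TruthSet, dict[str, str], dict[str, str]]:
    """Build the genome, its truth set, and the CDS / transposase reference
    sets.  Deterministic for a fixed config (the seed is part of it)."""
    rng = np.random.default_rng(config.seed)

    # reference databases (fragments are copied from these into masters)
    cds_db = {f"cds{i}": _random_dna(rng, int(rng.integers(900, 1800))) for i in range(1, 11)}
    transposase_db = {f"tpase{i}": _random_dna(rng, 2400) for i in range(1, 5)}

    width_cap = max(15000, *(f.width_max for f in config.families))
    same_group_gap = width_cap + 2000

    inserts: list[_Insert] = []
    masters: list[str] = []

    # family members
    for fi, fam in enumerate(config.families):
        tir = fam.tir_seed.upper()
        internal_len = fam.width_max - 2 * len(tir)
        master = _distinct_master(rng, internal_len, masters)
        masters.append(master)
        if fam.captured_fragment_source != "none" and fam.fragment_length > 0:
            db = cds_db if fam.captured_fragment_source == "cds_db" else transposase_db
            src_id = sorted(db)[fi % len(db)]
            src = db[src_id]
            off = int(rng.integers(0, len(src) - fam.fragment_length + 1))
            frag = src[off : off + fam.fragment_length]
            at = min(50, internal_len - fam.fragment_length)
            master = master[:at] + frag + master[at + fam.fragment_length :]
        widths = rng.integers(fam.width_min, fam.width_max + 1, size=fam.n_members)
        widths[0] = fam.width_max  # the representative-to-be is widest
        n_hop = int(round(fam.local_hop_fraction * fam.n_members))
        # reversed members are drawn from the tail so they are never the
        # widest member (member 0) nor a local-hop member (1..n_hop)
        n_rev = min(fam.n_reverse, max(fam.n_members - 1 - n_hop, 0))
        reversed_ids = set(range(fam.n_members - n_rev, fam.n_members))
        fam_first_index = len(inserts)
        for mi in range(fam.n_members):
            w = int(widths[mi])
            internal = _mutate(master, 0.04, rng)[: w - 2 * len(tir)]
            hop_mate = None
            if 1 <= mi <= n_hop:
                hop_mate = fam_first_index + mi - 1
                strand = inserts[hop_mate].record.strand  # hops keep orientation
            else:
                strand = "-" if mi in reversed_ids else "+"
            insert_seq, element, tsd5, tsd3 = _build_compliant_insert(
                rng, fam, internal,
                start_seed=tir, end_seed_rc=reverse_complement(tir),
                divergence=fam.tir_divergence, strand=strand,
            )
            inserts.append(
                _Insert(
                    insert_seq=insert_seq,
                    element_offset=len(tsd5),
                    element_len=len(element),
                    record=AnnotationRecord(
                        contig_id="chr1", start=0, end=0, strand=strand,
                        element_id=f"truth-{fam.superfamily}-{mi + 1}",
                        superfamily=fam.superfamily, category=fam.category,
                        cluster_id=fi + 1, tsd_seq_5=tsd5, tsd_seq_3=tsd3,
                    ),
                    kind="planted",
                    seed_group=fam.tir_seed.upper(),
                    hop_mate=hop_mate,
                )
            )

    # outward-facing decoys (reversed-TIR construction, valid TSDs)
    for di in range(config.n_outward_decoys):
        fam = config.families[di % len(config.families)]
        tir = fam.tir_seed.upper()
        div = (
            config.decoy_divergence[di % len(config.decoy_divergence)]
            if config.decoy_divergence
            else fam.tir_divergence
        )
        w = int(rng.integers(fam.width_min, fam.width_max + 1))
        internal = _random_dna(rng, w - 2 * len(tir))
        insert_seq, element, tsd5, tsd3 = _build_compliant_insert(
            rng, fam, internal,
            start_seed=reverse_complement(tir), end_seed_rc=tir,
            divergence=div,
        )
        inserts.append(
            _Insert(
                insert_seq=insert_seq,
                element_offset=len(tsd5),
                element_len=len(element),
                record=AnnotationRecord(
                    contig_id="chr1", start=0, end=0, strand=".",
                    element_id=f"decoy-{fam.superfamily}-{di + 1}",
                    superfamily=fam.superfamily, category="decoy",
                    tsd_seq_5=tsd5, tsd_seq_3=tsd3,
                ),
                kind="decoy",
                seed_group=fam.tir_seed.upper(),
            )
        )

    # singleton pseudo-families (their own seeds; removed by the singleton filter)
    for si, seed in enumerate(_singleton_seeds(config), 1):
        pseudo = FamilySpec(
            superfamily=f"single{si}", tir_seed=seed, n_members=1,
            tsd_length=5, width_min=450, width_max=700,
        )
        w = int(rng.integers(450, 700))
        internal = _random_dna(rng, w - 2 * len(seed))
        insert_seq, element, tsd5, tsd3 = _build_compliant_insert(
            rng, pseudo, internal,
            start_seed=seed, end_seed_rc=reverse_complement(seed),
            divergence=0,
        )
        inserts.append(
            _Insert(
                insert_seq=insert_seq,
                element_offset=len(tsd5),
                element_len=len(element),
                record=AnnotationRecord(
                    contig_id="chr1", start=0, end=0, strand=".",
                    element_id=f"single-{si}", superfamily=f"single{si}",
                    category="singleton", tsd_seq_5=tsd5, tsd_seq_3=tsd3,
                ),
                kind="singleton",
                seed_group=seed,
            )
        )

    # N-rich elements (valid structure, wildcard-heavy internal)
    for ni in range(config.n_n_rich):
        fam = config.families[ni % len(config.families)]
        tir = fam.tir_seed.upper()
        w = int(rng.integers(fam.width_min, fam.width_max + 1))
        internal = list(_random_dna(rng, w - 2 * len(tir)))
        n_count = int(np.ceil(config.n_rich_fraction * w))
        for i in rng.choice(len(internal), size=min(n_count, len(internal)), replace=False):
            internal[i] = "N"
        insert_seq, element, tsd5, tsd3 = _build_compliant_insert(
            rng, fam, "".join(internal),
            start_seed=tir, end_seed_rc=reverse_complement(tir),
            divergence=0,
        )
        inserts.append(
            _Insert(
                insert_seq=insert_seq,
                element_offset=len(tsd5),
                element_len=len(element),
                record=AnnotationRecord(
                    contig_id="chr1", start=0, end=0, strand=".",
                    element_id=f"nrich-{ni + 1}", superfamily=fam.superfamily,
                    category="n_rich", tsd_seq_5=tsd5, tsd_seq_3=tsd3,
                ),
                kind="n_rich",
                seed_group=fam.tir_seed.upper(),
            )
        )

    total_insert = sum(len(i.insert_seq) for i in inserts)
    if total_insert >= config.genome_length / 2:
        raise ValueError("total planted width must stay below half the genome length")

    _place(rng, inserts, config, same_group_gap)

    background = _random_dna(rng, config.genome_length, config.gc_content)
    ordered = sorted(inserts, key=lambda i: i.bg_pos)
    parts: list[str] = []
    cursor = 0
    shift = 0
    for ins in ordered:
        parts.append(background[cursor : ins.bg_pos])
        start = ins.bg_pos + shift + ins.element_offset + 1  # 1-based
        ins.record.start = start
        ins.record.end = start + ins.element_len - 1
        parts.append(ins.insert_seq)
        shift += len(ins.insert_seq)
        cursor = ins.bg_pos
    parts.append(background[cursor:])
    genome = GenomeSequences(contigs={"chr1": "".join(parts)})

    truth = TruthSet()
    bucket = {
        "planted": truth.planted,
        "decoy": truth.decoys,
        "singleton": truth.singletons,
        "n_rich": truth.n_rich,
    }
    for ins in sorted(inserts, key=lambda i: i.record.start):
        bucket[ins.kind].append(ins.record)
    return genome, truth, cds_db, transposase_db


def grade_divergence_series(
    base_config: SimulationConfig, budgets: list[int]
) -> list[tuple[int, TruthSet, GenomeSequences]]:
    """One genome holding one family per divergence grade.

    The first family of ``base_config`` is replicated once per budget ``b``
    (ascending) with ``tir_divergence = b`` and a distinct superfamily label
    ``<name>_div<b>``; the shared genome is returned once per grade together
    with the truth restricted to that grade's family, which is what a
    mismatch-budget sweep consumes.
    """
    if budgets != sorted(budgets):
        raise ValueError("budgets must be sorted ascending")
    proto = base_config.families[0]
    fams = tuple(
        replace(proto, superfamily=f"{proto.superfamily}_div{b}", tir_divergence=b)
        for b in budgets
    )
    config = replace(base_config, families=fams)
    genome, truth, _, _ = generate_genome(config)
    out = []
    for b in budgets:
        label = f"{proto.superfamily}_div{b}"
        sub = TruthSet(
            planted=[r for r in truth.planted if r.superfamily == label],
            decoys=[r for r in truth.decoys if r.superfamily == label],
        )
        out.append((b, sub, genome))
    return out


# -- canonical desk-scale study conditions ---------------------------------


def default_families() -> tuple[FamilySpec, ...]:
    """Six families spanning the five classic Class II superfamilies plus a
    second CACTA-like group: two autonomous (transposase fragment > 250 bp),
    three Pack (CDS fragments 60-250 bp), one non-Pack, with
    superfamily-characteristic TSDs (hAT 8 nt, Mariner "TA", PIF "TTA")."""
    return (
        FamilySpec(
            superfamily="CACTA", tir_seed="CACTACAAGAAAA", n_members=10,
            tsd_length=3, captured_fragment_source="transposase_db",
            fragment_length=400, local_hop_fraction=0.2,
        ),
        FamilySpec(
            superfamily="MULE", tir_seed="GGGGATGAAAACGGTA", n_members=10,
            tsd_length=9, tir_divergence=1, captured_fragment_source="transposase_db",
            fragment_length=350, local_hop_fraction=0.2,
        ),
        FamilySpec(
            superfamily="hAT", tir_seed="TAGGGGTGGCAAC", n_members=10,
            tsd_length=8, captured_fragment_source="cds_db", fragment_length=180,
            local_hop_fraction=0.3, n_reverse=3,
        ),
        FamilySpec(
            superfamily="Mariner", tir_seed="CTCCCTCCGTTCA", n_members=10,
            tsd_motif="TA", tsd_motif_fraction=0.9,
            captured_fragment_source="cds_db", fragment_length=120,
            local_hop_fraction=0.3,
        ),
        FamilySpec(
            superfamily="PIF", tir_seed="GGGCACGGTAACT", n_members=10,
            tsd_motif="TTA", tsd_motif_fraction=0.6, tir_divergence=1,
            captured_fragment_source="cds_db", fragment_length=90,
            local_hop_fraction=0.3, n_reverse=2,
        ),
        FamilySpec(
            superfamily="Harbinger", tir_seed="GTGCCCTTTGCAA", n_members=10,
            tsd_length=3, captured_fragment_source="none", local_hop_fraction=0.2,
        ),
    )


def default_config(seed: int) -> SimulationConfig:
    """The canonical desk-scale benchmark genome: 1 Mb, 60 compliant members
    across 6 families, 20 outward decoys, 5 singletons, 5 N-rich elements."""
    return SimulationConfig(
        seed=seed,
        families=default_families(),
        genome_length=1_000_000,
        gc_content=0.40,
        n_outward_decoys=20,
        n_singletons=5,
        n_n_rich=5,
    )


def hopping_config(seed: int) -> SimulationConfig:
    """Sparse conditions for the local-insertion statistics: three families
    on an 8 Mb genome, half of each family's members planted as local hops
    (within 100 kb of a family mate, same orientation).  Element density is
    kept low so that, unlike the dense recovery benchmark, being within
    100 kb of another family's member is the exception, not the rule —
    matching the geometry of real plant genomes where the test is applied."""
    return SimulationConfig(
        seed=seed,
        families=(
            FamilySpec(superfamily="hAT", tir_seed="TAGGGGTGGCAAC", n_members=8,
                       tsd_length=8, local_hop_fraction=0.5),
            FamilySpec(superfamily="PIF", tir_seed="GGGCACGGTAACT", n_members=8,
                       tsd_motif="TTA", local_hop_fraction=0.5),
            FamilySpec(superfamily="Mariner", tir_seed="CTCCCTCCGTTCA", n_members=8,
                       tsd_motif="TA", local_hop_fraction=0.5),
        ),
        genome_length=8_000_000,
        gc_content=0.40,
    )


def roc_config(seed: int) -> SimulationConfig:
    """Conditions for the graded-divergence ROC sweep: a long (MULE-like)
    TIR seed on a 300 kb genome, with outward decoys whose TIR divergence
    lags the families', so false positives appear only as the mismatch
    budget loosens."""
    return SimulationConfig(
        seed=seed,
        families=(
            FamilySpec(
                superfamily="MULE", tir_seed="GGCCATAGGTTCAAATGGAG",
                n_members=5, tsd_length=9, width_min=450, width_max=560,
            ),
        ),
        genome_length=1_000_000,
        gc_content=0.40,
        n_outward_decoys=5,
        decoy_divergence=(3, 4, 5, 6),
    )
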