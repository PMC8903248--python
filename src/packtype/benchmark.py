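"""Self-benchmarking: recovery against a known element set, reversed-TIR
decoy searches, and ROC/AUC over the TIR-mismatch sweep.

The false-positive rate of a TIR search cannot be measured directly without
exhaustive ground truth, but TIR pairs facing *outwards* are unlikely to
belong to one element, so repeating the search with forward and reverse
seeds exchanged estimates the rate of structurally spurious hits:

    sensitivity   = identified known elements / total known elements
    1-specificity = elements found with reversed TIRs
                    / elements found with correct TIRs

Sweeping the TIR mismatch budget and plotting the two rates gives a ROC
curve; the area under it summarises search performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from packtype.genome_io import AnnotationRecord, GenomeSequences
from packtype.tir_search import TIRQuery, scan_genome

DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.5
DEFAULT_TSD_MISMATCH = 2
DEFAULT_SWEEP = tuple(range(0, 11))


@dataclass(frozen=True)
class ROCPoint:
    """One operating point of the TIR-mismatch sweep.

    ``fpr`` is the raw reversed/correct ratio and may exceed 1 on
    pathological inputs; it is clamped to 1 only when plotting/integrating.
    """

    tir_mismatch: int
    sensitivity: float
    fpr: float

    def __post_init__(self):
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.fpr < 0:
            raise ValueError("fpr must be >= 0")


def compute_sensitivity(identified: int, total_known: int) -> float:
    """Fraction of a known element set recovered by the search."""
    if total_known <= 0:
        raise ValueError("total_known must be > 0")
    if not 0 <= identified <= total_known:
        raise ValueError("identified must lie in [0, total_known]")
    return identified / total_known


def compute_fpr(reversed_count: int, correct_count: int) -> float:
    """Reversed-TIR hit count over correct-TIR hit count (raw, unclamped)."""
    if correct_count <= 0:
        raise ValueError("correct_count must be > 0 (point undefined otherwise)")
    return reversed_count / correct_count


def reversed_tir_scan(genome: GenomeSequences, query: TIRQuery) -> int:
    """Count of candidates found with forward and reverse TIR seeds
    exchanged (outward-facing search).  Only the first pipeline stage runs:
    TSD filtering as configured, no clustering or classification."""
    return len(scan_genome(genome, [query.swapped()]))


def _interval_overlap(a: AnnotationRecord, b: AnnotationRecord) -> int:
    if a.contig_id != b.contig_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def evaluate_against_truth(
    predicted: list[AnnotationRecord],
    truth: list[AnnotationRecord],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> dict:
    """Match predictions to a truth set by reciprocal overlap.

    A prediction matches a truth element iff overlap/width >= threshold for
    *both* intervals; matching is greedy one-to-one by descending overlap.
    Returns recall = matched/|truth|, precision = matched/|predicted|
    (0 with ``precision_defined=False`` when there are no predictions), and
    the matched (predicted_index, truth_index) pairs.
    """
    pairs: list[tuple[int, int, int]] = []  # (overlap, pi, ti)
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth):
            ov = _interval_overlap(p, t)
            if ov == 0:
                continue
            if ov / p.width >= min_reciprocal_overlap and ov / t.width >= min_reciprocal_overlap:
                pairs.append((ov, pi, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[int, int]] = []
    for ov, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matched.append((pi, ti))
    recall = len(matched) / len(truth) if truth else 0.0
    if predicted:
        precision, precision_defined = len(matched) / len(predicted), True
    else:
        precision, precision_defined = 0.0, False
    return {
        "recall": recall,
        "precision": precision,
        "precision_defined": precision_defined,
        "matched_pairs": matched,
    }


def roc_auc(points: list[ROCPoint]) -> float:
    """Trapezoidal area under the ROC curve.

    Points are sorted by FPR (clamped to 1), anchors (0,0) and (1,1) are
    appended when absent, and duplicate points do not change the result.
    """
    if len(points) < 2:
        raise ValueError("at least two ROC points are required")
    xy = sorted({(min(p.fpr, 1.0), p.sensitivity) for p in points})
    if xy[0] != (0.0, 0.0):
        xy.insert(0, (0.0, 0.0))
    if xy[-1] != (1.0, 1.0):
        xy.append((1.0, 1.0))
    xs = np.array([p[0] for p in xy])
    ys = np.array([p[1] for p in xy])
    return float(np.trapezoid(ys, xs))


def roc_sweep(
    genome: GenomeSequences,
    query: TIRQuery,
    truth: list[AnnotationRecord],
    budgets: tuple[int, ...] = DEFAULT_SWEEP,
    tsd_mismatch: int = DEFAULT_TSD_MISMATCH,
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> list[ROCPoint]:
    """Sweep the TIR mismatch budget (TSD budget held fixed) and measure an
    operating point per budget: sensitivity against the truth set and the
    reversed-TIR false-positive ratio.  Budgets whose correct-TIR search
    returns nothing yield no point (the ratio is undefined there)."""
    from dataclasses import replace

    points: list[ROCPoint] = []
    for b in budgets:
        q = replace(query, max_tir_mismatch=b, max_tsd_mismatch=tsd_mismatch)
        cands = scan_genome(genome, [q])
        correct = len(cands)
        if correct == 0:
            continue
        predicted = [
            AnnotationRecord(contig_id=c.contig_id, start=c.start, end=c.end)
            for c in cands
        ]
        res = evaluate_against_truth(predicted, truth, min_reciprocal_overlap)
        identified = len(res["matched_pairs"])
        points.append(
            ROCPoint(
                tir_mismatch=b,
                sensitivity=compute_sensitivity(identified, len(truth)),
                fpr=compute_fpr(reversed_tir_scan(genome, q), correct),
            )
        )
    return points
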