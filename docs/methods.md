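# Methods

## The annotation problem

Pack-TYPE transposable elements are non-autonomous Class II (cut-and-paste)
DNA transposons whose internal sequence consists largely of captured
fragments of host genes.  Because they encode no transposase and their
internal sequence is idiosyncratic, homology-based repeat annotators — which
match candidate loci against libraries of known element families — miss them
systematically.  What every mobile TIR element does retain are two short
structural signals: a pair of terminal inverted repeats (TIRs) recognised by
the mobilising transposase, and a target-site duplication (TSD) — a short
direct repeat of host sequence created on integration, whose length or motif
is characteristic of the superfamily (8 nt for *hAT*, "TA" for *Mariner*,
"TTA"/"TAA" for *PIF*, ~9 nt for *MULE*, short TSDs for *CACTA*).

This package finds elements from those two signals alone, in three stages,
followed by self-benchmarking and family-level statistics.

## Stage 1 — TIR search and TSD verification (`tir_search`)

**Matching model.**  A TIR seed (8–30 nt) is matched against the genome
under a unit-cost Levenshtein budget with *semi-global* semantics: the seed
must be aligned in full, the genomic ends of the alignment are free.  This
keeps hits anchored to approximately seed length (span within seed length
± budget) while allowing substitutions and indels.  The matcher is a Sellers
dynamic program vectorised over the genome axis: per pattern row, the
horizontal dependency `D[i][j] <- D[i][j-1]+1` is resolved in closed form
via `D[i][j] = j + cummin(E - j)`, giving O(|seed| · |genome|) work in a
handful of numpy passes.  Every end position within budget is then verified
by enumerating its candidate windows explicitly, so the final hit list
equals an exhaustive per-window scan (the test suite asserts equality with
an independent brute-force oracle).

**Collapse rule.**  Overlapping windows describing the same locus are
collapsed to one hit: minimum edit distance, then leftmost start, then
shortest span.  The rule is arbitrary but fixed, for determinism.

**N handling.**  N counts as a mismatch against every symbol, including
another N, in both TIR and TSD comparisons.  This is conservative;
genuinely N-rich elements are additionally removed by the stage-2 wildcard
filter.

**Pairing.**  Forward-seed and reverse-seed hits on one contig are paired
whenever the forward hit starts before the reverse hit and the outermost
span width lies in the superfamily window (default 300–15,000 bp; 300–5,000
for short-element searches).  All nested/overlapping pairings are emitted
and resolved only at deduplication.

**TSD check.**  The two flanks read flush against the candidate's outer
boundaries (tsd-length bases immediately 5' and 3') are compared by
Levenshtein distance; the candidate is kept iff the distance is within the
TSD budget.  A superfamily motif (e.g. "TA"), when configured, is recorded
for composition summaries but is *not* a filter — filtering is always
flank-vs-flank.  Elements flush with a contig edge are rejected: the TSD
filter is mandatory, and an unverifiable TSD is treated as absent.

**Deduplication.**  Candidates from one or several queries whose genomic
spans overlap (transitively) are reduced to a single survivor: widest, then
leftmost, then earliest query.  Widest-wins is a deliberate choice — nested
TIR pairs inside a real element are artefacts of seed re-occurrence — but
it has a known failure mode at very loose mismatch budgets, discussed under
Limitations.

## Stage 2 — family building (`clustering`)

Elements with more than 10% N are removed.  The remainder are clustered by
greedy centroid assignment at 60% global identity: candidates are processed
in decreasing width order (ties: contig, then start) and each joins the
first existing centroid — in founding order — whose pairwise identity
reaches the threshold on either strand, else founds a new cluster.
Identity is matching columns over alignment length of the
edit-distance-optimal global alignment (computed with edlib).  Under this
metric two unrelated random DNA sequences score ≈0.53 — not ≈0.25 as a
naive matches-over-length intuition suggests — so the 0.60 default sits
only moderately above the random baseline; it cleanly separates families
diverged up to ~15% from unrelated sequence, which is the regime the
pipeline targets.

Singleton clusters are removed on the assumption that real transposons are
repeated in a genome; a one-off structural match is more likely a false
positive.  Surviving clusters are renumbered by decreasing size.

Because non-autonomous elements have no intrinsic orientation, each
cluster's widest member is declared forward ("+") by convention and every
other member takes the strand on which its global alignment to that
representative scores the higher identity (ties to "+").

## Stage 3 — classification (`classify`)

Categories follow the established Pack-MULE scheme, with strict precedence:

* **autonomous** — some transposase hit with E < 1e-5 and alignment length
  > 250 bp;
* **pack** — otherwise, some host-CDS hit with E < 1e-5 and alignment
  length > 50 bp (250 bp for short-TIR extended searches);
* **non_pack** — otherwise.

"Length" is alignment length, not element length.  Hits come from one of
three interchangeable sources: `blastn` (run with `-max_target_seqs 500
-task blastn-short -word_size 7`, E-value cutoff applied downstream), a
precomputed 12-column outfmt-6 table, or a built-in local aligner for
hermetic testing.

The internal aligner scores match +1 / mismatch −1 / linear gap −2 and
reports the best local alignment per element–subject pair on either strand.
Its E-value is Karlin–Altschul, `E = K·m·N·exp(−λS)` with `m` the element
length and `N` the total reference length.  Published λ/K tables cover
ungapped scoring only and badly overstate the significance of gap-padded
random alignments under a cheap linear gap; λ = 0.78 and K = 0.031 were
therefore calibrated once by a Gumbel moment fit to the null score
distribution of 400 random 600×800 bp pairs (the fit reproduces the
empirical tail within a factor of ~2).  Classification decisions sit far
from the 1e-5 boundary by construction — a clean 60 bp captured fragment
scores E ≈ 1e-17 — so modest calibration error is immaterial; the external
backend remains the reference for real data.

Element identifiers are `<genome>-<superfamily>-<N>` with N counting in
genomic (contig, start) order per superfamily — the deterministic
realisation of "order of discovery".

## Self-benchmarking (`benchmark`)

Sensitivity against a known element set is `identified / total`, where a
prediction identifies a truth element iff their reciprocal overlap is ≥ 0.5
(both directions), matched greedily one-to-one by descending overlap.  The
false-positive proxy repeats the stage-1 search with forward and reverse
seeds exchanged: outward-facing TIR pairs cannot belong to one element, so
their rate estimates the rate of structurally spurious calls:
`1−specificity = reversed-TIR count / correct-TIR count`.  The ratio is
reported raw (it can exceed 1 on pathological inputs) and clamped to 1 only
for plotting and integration.  Sweeping the TIR budget with the TSD budget
fixed (default 2) yields a ROC curve; AUC is trapezoidal with (0,0)/(1,1)
anchors.

## Family statistics (`family_analysis`)

* **TIR relatedness** — the first 80 bp of each oriented element (the
  forward-TIR side) is reduced to its 5-mer set; distance is the Jaccard
  complement (shared distinct k-mers over the union).  The exact metric
  behind published alignment-free k-mer distances is implementation-
  specific; Jaccard on k-mer sets is adopted and the function is pluggable.
  Complete-linkage hierarchical clustering (scipy) orders the matrix and a
  maxclust cut yields the groups (6 by default).
* **Local hopping** — cut-and-paste transposons preferentially reinsert
  near their donor locus.  For a cluster, the fraction of members within
  100 kb of a cluster-mate is compared with the fraction of non-members
  within 100 kb of a cluster member, via a one-sided 2×2 chi-squared
  without continuity correction (one-sided p = half the two-sided p when
  the observed direction is positive, else one minus that half; degenerate
  margins give p = 1).  Superfamily aggregates pool the 2×2 counts across
  clusters rather than combining per-cluster p-values.
* **Orientation concordance** — fraction of same-cluster local pairs
  (gap between nearest ends ≤ 100 kb; 0 when overlapping) inserted in the
  same orientation.
* **TSD composition** — exact-match fraction of 5' TSDs against a motif,
  plus the full frequency table.

## The synthetic-data generator (`synthetic_data`)

The generator plants ground truth into an i.i.d. background (default GC
0.40) so that every stage is testable hermetically:

* **Family members** share a mutated copy (4% point mutations, width jitter)
  of a family master internal sequence flanked by the family TIR (each copy
  independently perturbed by exactly `tir_divergence` edits) and a TSD
  (identical flanks up to `tsd_divergence` edits).  Masters are
  rejection-sampled to pairwise identity ≤ 0.55 — essentially the random
  baseline under the clustering metric — so families are as unrelated as
  random DNA allows.  A configured fragment from the generated CDS or
  transposase reference is spliced near the master's start, fixing the
  family's true category.
* **Outward decoys** use the same construction with the TIR orientations
  swapped: invisible to the inward scan, recovered exactly by the
  reversed-TIR benchmark.
* **Singletons** are structurally valid one-off pseudo-families (own seed);
  the singleton filter must remove them.
* **N-rich elements** carry 15% N internally; the wildcard filter must
  remove them.

Same-seed insertions are spaced further apart than the width window's upper
bound, so TIRs of different planted elements can never pair into an
in-window candidate; deliberate local-hop placements put family mates
17–80 kb apart (inside the 100 kb statistic window, outside the pairing
window) with matching orientation.  Every member insert is verified at
construction time: the matcher, run on the padded insert context at the
family's divergence budget, must recover exactly the planted boundaries
(edits at TIR ends can otherwise interact with the TSD and shift the
optimal match by a base, which the flush TSD check would then reject).
Terminals are resampled until compliant.  Reverse-complement members are
verified in their planted orientation, since the collapse tie-breaks are
not mirror-symmetric at equal distance.

A single integer seed makes config + genome + truth byte-reproducible.
Three canonical configurations encode the study conditions:

* `default_config` — 1 Mb, 6 superfamilies × 10 members (two autonomous
  families with >250 bp transposase fragments, three pack families with
  60–250 bp CDS fragments, one non-pack), 20 outward decoys, 5 singletons,
  5 N-rich elements.  Used for recovery, filtering and classification
  checks.
* `roc_config` — 1 Mb, one MULE-like 20 nt seed, five divergence grades
  (0–4) of five members via `grade_divergence_series`, plus five decoys at
  divergence 3–6 so false positives appear only as the budget loosens.
* `hopping_config` — 8 Mb, three families × 8 members, half planted as
  local hops.  Sparse on purpose: in the dense recovery genome every
  element lies within 100 kb of every cluster, which voids the
  local-hopping contrast; real plant genomes are sparse in exactly this
  sense.

What the generator does **not** emulate: nested insertions, sequence decay
gradients, Markovian base composition, segmental duplications, and
transposition dynamics.  Passing tests therefore demonstrate algorithmic
correctness on clean planted structure, not annotation completeness on real
genomes — on real data the conservative defaults are expected to trade
recall for precision.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (GFF3-native); half-open
  arithmetic is confined to module boundaries.
* The matcher's collapse rule and the deduplication tie-breaks are fixed
  (min distance → leftmost → shortest; widest → leftmost → query order) to
  make every pipeline stage deterministic under input permutation.
* The TSD window is flush to element boundaries, not sliding.
* Clustering runs on the merged, deduplicated candidate set of all queries.
* Identity threshold 0.60, N-fraction 0.10, classification thresholds
  (1e-5, 250 bp, 50 bp), 100 kb pairing window, 80 bp TIR prefix, k = 5 and
  6 dendrogram groups are the established defaults of the method this
  package implements and are all overridable.
* Problem sizes of the shipped study conditions (1 Mb / 8 Mb genomes,
  60-element benchmark, 25-element ROC series) were chosen as the smallest
  sizes at which every structural class (multi-family recovery, decoys,
  singletons, N-rich, divergence grades, sparse hop geometry) is
  represented with unambiguous expected outcomes.

## Known limitations

* **Loose budgets vs widest-wins.**  At mismatch budgets well past the true
  TIR divergence, spurious background hits can pair across real elements,
  occasionally pass the TSD check by chance, and the resulting multi-kb
  candidate then shadows the true element at deduplication.  Sensitivity is
  therefore not globally monotone in the budget — it is monotone up to the
  planted divergence range, which is where the method is meant to operate;
  the benchmark narrative (minimal budgets suffice) reflects the same
  trade-off.
* The greedy centroid clusterer reproduces the documented strategy of the
  reference tool but is not bit-identical to it; exact cluster counts on
  real genomes may differ at the margin.
* The internal similarity backend is a testing device with calibrated null
  statistics, not a BLAST replacement; real-data classification should use
  the external backend or precomputed hit tables.
* Chi-squared (not Fisher) is used for the 2×2 tests, without continuity
  correction: appropriate for genome-scale counts, anti-conservative for
  very small tables.
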