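# Methods

## Scope and overall design

`inotoscan` re-casts a manual comparative-genomics workflow — BLAST
searches, by-eye precursor annotation, motif-based receptor assignment,
and presence/absence bookkeeping over a phylogeny — as a deterministic
library. Every stage is rule-based and reproducible: given the same
inputs, the same seed and the same configuration, every output file is
byte-identical. Sequence retrieval from public databases is deliberately
out of scope; the unit of input is a FASTA collection plus a TSV species
manifest (species, order, subphylum), and the synthetic-data generator
stands in for real assemblies during testing.

Coordinates are 0-based half-open in all APIs and 1-based inclusive in
TSV reports.

## Homology search

Candidate discovery uses exact Smith–Waterman local alignment rather than
a seeded heuristic. The affine gap convention is the one used by common
search tools: a gap of length *g* costs `open + extend·g`, with defaults
`open = 11`, `extend = 1` under BLOSUM62. Consequences of going exact:
results are deterministic, and the hit set at a given cutoff can only be
a superset of a heuristic search's.

Significance uses the Karlin–Altschul expectation
`E = K·m·n·exp(−λS)` with the published gapped defaults for
BLOSUM62/11/1, λ = 0.267 and K = 0.041 (configurable on
`ScoringScheme`). `m` is the query length; `n` is the total residue count
of the searched dataset, with nucleotide entries counted at their
translated length over all six frames. No composition-based statistics
and no low-complexity masking are applied — a deliberate simplification;
on low-complexity inputs the E-values are therefore optimistic. Residues
outside the matrix alphabet score through the `X` column, and alignment
to a stop (`*`) never scores positively.

Traceback ties are broken deterministically: diagonal first, then the gap
consuming a query residue, then the gap consuming a subject residue; the
reported optimum is the maximum-scoring cell with the smallest query,
then subject index. The production recursion (a vectorised score-only
pass plus a full traceback pass on survivors) is checked in tests against
an independently formulated cubic gap-enumeration dynamic program and
against a third-party exact local aligner.

## Precursor grammar

A candidate precursor is parsed with a small grammar instead of a trained
model:

* **ring**: `C-X4-C` anywhere in the sequence;
* **tail**: 3 residues (nonapeptide) tried first, then 4 (decapeptide);
* **amidation signal**: glycine amide donor immediately after the mature
  peptide, then a dibasic pair from {KR, RK, KK}; RR is accepted but
  flagged `unusual_dibasic`. Mature peptides ending in A or S instead of
  G can still be amidated (the donor follows them) and are flagged
  `non_canonical_terminal`. A ring with no valid signal is still reported
  (`no_processing_site`) so unprocessed precursors remain representable.
* **neurophysin**: cysteines downstream of the mature domain are chained
  into runs whose consecutive members are ≤ 30 residues apart; the
  longest run is the framework if it has ≥ 6 cysteines, and it is
  *complete* at exactly 14. The gap threshold and minimum are
  configurable; both were chosen from the short inter-cysteine spacing
  characteristic of neurophysins.

When several rings occur, the first ring with a valid amidation signal
wins; failing that, the first ring followed within 150 residues by a
cysteine framework. An annotation is **complete** iff a mature peptide
and a framework are both present; framework-only sequences are
**partial** (truncated transcripts/assembly artefacts); everything else
is **rejected**. No signal-peptide predictor is implemented — the region
upstream of the mature peptide is reported as the signal region, with an
advisory `weak_signal_like` flag when the first 30 residues lack an
8-residue window of mean Kyte–Doolittle hydropathy > 1.5.

Batch statistics count, over complete annotations: precursors whose
mature peptide ends in an amidated glycine, and precursors with any
donor+dibasic signal.

## Receptor motif rule

Inotocin receptors are separated from CCAP receptors by two positional
motifs. TM2/ECL1: `X-P-Q-X2-W-X5-6-F` — 12 residues with the 5-residue
spacer, 13 with the 6-residue spacer — calling for ≥ 3 identical of the
four anchors P, Q, W, F; CCAP variant `X2-D-X8-W` (both anchors
required). TM7: `C-X-N-P-W` with the N-P core mandatory and ≥ 1 identical
of C/W; CCAP variant `A-X-N-P-[V/L/F]` (both anchors required). Anchor
identity is exact equality, not similarity groups.

Without structural TM assignments, the motifs are localised by position:
TM2/ECL1 is scanned over the N-terminal 60 % of the sequence, TM7 over
the C-terminal 25 % (both fractions configurable). Full-length sequences
combine the two criteria with OR; a conflict (one motif voting inotocin,
the other CCAP) yields `unclassified` with a `conflicting_evidence` flag
rather than a guess. Partial sequences lacking the N-terminus are called
on TM7 alone and marked `partial`.

The bare anchor rule has a quantifiable false-positive rate on random
sequence: a 3-of-4 anchor match arises by chance in a few percent of
shuffled ~380-residue sequences. In the intended pipeline order this is
immaterial — candidates reach the classifier only after passing the
E ≤ 10⁻⁴ homology filter — but the rule should not be applied raw to
arbitrary sequence collections.

As a grouping cross-check, `pairwise_identity_tree` builds a
neighbour-joining tree over distances `1 − identity` from global
alignments with free end gaps (same scoring scheme). This is a
deliberately light surrogate for a full likelihood phylogeny, which is
out of scope.

## Census, consensus and mapping

The census counts **precursors, not species**: a species with two
precursors encoding different peptides contributes two counts. Only
complete annotations contribute. Position frequency matrices are built
per occurrence (not per unique peptide) over equal-length peptides;
decapeptides join the census as their own keys but are excluded from the
9-column matrix. Consensus calling: a position is invariant when its top
residue frequency is 1.0 (upper-case), lower-case when above the majority
threshold (default 0.5), `X` otherwise.

Neurophysin segment statistics summarise the 13 inter-cysteine lengths of
complete frameworks with mean and SD (n−1 denominator; a single
observation reports SD 0 with a flag); incomplete frameworks are counted
but not averaged.

Presence mapping: a species is `present` for the precursor side if it
has any complete annotation, `partial` if only framework-only fragments,
`absent` otherwise; the receptor side counts only inotocin-like calls
(CCAP-like and unclassified calls establish nothing). Per-group INT/T
summaries count species with any non-absent evidence over species
sampled.

**Dollo loss inference** places the single gain at the most recent common
ancestor of all present leaves and reports the maximal absent subtrees
below it; their stem edges carry the losses. This loss set is minimal and
is the unique minimal set closest to the root, which resolves ties
deterministically; minimality is verified in tests against exhaustive
search over loss-edge subsets on small trees. The species tree is always
user-supplied Newick — the package never infers it. An order-level
arthropod tree (transcribed at order resolution from the published
insect phylogeny) ships as a packaged fixture.

**Contamination flag**: a species is flagged when it is the only sampled
member of its order with the system while ≥ 3 sampled members lack it,
*and* it shares a byte-identical mature peptide with a species from a
different subphylum (relaxable to a different order). Both thresholds are
configurable.

## Synthetic data generator

The generator emulates the *structure* of real mining inputs: precursors
with the full architecture (signal 19–25 residues, hydrophobic-biased;
mature peptide drawn from the packaged 21-peptide table with observed
frequencies as weights; amidation signal drawn as GKR 0.8 / GRK 0.1 /
GKK 0.1; neurophysin from a packaged 14-cysteine template whose 13
segment lengths are jittered ±2 by default), receptors as 7-helix
scaffolds with the family motifs embedded in their expected positional
windows, motif-free receptor scaffolds (`family="decoy"`), and
residue-shuffled decoys.

Two design choices matter for interpreting test results:

* **Shared base scaffolds.** All members of a generated class share fixed
  background strings; per-record variation comes from segment-length
  draws, mutation noise and shuffling. Real family members are homologous
  over their whole length — that is the premise of similarity search —
  and a generator with independent random backgrounds would produce
  "family members" that no aligner could relate. The flip side: generated
  within-class diversity is lower than real diversity, so perfect recall
  at μ = 0 demonstrates correctness of the machinery, not expected
  sensitivity on deeply diverged real sequences.
* **Disjoint alphabets.** Background regions contain no cysteines, no
  dibasic pairs, and no receptor-motif anchor residues, so mutation-free
  output is unambiguous for the annotators. Mutation noise re-introduces
  ambiguity deliberately. Point mutations spare the ring cysteines, the
  framework cysteines and the 3-residue amidation signal so truth labels
  remain valid; receptor motif anchors are spared unless
  `anchor_sparing=False` (robustness tests).

Two packaged expansions reproduce reference statistics by construction:
`expand_table1_precursors` (one precursor per table count; census = the
table), and `amidation_survey_precursors` (110 precursors: 103 amidated
terminal-G, 6 amidated terminal-A/S, 1 with no processing site). The
latter is a synthetic stand-in for a *survey-scale* annotated precursor
set with the reported composition.

What the generator does **not** emulate: phylogenetically correlated
divergence, indels (substitutions only by default), codon-level gene
structure, assembly noise other than truncation, and realistic proteome
background composition (uniform over the class alphabets). Passing tests
on synthetic data therefore validate the algorithms and their contracts,
not field performance on raw assemblies.

## Problem sizes and numerics

Default test and acceptance runs use desk-scale inputs — 20-species
datasets with 50 decoys, 110–121-precursor expansions, 50-precursor
framework sets, ≤ 8-leaf trees for exhaustive Dollo verification, and
≤ 15-mers (200 seeded pairs) for alignment-oracle comparison — sizes at
which every check is exact and the full suite runs in well under a
minute. All randomness flows through `numpy.random.default_rng` seeded
from the configuration; PFM column sums are asserted to 1e-9; E-value
monotonicity in score is strict. Degenerate inputs have defined
behaviour: empty FASTA → empty collection, no present leaves → zero
losses and no gain, a single framework → SD 0 with a flag, scoreless
pairs → an explicit empty alignment.

## Known limitations

* Karlin–Altschul parameters are fixed constants, not estimated from the
  scoring system; E-values for non-default schemes require the caller to
  supply λ and K.
* The positional TM windows (60 % / 25 %) are a proxy for real TM
  topology; receptors with unusual domain proportions could place a true
  motif outside its window.
* The count of precursors "analysed" versus "complete" in survey-style
  datasets depends on upstream curation; the batch summary reports both
  countable sets (complete; amidation subsets) and leaves the mapping to
  the user.
* The contamination heuristic needs a reasonably sampled order (≥ 3
  negative peers) and an identical peptide elsewhere; genuine
  single-species presences in an otherwise empty order are
  indistinguishable from contamination by these rules alone.
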