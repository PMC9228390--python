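# Methods

This note documents the models, rules and numerical choices behind
toxprospect, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Length partitioning and assembly statistics

`partition_by_length` keeps records with length ≥ threshold (default
200 bp). The threshold itself is placed in the *kept* bucket: labels
like ">200 bp"/"<200 bp" leave the boundary unassigned, and keeping it
preserves boundary transcripts for downstream completeness analyses;
the threshold is configurable. GC%, N50 and total bases are computed
over the kept partition only. N50 is the largest contig length L such
that contigs of length ≥ L together cover at least half of the total
kept bases; it is computed by sort-and-accumulate and cross-checked in
the tests against an independent oracle.

## ORF extraction

`longest_complete_orf` is a deterministic six-frame scanner for
Met-initiated, stop-terminated ORFs under the standard genetic code,
standing in for trained gene predictors: it needs no genome template,
and "longest complete ORF per contig" is exactly the reported rule it
implements. Equal-length ties break by frame order +1, +2, +3, −1, −2,
−3, then leftmost start on the scanned strand. Coordinates are 0-based
half-open on the forward strand and include the stop codon. Non-ACGT
input is rejected rather than guessed at.

## Identity and greedy clustering

Identity between two sequences is the number of identical aligned
positions of an optimal alignment divided by the length of the
*shorter* sequence, so a fragment contained in a longer isoform scores
1.0 and counts as redundant — the behaviour transcriptome redundancy
removal relies on. The alignment scores match +1, mismatch 0, internal
gap −1, with the unaligned ends of both sequences free.

Two numerical choices matter here:

- **Path independence.** Score-optimal alignments under this scoring
  can differ in how many matched positions they contain. The DP
  therefore maximizes the pair (score, matches) lexicographically
  (packed into one integer), which makes the identity value a function
  of the sequences alone, not of traceback tie-breaking.
- **Word filter.** An optional (default-on) conservative shared-3-mer
  bound skips pairs that cannot reach the threshold: an alignment with
  d non-matching columns destroys at most 3d of the shorter sequence's
  3-mers, so a qualifying pair must share at least (L−2) − 3d of them.
  The filter only skips provably failing alignments and never changes
  the result; the oracle-equivalence tests run with it enabled.

Clustering is greedy and incremental: records sorted longest-first
(ties in input order); each record joins the *best*-scoring existing
representative at or above the threshold (ties to the earlier-founded
cluster) or founds a new cluster. Best-assignment rather than
first-assignment keeps results independent of founding order. Because
processing is longest-first, representatives are always the longest
member. Cross (2D) mode reports which queries are represented in a
subject set; symmetric overlap is obtained by running both directions
and uniting matches.

Default identity threshold: 0.85, the conventional cap for collapsing
assembler isoforms. Redundancy percentages are truncated (not rounded)
at the second decimal, matching the convention of the redundancy tables
this accounting mirrors; the arithmetic is integer-exact.

## Multi-assembler merge

Per-assembler non-redundant sets are pooled and clustered at the same
threshold; each cluster is labeled by its source span: common (all
assemblers), shared-pair (exactly two), unique (one). Strict set
semantics and the published-accounting convention disagree on where
two-assembler clusters belong, and the published common/unique
arithmetic is only self-consistent when they are folded into "common";
both interpretations are implemented (`paper_mode` folds, the default
keeps all four bucket kinds), and neither is asserted as the original
intent. The merge report computes, per bucket, annotated and
unannotated counts, each bucket's contribution to the unannotated total
and its share of the annotated total (two decimals); degenerate
denominators report NA. Percent changes round to the nearest integer.

## Cysteine-scaffold grammar

The primary structural motif (PSM) is six anchor cysteines with bounded
spacers, `C1-X(4,6)-C2-X(4,9)-C3-C4-X(2,10)-C5-X(3,14)-C6-X(1,16)`; the
extra structural motif (ESM) is `C-X-C` (exactly one intervening
residue). Spacer residues are unconstrained — in particular they may be
cysteines, so frameworks with more than six cysteines still match. The
trailing X(1,16) means a PSM needs at least one residue after C6, which
excludes matches ending flush at the C-terminus. All anchor placements
are reported, leftmost first, since multi-domain precursors occur. ESM
detection after a PSM defaults to "anywhere downstream of C6";
requiring adjacency is a flag. PSM presence alone marks an ICK
candidate; the ESM flag is recorded separately and does not gate the
call.

## Homology screen

Exact Smith–Waterman local alignment (BLOSUM62, gap open 11 for the
first gap residue, extend 1) replaces seeded heuristics: at the scale
of one merged ORF set against a curated toxin reference, exact DP is
affordable and strictly more sensitive. Significance uses the
Karlin–Altschul expectation E = K·m·n·e^(−λS) with the standard gapped
BLOSUM62 parameters λ = 0.267, K = 0.041 and the actual sequence
lengths as m and n; hits are kept at E ≤ 1e−5. A query inherits the
keywords of every retained target, so per-keyword counts (which count
queries) can sum to more than the number of distinct queries — several
sequences relate to multiple activities. Keywords come from a fixed
sixteen-term activity vocabulary; unknown keywords in a reference map
are errors.

## Profile competition

Each toxin family contributes a position-specific log-odds profile
built from its seed alignment: gap-majority columns are dropped from
the match states; per-column residue probabilities use
background-proportional (Dirichlet) pseudocounts with total prior mass
5 (pseudocount 0.25) — small enough that a handful of seed sequences
dominates the prior, and reducing to plain additive smoothing under a
uniform background; scores are natural-log odds. The default background
is the smoothed residue composition of the seed itself;
`alignment_background` pools several seeds into a database-wide table,
which is what the pipeline uses. A composition-derived background is
essential: against a uniform background, composition bias alone lifts
unrelated sequences above the null.

A sequence is scored against a model by the best ungapped placement of
the match columns (sum of column log-odds; residues outside the
20-letter alphabet score 0). `compete` assigns the best-scoring family,
or none when no model exceeds 0 — the expected score of a
background-composition sequence is −Σ KL(background ‖ column) < 0, so
zero is a natural null. Ties go to the lexicographically first family
name. Full profile-HMMs with insert/delete states are a deliberate
extension point, not implemented: winner-take-all discrimination above
a null is the behaviour the pipeline needs.

## Combining the strategies

Homology queries are deduplicated by redundancy clustering of their
sequences; profile queries falling in a homology cluster form the
overlap; previously reported sequences are subtracted per strategy.
The final count is |nr homology| + |profile| − |overlap| − |previously
reported|. Previously reported ids absent from the hits produce a
warning, not an error, since curation lists routinely outlive the runs
they were built from.

## Maturation

Signal peptides: rule mode requires a leading Met and an uninterrupted
run of ≥ 6 residues with Kyte–Doolittle hydropathy ≥ 1.6 within the
first 30 positions, then takes the shortest signal length in [12, 45)
whose −1 and −3 residues are small (A/G/S/C/T) — the classic
hydrophobic-core + (−3,−1) rule. External predictor output can be
imported from TSV and takes precedence; the rule exists so the
pipeline runs offline, and it is deliberately conservative rather than
a learned model.

Pro-peptide cleavage: di-basic pairs KR/RR/KK/RK (cleavage after the
pair) and the processing quadruplet motif, implemented as an R whose
three preceding residues include at least one E (cleavage after the R),
with the residue set configurable — the quadruplet's exact definition
varies in the literature and this approximation is recorded as such.
Duplicate positions merge with the di-basic label winning. Sites flush
with the C-terminus (no mature side) are dropped.

Mature resolution: the signal is stripped first; the mature start is
the greatest cleavage position at or before the homolog-span start
(the signal cleavage qualifies), the mature end the smallest cleavage
position at or after the span end, else the C-terminus. A mature
peptide is only reported when the N-terminal bound is an actual
cleavage or signal site; otherwise the record keeps its category
(both / signal-only / pro-peptide-only / neither) and no mature
sequence. Homolog spans reaching into the signal region are clipped
with a warning. When several screen hits provide spans, the
highest-scoring hit defines the span (ties: longest). Cysteines are
counted on the mature peptide and odd frameworks flagged.

Naming clusters mature peptides at 0.85 identity; each cluster gets an
index (numbered from a configurable start, default 5, in order of
first appearance) and members get letters a, b, c, … (aa, ab after z)
in input order: `U-theraphotoxin-Pv5a`. The published numbering this
mirrors does not reconcile exactly (65 mature toxins vs 57 indices vs
12 groups holding 74%); the scheme here — one index per cluster, one
letter per member — is declared rather than reverse-engineered.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as a realistic small venom-gland study: 200
precursors in 8 families; signal peptides 15–25 aa, pro-peptides 10–30
aa, mature regions 40–80 aa; every family founder carries a planted
PSM (psm_fraction 1.0); members diverge from their founder at 5% —
matching the screen's design range — and assembler views diverge at 2%
with a 40/30/30 common/pairwise/unique split and 10% added
within-assembler redundancy (truncated, mutated duplicates). References
are 5 point-diverged copies of each founder mature, equal-length and
hence trivially aligned, tagged with one or two activity keywords.

Constructions are exact by design: signals are built so the rule's
earliest valid cleavage is the planted one; mature regions draw spacers
from an alphabet without C/K/R/E so the planted cysteine framework and
cleavage boundaries are unambiguous; mutations never touch anchor
cysteines or cleavage-site residues. All randomness flows from one
integer seed through numpy Generators; iteration order is fixed, so
output is bit-identical across runs and platforms.

What this does *not* emulate — and therefore what passing recovery
tests do not show about real data: assembly artifacts (chimeras,
isoform collapse, frameshifts), realistic residue composition and
length distributions, families with internal indels (real seed
alignments have gaps; synthetic ones do not), signal peptides that
violate the (−3,−1) rule, pro-peptides with non-canonical processing,
and toxins whose homolog support is partial or misleading. Recovery
rates near 100% on synthetic data certify the machinery, not
real-world accuracy of the rule-based predictors.

## Problem sizes and determinism

The test suite runs the oracle-equivalence checks at 1000 random
fixtures per operation and the recovery suite at 200 precursors
(boundary recovery additionally at 500), sizes at which the full suite
completes in well under a minute on one CPU; the acceptance script uses
the generator defaults (200 precursors) and subsamples 60 precursors
for the exact-alignment homology-recall rate, which is stable at that
n. All tests and the script are seeded and deterministic.

## Known limitations

- The clustering is exact greedy DP without CD-HIT's k-mer banding
  heuristics; it reproduces the semantics, not the throughput, and
  nucleotide-mode clustering is out of scope.
- E-value parameters are fixed per scoring system, not estimated from
  the data; composition-based score adjustment is not implemented.
- The signal and pro-peptide rules are intentionally simple; on real
  precursors they inherit the known weakness of di-basic-centric
  prediction for spider toxins, and the import path for external
  predictors exists for exactly that reason.
- Functional annotation (GO-term retrieval, database lookups) is out of
  scope; only the printed-count arithmetic around it is reproduced.
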