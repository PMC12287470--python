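# Methods

This note documents the models and procedures implemented in satarray, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that make
runs reproducible.

## Coordinate and format conventions

All internal coordinates are 0-based half-open on the reference + strand;
conversion happens only at format boundaries (RepeatMasker `.out` is 1-based
inclusive, strand `C` maps to `-`). Readers always return records sorted by
(chromosome, start). Elements whose members are majority minus-strand are
reverse-complemented before segmentation so that units are always read
anchor-first.

## Element consolidation

Repeat annotators fragment long tandem arrays: at diverged stretches, and
wherever a retroelement-derived insertion (the MLT2B4-like "decoys", ~100 bp)
interrupts the array. Consecutive same-family copies on one chromosome are
merged when `next.start − prev.end ≤ gap_threshold`; the default threshold is
1000 bp, with the boundary case (exactly 1000) merging because only strictly
larger gaps split. Strand is ignored for merging: the criterion is genomic
distance only. Decoy-family annotations fully contained in an element
envelope are recorded on the element as reclaimed intervals — they are not
re-labeled in the annotation output (provenance stays auditable), but their
bases count as element territory for expression aggregation, and the
annotation-delta operation quantifies the resulting base-level revision.
Element ids are per-chromosome ordinals in coordinate order (`chr20#4`).

## Unit segmentation and the refine loop

Units begin with a conserved 5-mer anchor, `CAGCT` by default, with explicit
variants `CAGCC` and `CATGT`; an optional Hamming radius around the primary
motif can widen the scan. Segmentation cuts at anchors left to right,
skipping any anchor closer than `min_len` (default 40 bp) to the previously
accepted one; each unit spans its anchor to the next accepted anchor, the
last runs to the sequence end. Sequence before the first anchor is emitted
as a flagged fragment. Units outside [40, 70] bp are kept but flagged
(`irregular_short` / `irregular_long`); units containing N are flagged and,
like irregular units, excluded from alignment and consensus building. The
bounds bracket the four 47–53 bp types with margin. Concatenating all
emitted pieces always reproduces the input sequence exactly.

Alignment of the clean units is anchor-pinned center-star alignment: the
first five columns are fixed (every unit starts at its anchor), suffixes are
aligned pairwise to a deterministic center (modal-length unit, ties by
lexicographic order) under an affine scheme (match +1, mismatch −1, gap open
−3, gap extend −1, via Biopython's PairwiseAligner), and per-center-position
inserts are merged left-justified to their maximum length — making the
result independent of unit input order. The procedure then realigns against
the majority consensus until the consensus is a fixed point (≤ 10 rounds).
Majority consensus is taken over columns with < 50% gaps, ties breaking
toward the alphabetically first base for determinism.

The refine loop automates the manual cut–align–correct curation such arrays
have traditionally required: each round segments, aligns, derives a
consensus, and adds rescue anchors, stopping at a fixed point or after
`rounds` (default 3, matching the two-to-three manual iterations that were
historically needed). Two rescue rules apply, both deliberately confined to
irregular regions (fragments and over-long units) so that substitution noise
inside clean units can never inject spurious anchors:

1. positions whose 5-mer is within 1 mismatch of the consensus anchor
   window;
2. positions where the full consensus matches at ≥ 80% identity — this
   recovers units whose anchor is too diverged for rule 1 (e.g. a 2-mismatch
   anchor corruption), which rule 1 alone provably cannot find.

## Profile model and empirical E-values

The profile is a standard per-column match/insert/delete model estimated
from the unit alignment: columns with ≥ 50% gaps become insert states;
emissions and transitions use an additive pseudocount (default 0.25, Laplace
over four bases — appropriate for training sets of tens to a few hundred
units). Insert openings from delete states are rare and are pooled with
match openings; inserts after the final column are ignored (the model is
local). Scoring is log2-odds Viterbi against a background base composition
(uniform by default), local on both sides: paths enter and leave the profile
at any match column for free, since units can be truncated at element edges.
The batch scorer is exact and is verified in the test suite against
exhaustive path enumeration on small profiles.

Significance is calibrated empirically rather than analytically: maximum
local scores of seeded random background sequences (default 5000 sequences
of 200 bp) are fitted to a Gumbel distribution, giving
`E(S) = K·m·n·2^(−λS)` with `λ = 1/(β ln 2)` and `K = e^(μ/β)/(m·n₀)` from
the fitted location μ and scale β. The calibration seed is stored in the
model, so E-values are reproducible. Search slides overlapping windows
(width 3m, step m), resolves each promising region by traceback, masks it,
and rescores affected windows — realizing greedy best-score-first
non-overlap selection (ties to the leftmost start). Hits must satisfy
E < 0.01 (default) *and* span at least half the profile columns: the Gumbel
tail fitted from ~200 bp maxima is not sharp enough to support the
significance of very short local fragments, and the search targets units,
not fragments. Forward-algorithm E-values are out of scope (Viterbi only).

## Unit types and the variable region

Each unit is a conserved scaffold with a mid-unit variable region. The
scaffold is 41 bp — a 25 bp 5′ block beginning with the anchor and a 16 bp
3′ block — so the variable region occupies unit offsets 25..(L−16) (0-based)
and a type's nominal length is 41 plus its motif width. The four motifs are
`CATCAG` (47 bp), `CAA-A--G` (49 bp), `CAACACCAG` (50 bp), and
`CAGCAGCACC-G` (53 bp). Dash characters mark weakly conserved positions and
are matched as wildcards; the motif *width* (dashes included) is the
variable-region length, which is the only reading under which all four
printed type lengths are consistent with a single shared scaffold, and under
which the tree-building span (consensus columns 26–37, twelve columns)
coincides exactly with the 53 bp type's variable region. Classification
keys on length first (variable-region width must match a type) and accepts
at ≤ `max_mismatch` (default 1, the smallest nonzero tolerance) mismatches
at non-wildcard positions; everything else is "unassigned". An element's
type is the modal type of its units. Logo matrices report per-column base
frequencies (gaps excluded, depth renormalized) and information content
`IC = 2 + Σ p·log2 p` bits.

The type table, scaffold sequences, and the variable-region boundary are a
user-editable YAML config; the packaged defaults are synthetic scaffolds
(see below), and users working from real alignments can substitute scaffolds
transcribed from their own consensus logos.

## Expression

The module consumes per-interval count tables; read mapping, QC, and
multi-mapping resolution are upstream concerns (quantification of repeats
depends on the counter used — an optional fractional-weight column is summed
as-is). Element counts sum member intervals plus reclaimed decoy intervals,
because a consolidated element is transcribed as one continuous region.
Library sizes are an explicit input defaulting to column sums; pass the true
mapped totals when the table is a subset. CPM is `count/library·10⁶`,
optionally `log2(CPM+1)`. Stage summaries are per-feature means (or medians)
over the stage order GV, MI, MII, PN, CL, MO, IC, TP. Group comparison is a
two-sided pooled-variance Student's t-test by default (a paired mode is
available — the choice of test variant and of CPM vs log2 scale is exposed
because either is defensible for matched designs); zero-variance degenerate
inputs report p = 1 (equal means) or a p at the floating-point floor
(unequal means). No multiple-testing correction is applied by default; a
Benjamini–Hochberg helper is provided.

## Trees and comparative analyses

Variable-region trees use p-distances (mismatches over columns where neither
sequence is gapped) over consensus columns 26–37 and neighbor joining, with
negative branch lengths clamped to zero and Newick output. NJ on p-distances
is the deliberate desk-scale substitute for external maximum-likelihood
inference: it is dependency-free, deterministic, exactly recovers additive
distances (verified on randomized additive matrices up to 8 taxa), and the
Newick output lets users re-estimate with an ML tool if desired. Taxa
default to individual units; the pipeline subsamples evenly to at most 60
taxa to keep the cubic NJ cost negligible. Cross-assembly comparison takes
an explicit element pairing (synteny discovery, e.g. by BLAST, is out of
scope) and reports lengths, global-alignment identity under the same affine
scheme, and total gap bases. Per-assembly tallies report summed family bp
and the share of the grand total, with absent families reported as zero.

## Synthetic data generator

The generator emulates the study conditions end to end: tandem arrays of
47–53 bp units sharing the CAGCT anchor; per-base substitution noise with
optional anchor protection; ~100 bp anchor-free decoy insertions placed
between whole units (matching the observed pattern of continuous
transcription across insertions; a mid-unit corruption mode exists behind a
flag for robustness testing); fragmented annotations split at each decoy so
consolidation must re-merge them; and stage-structured counts drawn from a
negative binomial (size r, default 10; Poisson in the r→∞ limit) whose focal
feature is high from GV through CL (default mean 300) and low from MO
through TP (default 15) against flat background features, with library size
10⁶ and 3 samples per stage. All outputs are bit-identical under a fixed
seed, and every truth object records its seed.

The default scaffolds are fixed arbitrary sequences of the derived lengths
(5′ `CAGCTGTGCTCATTTCCAATAAGAC`, 3′ `AGGACTCGATTGAACG`), chosen by
constrained search so that in tandem context no 5-mer other than the true
anchor matches any anchor motif, and every 5-mer starting at unit offset
≥ 38 (including junctions into the next unit's anchor) is ≥ 3 mismatches
from all three motifs. The margin matters: with greedy `min_len = 40` anchor
acceptance, spurious anchors at offsets < 40 are harmless, but an anchor
created by noise in the unit tail would shift a boundary — the Hamming
margin makes that require three simultaneous specific substitutions,
negligible at the 2% study noise rate. Wildcard motif positions get fixed
default fills.

What the generator does **not** emulate: sequencing errors and read-level
artifacts (counts are drawn directly), higher-order repeat structure beyond
simple tandem stacking, indel polymorphism between units, GC-biased
background composition, and real decoy sequence (decoys are anchor-free
random sequence). Passing tests therefore demonstrate correctness of the
algorithms under controlled noise, not performance on real annotation
tracks, where divergence structure is richer and boundary cases are harder.

## Problem sizes and numerical choices

The test and acceptance workloads use arrays of 10–60 units and genomes of
4–5 elements, profile calibration with 2000–5000 random sequences, and
100-trial tree recovery — sizes chosen so the full validation runs in well
under a minute per component while still exercising every code path at
realistic unit counts per element. Tolerances: floating-point comparisons at
1e-6 to 1e-9 where closed forms exist; stochastic assertions (recovery and
accuracy rates) at the rates stated with fixed seeds. All tie-breaks
(consensus bases, anchor conflicts, hit selection, NJ joins) are
deterministic and documented above.

## Known limitations

- The profile search's Gumbel calibration extrapolates the tail from random
  maxima; the half-profile span requirement compensates, but E-values for
  marginal short hits should not be over-interpreted.
- Center-star alignment with consensus iteration is not guaranteed optimal
  for highly diverged unit sets; for the ≤ 10% divergence regimes this
  family exhibits it is accurate and order-independent.
- Elements with fewer than two clean units cannot support alignment,
  profile, or logo stages; the pipeline skips those stages and logs it.
- Expression results inherit whatever multi-mapping policy produced the
  input counts; repeat expression estimates are only as good as the
  upstream counter.
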