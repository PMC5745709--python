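# Methods

## The model

Mitochondrial gene orders in metazoans are conserved in content (13
protein-coding genes, 2 rRNAs, 22 tRNAs on a circular ~16.5-kb molecule)
but variable in arrangement. The duplication–random-loss (DRL) mechanism
explains most rearrangements: a contiguous block of genes is duplicated in
tandem; for each gene one of the two copies eventually sustains a
loss-of-function mutation, leaving selection to preserve the other; the
dead copy decays and is ultimately deleted. Which copy survives at each
position determines whether the original order is restored or a new one is
fixed.

`mitodrl` formalizes one DRL event as a pair *(span, retention)*: a
contiguous arc of the ancestral circular order, plus a per-position
retention value in {`first`, `second`, `both`, `remnant`}. `both` keeps
both copies intact (the fate of the duplicate tRNAs); `remnant` keeps both
but one as a recognizable pseudogene — because "remnant" alone does not say
*which* tandem copy decayed, the scenario carries a companion
`pseudogene_copy` map so that forward replay is fully determined.

## Single-DRL inference

Given ancestral and derived orders, the inference enumerates every
candidate span and asks whether the derived arrangement is reachable by
one DRL event. The criterion follows directly from the mechanism: after
tandem duplication and loss, the surviving span copies form one contiguous
block sitting where the original span was, and the block read left to
right must decompose into two subsequences — copy-1 survivors then copy-2
survivors — each strictly ascending in span order, with genes retained
twice present in both and pseudogene marks consistent (a gene's sole
surviving copy may not be a pseudogene; at most one of two copies may be).
Every candidate that passes is verified by forward replay before being
reported. Reported spans are containment-minimal: a span strictly
containing another reported span is dropped, but incomparable arcs are all
reported — on a circle a derived order often admits several genuinely
different minimal explanations, and the package does not pick among them.

Two scoping decisions: strand changes reject a pair outright (DRL
duplicates in place and never inverts), and the ancestral order must have
unique labels. Derived orders may repeat labels freely (that is the
point), but a repeated-label *ancestor* makes the copy correspondence
ambiguous; decayed repeat tracts and pre-existing pseudogenes should be
filtered out of the orders before inference (`extract_gene_order`
supports this), which in practice restores uniqueness. Linear inputs are
handled exactly by embedding them in a circle with a sentinel element that
no span may cover.

Spacers and the control region are first-class order elements by default,
since observed duplications include intergenic spacers; they can be
excluded with a flag when repeat tracts have decayed beyond recognition.

## Pairwise alignment and decay quantification

The aligner is a standard Gotoh three-state dynamic program for global
alignment with affine gaps; a length-*L* gap run costs
`gap_open + L·gap_extend`. Defaults are integer-valued (match +1,
mismatch −1, gap_open −2, gap_extend −1) so that optimality can be checked
bit-exactly against exhaustive path enumeration; the published analyses
used ClustalW, whose scores are not reproducible bit-for-bit, and the
difference summaries reported here are insensitive to reasonable scoring
choices when edits are well separated. Traceback ties break
deterministically: diagonal, then gap-in-query (deletion from the
candidate), then gap-in-reference (insertion into the candidate).

Differences are summarized per alignment column: a maximal gap run in the
reference row is one insertion event (the candidate gained bases), in the
query row one deletion event. **Identity is matches divided by total
columns, gap columns included** — this is the convention under which the
printed worked-example counts (a 682-bp reference with 30 substitutions,
one 2-bp deletion and 5 bp of insertions) reproduce 650/687 = 94.6%
exactly. Columns containing N count toward the total but are neither
matches nor substitutions, and N scores neutrally (0) in the aligner.

ORF scanning uses the vertebrate mitochondrial code (stops TAA, TAG, AGA,
AGG; starts ATG, ATA, GTG) over the three forward frames; paralogs retain
the strand of their functional copy, so reverse-frame scanning is off by
default but available. An ORF runs from a start codon to the next stop
(amino-acid length excludes the stop) or to the sequence end
(`open_ended`). ORFs shorter than 2 aa are suppressed by default — a lone
in-frame start codon at a sequence edge is noise, not residual coding
potential.

Paralog classification uses three pieces of evidence: alignment identity,
a premature-stop flag, and the candidate/functional length ratio. The
premature-stop flag is *relative*: the candidate's frame terminates
strictly earlier than the functional copy's, so a perfect copy of any gene
is never flagged. Calls: identity below 0.50 → `unrecognizable` (random
DNA aligns at roughly 25–40% under these scores, well below this);
identity ≥ 0.98 with an undisrupted frame and length ratio ≥ 0.9 →
`intact`; otherwise `pseudogene`. Thresholds are configurable.

## Divergence

*D*<sub>XY</sub> is the mean proportion of differing sites over all
between-group pairs, Jukes–Cantor corrected:
*d* = −(3/4)·ln(1 − 4p/3), defined for p < 0.75. Sites with a gap or N in
either sequence of a pair are excluded pairwise (complete deletion per
pair, not listwise, to maximize comparable sites). The correction is
applied to the mean p by default; whether published estimates applied JC
per pair or to the mean is generally not stated, so per-pair correction is
available behind a flag — at shallow divergence the two differ only by a
Jensen-gap term far below sampling noise. No variance is attached to the
estimate.

## Event mapping

The gene order of each sampled individual is an unordered multistate
character on a rooted tree; each rearrangement counts as one step (no step
matrix). The bottom-up pass is classic Fitch set intersection/union and is
exposed as `ancestral_sets`; the minimum change count, one
most-parsimonious reconstruction (ties resolved toward the parent's
state) and the exact number of MPRs come from a unit-cost Sankoff dynamic
program, which agrees with Fitch on the minimum and additionally supports
counting. Change counts are invariant to rooting; placements require a
root, so unrooted input is rooted at a user-chosen outgroup (or an
arbitrary edge otherwise) and polytomies are resolved arbitrarily —
resolution cannot change the minimum for an unordered character. Species
polymorphic for gene order contribute one tip per individual, never a
per-population state: with few individuals per species, fixation within
populations cannot be asserted.

## The simulator

The synthetic genome is a list of segments that tile a circle exactly, so
duplication and deletion are exact sequence surgery and every coordinate
shift is implicit. The default template is the typical vertebrate
mitochondrial order — 37 genes with ND6 and eight tRNAs on the minus
strand, one intergenic spacer between trnT and trnP (the position that
participates in the observed salamander duplications) and a control
region. Default lengths are drawn per class (protein 300–1800 bp, rRNA
800–1700 bp, tRNA 65–75 bp, control region 800–1500 bp), giving genomes of
roughly 17–20 kb; per-gene lengths can be pinned, and the two-event preset
pins the decay-relevant genes to representative values (ND6 519 bp, ND1
960 bp) so planted edit arithmetic lands on realistic sizes. Protein genes
are generated as valid ORFs (start codon, stop-free interior, terminal
stop).

Sequence evolution is Jukes–Cantor: each targeted site substitutes
independently at the given rate, uniformly to one of the three other
bases; indel events are Poisson per site with geometric lengths (mean 2,
matching the small observed indels of 2–5 bp). Every applied event —
duplication, substitution, insertion, deletion, segmental deletion,
rotation — is appended to a `TruthRecord` with coordinates valid at
application time, so replaying the log on the ancestral sequence
reproduces the final genome byte-for-byte; this replay identity is the
simulator's core invariant and is tested on random operation pipelines.
Loss of function is emergent from substitutions and frameshifts, with a
`plant_premature_stop` option for deterministic tests.

`plant_edits` is the deterministic counterpart used for exact-recovery
tests: it places a requested edit load with at least `min_gap` (default 8)
unedited sites between edits, pins deletions so their gaps cannot slide to
an equal-scoring placement, and draws inserted bases differing from both
flanks. Under these conditions the optimal alignment is unique in its
difference counts and recovery is exact; when edits may abut (the `evolve`
process), alignment ambiguity makes counts approximate, and the recovery
tests assert agreement within ±10% on totals over 50 replicates.

The `aneides` preset composes two events on one genome: a basal
duplication of (ND6, trnE, CYTB, trnT, IGS, trnP) resolved so that CYTB
comes to precede ND6 with a recognizable trnP pseudogene left behind, then
a recent duplication of the (ND6 … ND1) arc spanning the control region
and both rRNAs, with one ND6 and one (682-bp-truncated) ND1 copy decayed
to pseudogenes, the duplicate rRNA block deleted down to a 111-bp
unrecognizable remnant, and duplicate tRNAs left essentially intact. What
the preset emulates — and what it does not: sequences are i.i.d. uniform
DNA without codon bias, strand-asymmetric mutation, rate heterogeneity or
realistic tRNA/rRNA structure, so passing recovery tests demonstrates the
correctness of the bookkeeping, the inference algebra and the estimators
under the stated model, not robustness to every property of real
mitogenomes. Depth tracks, read-level data and selection are out of scope.

## Numerical and edge-case choices

- Coordinates are 0-based half-open internally, 1-based inclusive on disk
  (GFF dialect); origin-wrapping features use `end > genome length`.
- Circular orders canonicalize by rotating to trnF (falling back to the
  lexicographically smallest label), tie-broken by smallest element tuple;
  equivalence testing uses anchor-free minimal rotation so it never
  depends on the anchor choice.
- The depth-ratio background uses a trimmed mean (5% per tail) to resist
  control-region pileups; a zero background is an error, as is an empty
  background.
- `jukes_cantor` raises at p ≥ 0.75 (saturation); `p_distance` raises
  when no comparable sites remain.
- D_XY simulations at planted divergence 0.024 over 10-kb sequences are
  asserted within three Monte-Carlo standard errors
  (≈ 3·√(p(1−p)/L) ≈ 0.0046); with sequence length the estimator's bias
  vanishes, checked at 10³ and 10⁴ sites.
- Exhaustive oracles bound the battery sizes: alignment enumeration at
  lengths ≤ 8, DRL enumeration at order length ≤ 7 (5 retention choices
  per span position), Fitch enumeration at ≤ 8 tips; these sizes keep the
  default test run to a couple of minutes on one core while covering the
  combinatorics densely.

## Known limitations

- DRL inference composes single events only; multi-event scenarios are
  analyzed event by event against intermediate orders, and sorting
  distances (minimum number of DRL events between arbitrary orders) are
  out of scope, as are inversions, transpositions and tRNA remolding.
- The aligner is nucleotide-only; codon-aware alignment could shift
  indel placements in coding pseudogenes by a few columns.
- tRNA functionality is proxied by sequence identity, not by folding
  into cloverleaf secondary structure.
- Reported identity percentages depend on the matches/columns convention;
  other conventions (gap-excluded denominators) give values a few tenths
  of a percent different and are not implemented.
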