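# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Coordinates and the in-memory model

All intervals are 0-based half-open genome coordinates; GenBank's 1-based
inclusive convention is converted at the I/O boundary (human-readable TSV
output converts back). Exon lists are kept in transcript order — descending
genome coordinates for minus-strand genes — so splicing is "concatenate,
reverse-complementing each minus-strand piece". Features wrapping the
circular origin are stored as two intervals with a wrap flag, and the two
flanking pieces count as a single exon for intron arithmetic. Circular
intervals elsewhere (IR annotations, gene spans) are `(start, end)` pairs
with `end` allowed to exceed the genome length to denote wrapping.

Only CDS features are ingested; tRNA/rRNA annotations are ignored because
the analyses are defined over a 72-gene protein-coding panel. Gene symbols
are case-folded and resolved through a curated synonym table (e.g. *pbf1* →
*psbN*, *ycf9* → *psbZ*); trailing copy designators (`_1`, `-A`) are
stripped only when the bare symbol is not itself a panel name, which makes
normalization idempotent. Symbols outside the panel are rejected at parse
time and never reach any analysis. Pseudogene copies (`/pseudo`) are parsed
but excluded from the panel by default: presence/absence statements should
not conflate pseudogenes with functional copies. CDS features with a
`/trans_splicing` qualifier — or with exon gaps above 20 kb, the situation
of *rps12* whose 5' exon lies tens of kilobases from the 3' cluster — are
flagged trans-spliced; their intron count is undefined and reported NA, and
their position in the gene order is the start of the 3' exon cluster.

## Taxon and occupancy filters

A genome is removed when strictly more than 50% of the 72-gene panel is
absent (zero non-pseudo copies); 36 of 72 missing is kept, 37 is removed.
For supermatrices, seven genes (*ndhF, psaA, psaB, rpoB, rpoC1, rpoC2,
ycf2*) are dropped unconditionally — they are chronically mis- or
un-annotated in public plastomes — and any remaining gene whose
missing-cell fraction (gap characters plus wholly absent taxa, measured
against the cohort's taxon universe) strictly exceeds 50% is dropped too.

## GC by codon position

Reading frame starts at position 0 of the spliced CDS; a trailing partial
codon is ignored; ambiguity codes are excluded from numerator and
denominator; stop codons are counted like any other codon. GC12 and GC123
are computed from pooled base counts, which coincides with the arithmetic
mean of the positional fractions whenever the sequence is codon-complete
and unambiguous (asserted to 1e-12 in the tests). Multi-copy genes are
measured on the first copy by coordinate (IR copies are identical in
practice and determinism matters); averaging over copies is available.
Clade aggregation defaults to the unweighted mean over genomes — each
species counts once — with a pooled-base mode available, since published
per-clade averages rarely state their weighting.

Group comparisons use Student's two-sample *t*-test with pooled variance
(Welch optional), significance stars at 0.05/0.01/0.001. Degenerate inputs
are resolved explicitly: identical constant groups give t = 0, p = 1;
distinct constants give ±inf, p = 0. Groups with fewer than two values are
an error, and the per-gene in-IR/out-IR comparison skips genes whose
classes are that small.

## Inverted-repeat detection

`detect_ir` searches for the longest pair of disjoint segments on the
circle where one segment equals the reverse complement of the other. All
circular k-mers (k = 25, exact 2-bit packing, ambiguous windows excluded)
of the sequence are matched against those of its reverse complement; hits
on a common anti-diagonal are merged into maximal runs (including across
the origin), each run corresponding to one maximal repeat pair. Candidates
shorter than `min_ir_len` (default 1000 bp, matching the scale at which
single-copy/IR architecture is meaningful) or overlapping themselves are
discarded; ties break toward the longer repeat, then the smaller start
coordinate. With k = 25 the chance of a spurious seed in a 200 kb genome is
negligible, so exact matching (the default) recovers planted repeats at
exact coordinates. `max_mismatch > 0` bridges seed gaps on a diagonal with
an estimated mismatch count — a heuristic escape hatch for degraded
repeats, not the validated path. The two single-copy gaps between the
repeats are named by length (longer = LSC); naming is content-free and
deterministic. A gene copy wholly inside IRA∪IRB is "IR", wholly inside a
single-copy region takes that name, and anything straddling a boundary is
reported as an explicit "junction" class rather than being forced into
either side; a gene is "in-IRs" for a genome when at least one copy is
IR-located.

## Gene orders and blocks

A genome's order is the sequence of (gene, strand) pairs sorted by 5'-most
coordinate, both IR copies retained (orders follow annotated positions, and
collapsing IR copies would silently change adjacency structure at the
IR/SSC boundaries). Orders hash by their canonical form: the
lexicographically smallest rotation of the sequence or of its mirror
(reversal with strands flipped), making comparisons invariant to how a
circular molecule was linearized or oriented. Deduplication collapses
identical canonical orders within a taxonomic order to the smallest
accession; a looser content-only (gene-set) signature is available.

A block matches a genome when some window of consecutive elements equals
the block's genes with identical strands, or the mirrored block, windows
wrapping the origin allowed; a sign-insensitive mode exists because
published block labels carry no strands. Block frequency divides by all
representatives by default; a present-only denominator (genomes containing
all the block's genes) is provided and reports NA when empty.

Conserved-chain discovery builds a signed adjacency graph: the frequency of
adjacency a→b (orientation-normalized so a→b pools with −b→−a) is the
share of genomes in which it occurs. Chains grow from qualifying
adjacencies (≥ `min_freq`, default 60%) along qualifying edges, under two
side conditions that pin down the corner cases: a chain may not repeat a
gene, and every intermediate chain must actually occur contiguously in at
least one genome (the pooled graph alone can assemble chains no genome
contains). Reported chains are maximal — no single-gene extension both
qualifies and occurs — and a chain closing around an entire genome is
collapsed to one canonical circular block rather than being reported once
per rotation. A chain's reported frequency is its whole-block occurrence
share, which can never exceed its weakest internal adjacency. The test
suite checks this whole semantics against an independent exhaustive window
enumerator on hundreds of randomized cohorts.

## Supermatrices

Retained per-gene alignments are concatenated in alphabetical gene order
(input order available), absent taxa gap-filled, and the gene → column
interval map recorded; partitions must tile the matrix exactly. nt12 keeps
columns ≡ 0,1 (mod 3) within each partition, so a codon-complete matrix
loses exactly one third of its columns. Translation uses the
plastid/bacterial genetic code (table 11); all-gap codons stay `-`,
partially gapped or ambiguous codons become `X`, internal stops translate
to `*`. `?` on input is normalized to `-`. On real data the AA matrix need
not be exactly one third of nt123 when amino-acid alignments are trimmed
independently; the identity is asserted only for matrices derived from one
another.

## The synthetic cohort generator

The generator emulates the structural features the pipeline measures: a
circular quadripartite genome assembled from a reference signed order (56
LSC genes, 5 IR genes — *rpl2, rpl23, ndhB, rps7, rps12* — and 11 SSC
genes, modeled on the canonical angiosperm arrangement so the classic
named blocks are present by default), coding sequences drawn per codon
position from Bernoulli GC targets, introns for the usual intron-bearing
genes (two for *clpP*), and an IRB that is the literal reverse complement
of the assembled IRA segment. Defaults: gene lengths 300–1500 bp
(realistic values clamped to that range), 200 bp spacers at GC 0.30,
150 bp introns, 3 kb of non-genic fill inside the IR, global GC targets
(0.45, 0.40, 0.30), and two gene-class overrides reproducing the conserved
vs non-conserved *psb* GC contrast (≈42% vs ≈33.8%). Events planted per
genome — losses, LSC inversions, IR boundary expansions, GC shifts — are
applied in schedule order, and every planted fact is returned in a truth
record. One spacer base at each repeat boundary is adjusted so the planted
repeat is maximal, making "exact coordinate recovery" a well-posed check.
Output is deterministic and byte-identical for a given seed.

What it does not emulate: substitution processes along a phylogeny,
indels, codon-usage structure beyond positional GC, intergenic sequence
realism, or tRNA/rRNA genes. Passing tests therefore demonstrate correct
recovery of arrangement, composition and architecture signals, not
robustness to alignment error or annotation noise in real archives.

## Problem sizes and determinism

The validation suite runs at deliberately moderate scales — a 200-genome
cohort for truth recovery, 200 randomized small cohorts for oracle
equivalence, 100 planted repeats of 5–25 kb, 2,000 replicates for type-I
calibration — chosen so the full suite completes in well under a minute of
compute per property while keeping binomial/SE margins tight. All
randomness flows through explicit seeds; pipeline reruns with identical
inputs and configuration are byte-identical.

## Known limitations

- The trans-splicing heuristic (20 kb exon gap) can misclassify a gene
  with a genuinely enormous intron; the explicit qualifier always wins.
- `detect_ir` reports only the single best repeat pair; genomes with
  multiple independent long repeats expose only the longest.
- Chain discovery enumerates realized chains; on adversarial cohorts with
  dense qualifying graphs the search is budget-capped and raises rather
  than silently truncating.
- The junction class is assigned from detected IR boundaries; when
  detection fails (no repeat ≥ `min_ir_len`) every gene is reported
  out-IRs with a warning rather than guessing.
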