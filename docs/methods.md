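# Methods

This note documents the models, algorithms and numerical choices behind
`merlintools`, in the order the pipeline applies them, together with what
the synthetic-data generator does and does not emulate.

## Synthetic genomes (`simgenome`)

The generator plants complete Merlin-like elements into an i.i.d. random
background (uniform nucleotides, tunable GC). That null is deliberate: it
is the simplest background that does not itself produce detectable
inverted repeats or tandem arrays at the scales the detectors operate on,
so every positive call on simulated data is attributable to a planted
feature.

An element is assembled as `TIR5 + UTR5 + ORF + UTR3 + TIR3`:

* **TIRs.** The 5' TIR is random (forced to start `GG` when
  `terminal_gg`); the 3' TIR is its reverse complement with exactly
  `tir_mismatches` substitutions planted at scattered positions. Three
  construction constraints keep the planted parameters recoverable rather
  than merely nominal: the terminal `GG`/`CC` and the innermost TIR base
  are never mutated, mismatch positions are re-drawn until no run of 4+
  consecutive mismatches exists (the detector's stop rule would otherwise
  truncate the repeat), and the four interior positions adjacent to each
  TIR are set to *not* extend the inverted repeat — a real TIR has a
  defined internal border, and without this the "true" maximal repeat
  would be the planted one plus a random-length extension.
* **ORF.** The transposase protein is built around the three consensus
  DDE blocks with random linkers (50–70 aa between blocks 1 and 2,
  15–25 aa between 2 and 3, clamped for short ORFs), then
  reverse-translated with uniformly random synonymous codons. An in-frame
  stop is placed immediately before the ATG so the planted ORF is exactly
  the first ATG of its stop-to-stop segment.
* **TSDs.** Drawn independently per copy (resampled until pairwise
  distinct within a family) and written identically on both flanks —
  matching the biological fact that TSD composition differs among
  transposition products.
* **Degeneration.** Intact copies receive per-site substitutions at
  `per_copy_divergence`; substitutions falling in the ORF are resampled if
  they would create a stop codon or destroy the ATG, so a copy recorded
  as intact in the ground truth genuinely has an intact ORF at the
  recorded nucleotide divergence. Frameshifted copies additionally get
  1–2 single-nucleotide indels inside the ORF. Remnants are random
  40–80 % truncations (no published degeneration model exists for
  remnants; this truncation model is a package decision, not an inferred
  mechanism). Segmental-duplication copies are pasted together with
  500 bp of shared flank and carry the *same* TSD.
* **Contamination.** Contaminant contigs carry three ORFs copied from a
  bundled bacterial-like decoy protein set (generated deterministically
  from a fixed internal seed) with ~2 % residue mutation, so their
  identity to the decoy set is >98 %, safely above the 80 % rule.

What the generator does **not** emulate: host genes and their composition
biases, nested/composite insertions, polycistronic context, GC
heterogeneity along a chromosome, sequencing/assembly error, or realistic
codon usage. Passing tests therefore demonstrate correctness of the
detectors under clean insertion geometry with known truth — not
performance on real assemblies, where boundary noise and repeat context
are harsher.

## DDE-domain scan (`orf_domain`)

The catalytic domain is modelled as three blocks with invariant D/D/E
anchor residues. The bundled block alignment is synthetic: it encodes the
published *description* of the domain (three conserved blocks around the
triad, block 1–2 separation of ~50–70 aa with outliers to ~110, short
block 2–3 spacing) rather than any particular alignment, whose rows are
not redistributable here. Columns get +0.5 pseudocounts and are scored as
log2 odds against a uniform 1/20 background. The scanner evaluates every
block placement satisfying the spacing windows (linker 40–120 aa and
10–60 aa) by dynamic programming, breaking ties leftmost. The default
acceptance threshold is 70 % of the profile's own-consensus score; the
per-block threshold for "block present" (used for truncated-domain calls)
is 70 % of that block's consensus score. At these settings the empirical
false-positive rate on random 400-aa proteins is below 1 % (tested at
n = 1000). The profile is serializable to JSON so users can substitute
their own block alignment.

ORF discovery reports maximal stop-to-stop ORFs with an in-frame ATG in
all six frames; ORFs running off a contig end are not called (the
extraction stage flags truncated windows instead).

## Translated search and copy extraction (`copyfinder`)

Seed-and-extend against all six frame translations: exact 4-mer seeds,
ungapped X-drop extension (drop 14, BLOSUM62), gapped local re-alignment
of surviving segments (BLOSUM62, gap open −11 / extend −1). Significance
is the Karlin–Altschul expect value with the standard gapped BLOSUM62
parameters (λ = 0.267, K = 0.041) over the translated database size, so
the conventional two-round cutoffs (1e−4, then 1e−3) behave as expected.
Overlapping same-strand hits to different queries collapse to the best
scorer; hits within 300 nt on one strand merge into one copy (frameshifted
copies split their hits; 300 nt covers the indel scale the simulator
plants). Copies are extracted with 2-kb flanks — comfortably more than
the largest TIR (462 bp) plus TSD plus boundary slack.

Copy status: `intact` if one re-called ORF carries a full three-block
motif; `frameshifted` if all three blocks are present in the element
region but not in a single ORF; `remnant` otherwise.

Segmental duplications are flagged when two copies' 5' **and** 3' flanks
each align at ≥ 90 % identity over ≥ 200 bp; copies with truncated or
short flanks are *undetermined* (`None`), which is deliberately distinct
from `False`.

## Boundary inference (`boundaries`)

Copies plus up to 1.3 kb of flank are center-star aligned and per-column
mean pairwise identity is computed with gap-containing pairs counted as
mismatches. A pairwise aligner inflates the apparent identity of
unrelated flanks (it pairs whatever happens to match — ~0.52 mean column
identity for two random sequences under these scores), so the boundary
threshold is adaptive: never below the nominal 0.5, and raised to halfway
between the flank null (estimated from the outermost alignment columns)
and the conserved-core peak. The scan walks outward from the most
conserved column until the smoothed identity stays below threshold for 8
consecutive columns, then a changepoint fit over ±15 columns refines the
edge; a clean raw-identity step (≥ 0.4 drop across 5 columns) is reported
`sharp`, otherwise `fuzzy`. Ends where conservation never drops — no
flanks in the alignment, or identical flanks as in segmental duplications
— are `unresolved`.

Alignment evidence alone leaves a few bp of ambiguity (chance-identical
flank columns), so element limits are then *snapped to structural
evidence*, iterated to a fixpoint:

1. **TSD snap.** The TSD search scans ±3 bp of boundary jitter; when the
   best parse needs a shift, the element bounds move to the TSD-defined
   insertion site and the search repeats (a parse outside the jitter
   window can become visible after the first snap).
2. **TIR rescue.** If no TSD is found, a GG-terminal TIR found in a
   slack-extended window (±15 bp beyond the called element) re-cuts the
   element at the repeat's anchors, and the TSD search runs again.
3. **Cross-copy harmonization.** One family has one TSD length. A
   duplication whose first/last base chance-matches the adjacent sequence
   admits rotated parses at k±1 with shifted bounds; the modal k across
   the cluster re-resolves minority calls, and members with no TSD at all
   are rescued with a wider (±8 bp) scan at the family's k.

TSD parse ranking, in order: parses whose implied element starts `GG` and
ends `CC` (the superfamily signature) win; then k ∈ {8, 9} (the
superfamily's duplication sizes) over 7 or 10; then the smallest boundary
shift; then the longest k. TSD matching itself is exact — the whole point
of a TSD is that conservation between the two flanks signals recency, and
allowing mismatches would blur that evidence.

TIR detection enumerates anchor pairs within a slack window of the
sequence ends and extends inward while the cumulative mismatch fraction
stays ≤ 0.5, stopping at 4 consecutive mismatches. Candidates must end on
a match; for each anchor both the best-scoring length (score = length −
2 × mismatches) and the longest admissible length are kept, because for
highly imperfect TIRs the structurally meaningful repeat is *not* the
best-scoring one — the published 12-mismatches-in-26 family is exactly
such a case, and `tir_at_length` quantifies imperfection at a length
established from other evidence. The `extendable` flag marks candidates
stopped by the run rule, mirroring the reported families whose internal
TIR borders "could be extended considering additional mismatches"; where
that border truly is remains a judgment call and the stop rule is this
package's concrete stand-in for it.

Classification: `family_candidate` = GG-terminal TIR **and** TSD;
`group_member` = intact motif without that structural evidence;
`remnant` = the rest.

## Families, trees and consensus (`families`)

Clustering uses single linkage at 0.25 divergence. The divergence used
for *clustering* is 1 − (matches / global alignment length): the
pairwise-deletion p-distance systematically understates how different
unrelated sequences are (the aligner pairs what it can and gaps the
rest), which would merge unrelated families. Within-family divergence
statistics still use the classical p-distance. The 0.25 linkage threshold
is a package decision — no published number exists — chosen so families
at the divergences reported for active elements (≤ ~15 %) stay connected
while unrelated elements (global identity ≈ 0.45–0.55) never join; it is
exposed as `family_linkage` in the config. Clusters whose members' TIRs
differ at > 30 % of positions are split. Family ids are numbered by
descending size (F1, F2, …; groups G1, G2, …).

Neighbor joining is implemented directly (Saitou–Nei, smallest-index
tie-breaking for determinism) and cross-checked in the test suite against
scikit-bio's implementation and against exhaustive least-squares topology
search on 5-taxon additive matrices. Bootstrap support resamples
alignment columns with replacement and counts the fraction of replicate
trees containing each internal split.

Degenerate consensus calls a base on a strict majority (> 50 %) of
non-gap residues and otherwise emits the minimal IUPAC code covering the
observed bases; an exact two-way tie — the normal situation when the two
rows are a TIR pair — therefore produces the degenerate code, which is
how family TIRs are conventionally displayed. All-gap columns drop.

Activity dating is a coarse heuristic: `recent` needs mean within-family
p-distance ≤ 0.02 *and* ≥ 2 distinct TSDs; `ancient` needs a TIR/TSD-less
group at mean distance ≥ 0.15; everything else, including single copies,
is `unclear`.

## Tandem repeats (`repeats`)

For every period the sequence is compared against itself shifted by the
period, positions score (match − 0.8), and the Ruzzo–Tompa all-maximal-
scoring-subsequences decomposition yields the repeat runs — a canonical,
direction-independent segmentation, so calls mirror exactly under
sequence reversal. A run of span s at period p is reported with
fractional copy number s/p + 1 (floor 1.5). Harmonic duplicates (period a
multiple of an equally clean smaller period, covering the same region on
both sides) are suppressed; genuinely nested repeats with unrelated
periods — such as a 6-bp unit inside a 52-bp unit — are reported at both
scales. Since sequences here are short (elements, not chromosomes), all
periods from 2 to 200 are scanned directly rather than pre-filtered by
autocorrelation peaks.

## Contamination (`contamination`)

Best local-alignment identity against a bacterial reference set, counted
only when ≥ 50 % of the query aligns (the coverage floor prevents short
spurious matches from triggering the rule; published practice is silent
on this). Strictly > 80 % identity → contaminant; 40–80 % → suspect,
upgraded only when ≥ 2 neighboring ORFs within 10 kb independently exceed
40 % identity to the reference set. Verdicts are monotone in identity. A
window with no callable ORFs is clean-with-note, not suspect.

## Phylogenetic matrix preparation (`phyloprep`)

The filter chain runs in the fixed order size → identity-cluster → align
→ trim → final length, because the order matters: a 112-aa domain fails
the initial > 115 aa filter but would pass the final ≥ 110 aa filter (the
test suite pins this asymmetry). Identity clustering is greedy
longest-first with identity defined as matches / global alignment length
— a documented, testable stand-in for tool-internal definitions used by
common redundancy reducers. Column trimming keeps columns whose non-gap
fraction is ≥ 0.4 (similarity-based trimming is disabled and raises if
requested). Export is relaxed PHYLIP or NEXUS, round-trip safe through
the module's reader; tree inference itself (Bayesian/ML) is out of scope.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (`numpy.random.default_rng`)
and the pipeline's report hash is reproducible bit-for-bit for a fixed
config. Tests and the acceptance script run on genomes of 12–70 kb with
2–21 planted copies and proteins of 120–600 aa; these sizes exercise
every code path (multi-family separation, frameshifts, remnants, segdups,
contaminant contigs) while keeping the full validation suite at around a
minute. The acceptance script reports medians over three replicate
genomes per scenario so that a single chance flank coincidence does not
dominate a reported value.

## Known limitations

* Boundary inference needs ≥ 2 copies; single-copy elements are reported
  with unresolved limits unless TIR+TSD evidence alone pins them.
* The block profile is synthetic; sensitivity to *real* divergent Merlin
  transposases depends on substituting a profile built from a curated
  alignment (supported via `BlockProfile.from_json`).
* The internal center-star aligner is adequate for within-family
  divergences (≤ ~25 %); for deep alignments users should import an
  externally produced aligned FASTA, which every consumer accepts.
* Copies whose terminal bases mutated away from `GG`/`CC` are classified
  as group members even when TSD evidence exists — the strict GG rule is
  faithful to how the superfamily is defined, but it is conservative for
  copies in the process of degeneration.
* The recency heuristic uses fixed thresholds and no molecular clock; it
  flags evidence patterns, not ages.
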