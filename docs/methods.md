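# Methods

This note documents the procedures implemented in `satdisperse`, the
parameters that matter, what the synthetic genomes do and do not emulate,
and the design choices made where more than one reasonable option existed.

## Homology scan (satscan)

The scanner is a megablast-style seed-and-extend search specialised to
short tandem queries.  Exact k-mers (default k = 11) shared between the
genome and any consensus variant (both subfamilies, both strands) are
clustered into candidate regions (seed spacing ≤ 150 bp, at least 2 seeds,
±400 bp margin).  Each region is locally aligned against every consensus
variant under the package-wide scoring scheme (match +1, mismatch −1, gap
open −2, extend −1); the best alignment is recorded as a hit and its
genomic footprint masked, and alignment repeats until the best score falls
below the floor (`x_drop`, default 20).  This mask-and-realign loop gives
every monomer copy of a tandem array its own hit, which is what makes
fractional copy numbers computable later.  Hit identity is matches over
all alignment columns, gaps included.  Hits below identity 0.5 are
discarded; overlapping opposite-strand hits at one locus keep the higher
score (tie → plus strand).

Local alignments over random flanks can drift past the true homology by
chaining chance match islands: such tails score marginally above zero.
Every accepted alignment is therefore reduced to its maximum-scoring
subsegment under a slightly harsher per-column rescoring (match +1,
mismatch −1.25, gap −2.25, break-even identity ≈ 0.56 instead of 0.50).
Genuine homology at the divergences handled here (identity ≥ 0.75) is
never touched by this trim; measured boundary jitter stays within a few
base pairs.

Merging joins same-chromosome hits whose genomic gap is at most 150 bp
(`max_gap`; the survey only says "short", so this is exposed as a flag and
never asserted in tests).  The aggregate identity of a merged candidate is
the length-weighted mean over members.  Filters follow the survey
literally: length ≥ 140 nt, identity strictly > 0.80.

## Element delineation

A transposon-like unit contains sequence the scanner cannot see: unique
TIR tails and an internal spacer.  After filtering, each candidate is
joined with nearby satellite hits (≤ 400 bp away, identity ≥ 0.75 and
score ≥ 40 so that chance hits cannot drag boundaries).  Only when the
joined locus contains satellite homology in *both* orientations — the
transposon hallmark — is a window (±300 bp) searched for a
reverse-complementary arm pair (minimum 50 columns at ≥ 0.70 identity,
best local alignment of the left half against the reverse complement of
the right half, trimmed as above).  A qualifying arm pair anchored on the
satellite span extends the element to the outer arm ends, recovering the
unique TIR portions the way a dot-plot inspection of the locus would.
Plain tandem arrays skip arm extension entirely: they have no TIR tails to
recover, and a chance inverted match in the flanks must not move their
boundaries.

The arm-identity floor used by the pipeline is 0.70 rather than the 0.80
default of `detect_tirs`: two TIR copies that each accumulated ~12.7 %
divergence from their ancestor (the level emulated for transposon-like
elements) retain only ~77 % mutual identity, so an 0.80 floor would reject
genuine full-length arms.  `detect_tirs` itself keeps the stricter default
for use as a standalone hallmark test.

## Dot-matrix segmentation and copy number

`dot_matrix` enumerates every window pair (i, j) whose subsequences differ
at no more than the mismatch limit, forward and against the reverse
complement — the classic dnadot parameters (9/0 standard, 11/1 relaxed).
Non-ACGT characters never match anything, including each other.

`segment_tandem` runs the element against both consensus monomers at the
relaxed parameters and chains matches along diagonals (diagonal tolerance
±10, gap along a diagonal ≤ 80 bp).  Chains shorter than 25 bp, with fewer
than 3 matches, or sparser than one match per 20 bp are discarded: genuine
monomer homology keeps at least ~0.2 matches/bp even at 12.7 % divergence
(window-match probability ≈ 0.26), while chance diagonal runs are far
sparser.  Overlap conflicts go to the denser chain.  Chain extents are
then stretched across small unmatched gaps (≤ 30 bp — the jitter left by
diverged windows at array junctions and element ends), subfamilies are
(re)assigned by global-alignment p-distance (global, not local: a local
alignment would let a chimeric subunit match only its easiest fragment),
and completeness is the covered fraction of the assigned monomer.  The
copy number is the sum of completeness values rounded half-up to one
decimal — composition-based counting, which is the only convention
consistent with fractional values like 0.6 for a 203 bp partial monomer
(203/362) alongside 2.8 for a 993 bp array.  If no chain covers ≥ 0.3 of
a monomer the element has no recognisable subunit structure and copy
number 0.0 is returned for the caller to judge.

## Classification, TIRs, TSD, flanks

An element is transposon-like iff satellite subunits of both orientations
flank a non-satellite internal spacer of ≥ 100 bp, **or** a TIR pair was
detected with an arm overlapping a satellite subunit; otherwise it is a
satellite-like array.  The two routes back each other up: at 12.7 %
divergence the ~121 bp inverted arm occasionally chains too short to pass
the 0.3-monomer subunit threshold, while the arm-pair alignment is robust,
and vice versa for elements that lost their TIR tails.

The `truncated` flag reports whether the element retains *intact* TIRs,
operationalised as an arm pair that extends ≥ 20 bp beyond the outermost
satellite subunits on both sides (intact TIRs include unique, non-satellite
tails; arm pairs made of satellite alone mean those tails were lost).

Target-site duplications are probed as the k bases (default 3) immediately
flanking the element, with the boundary pair shifted as a block by 0, ±1,
±2 (smallest shift first, negative before positive) because extension
boundaries are approximate.  A deliberate consequence of keeping the probe
this conservative: at the divergences emulated here, refined boundaries
carry ±1–4 bp of independent per-end jitter, so the planted "ACT" is
recovered for only a minority of full-length synthetic elements.  Widening
the probe is not statistically sound (each extra shift pair admits a 1/64
chance duplication), so TSD detection is exercised by constructed cases
with exact boundaries and is not part of the recovery scoring.

Flank AT content is the A+T fraction of the 100 bp on each side, truncated
at contig ends (None when no flanking base exists).

## Gene association

GFF3 gene models are parsed with gffutils; the representative transcript is
the mRNA with the largest summed exon length and "introns" are the gaps
between its consecutive exons.  An element entirely inside one intron is
"inside"; otherwise the nearest gene ending before the element and the
nearest gene starting after it become its 5′ and 3′ neighbours with
boundary-to-boundary distances.  Element sidedness is defined on the plus
strand of the chromosome; the neighbouring gene's own strand does not flip
it (the published table lists one 5′ and one 3′ gene per element
regardless of gene strands).  Elements overlapping an exon are flagged
`exonic_overlap`, warned about, and conservatively treated as inside —
the convention for a case that never occurs in the published data.

## Statistics

* **p-distance** — mismatched sites over columns where both sequences have
  a base (pairwise deletion).  With `alignment="global"` pairs are
  realigned first; with `alignment="precomputed"` the inputs are rows of
  an existing alignment.  Score-optimal realignment of diverged sequences
  occasionally swaps a few substitutions for gap pairs, deflating the
  estimate slightly — hence the precomputed mode, which the tests hold to
  exact agreement with direct site counts on generator-aligned sequences.
* **Chromosome distribution** — per chromosome, a two-tailed hypergeometric
  test (doubled smaller tail, capped at 1) of the observed element count
  against drawing all elements from a discretized pool (10⁶ units) split
  by background weights; Bonferroni across chromosomes at α = 0.025.  The
  background is an explicit input (assembly length share, element counts,
  or uniform) because the original survey never stated its background; its
  "no significant deviation" result is therefore not asserted anywhere.
* **Enrichment** — exact upper-tail hypergeometric P(X ≥ k) per category,
  Bonferroni by default, Benjamini–Hochberg available.  The survey's
  printed enrichment p for immunoglobulin-like genes (4.27 × 10⁻⁶) came
  from GeneCodis with unstated internal set sizes; the exact tail at the
  printed counts (9 of 101 against 134 of 14,869) is 3.1 × 10⁻⁷, which the
  acceptance script reports as computed and never matches to the printed
  value.

## Synthetic genomes

The generator's defaults are the study conditions: 2 chromosomes × 1 Mb of
AT-rich (66 %) background, 20 satellite-like insertions at 6 % divergence
with fractional copy numbers drawn from a table-like menu (0.6–4.0,
subfamilies optionally interspersed), and 20 transposon-like insertions at
12.7 % divergence built as `u + monomer + spacer + inverted 121 bp arm +
reverse-complemented u` (u = 148 bp and spacer = 306 bp of unique sequence
shared by all elements of a genome, giving 269 bp TIRs), half of them
truncated.  Full-length insertions are flanked by an "ACT" duplication.
Mutation is substitution-only by default (the emulated divergences are
p-distances); an indel-rate knob exists and defaults to 0.  Genes with
≥ 2 exons are placed so a configurable fraction of elements fall inside
introns, with a 200 bp buffer making flank distances unambiguous;
annotation tables plant an enrichment signal by boosting one category near
elements.

Two deliberate simplifications matter for interpreting green tests.
First, truncation always removes the unique TIR tails from both ends, so
every planted element terminates in either satellite sequence or a paired
arm; a one-sided unique tail with no surviving partner is undetectable by
homology to the monomer alone (the original survey recovered such
boundaries by comparing elements to each other, which is out of scope), so
recovery scores here do not speak to that case.  Second, the background is
i.i.d. random sequence: there are no other repeat families, assembly gaps
or sequencing artefacts, so the measured precision reflects only the
method's intrinsic false-call rate.  Copy-number scoring compares the
pipeline's one-decimal calls against the exact planted fraction, so a
one-step rounding disagreement (e.g. 2.1 vs 2.0) sits exactly on the
±0.1 bound and is accepted as within it.

The published consensus monomers are not printed anywhere, so
`make_consensus_pair` synthesizes a stand-in pair: subfamily a is 362 bp
of random sequence; subfamily b substitutes every position of the 100 bp
divergent region and 40 positions elsewhere and inserts 15 bp, reaching
377 bp.  Measured with the package's own global aligner under pairwise
deletion, the pair's identity lands near the documented 79 % (more raw
substitutions are planted than 21 % of the length because the realigner
recovers part of the randomized region).

## Problem sizes and runtime

The acceptance script uses five ~2 Mb genomes with 40 insertions each —
enough for recovery rates over 200 planted elements with replicate
variation — and completes in a few minutes on one CPU; the test suite runs
smaller single-genome configurations of the same generator.  Reported
per-subfamily divergence means use up to 28 recovered subunits per
subfamily, matching the scale of the original alignments.

## Known limitations

* No family-wide comparison between elements: truncated elements with a
  unique tail and no paired arm are delineated only to their satellite
  extent.
* TSD recovery degrades with boundary jitter (see above).
* The scanner assumes a monomer-scale query; queries much longer than the
  elements they detect would need different merge logic.
* Hairpin stability, ORF content and transposase homology are out of
  scope; TIR arm length/identity is the only mobility proxy.
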