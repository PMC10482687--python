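# Methods

This note records the models and procedures `scarscan` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates, break ends and junctions

All internal coordinates are 1-based inclusive; BEDPE I/O converts 0-based
half-open single-base intervals (break-end position = BEDPE start + 1).
A break end is an oriented breakpoint: `LEFT` means the sequence toward
lower coordinates is retained in the fusion, `RIGHT` the sequence toward
higher coordinates. Because SV callers encode strands differently, the
BEDPE strand→orientation mapping is a configurable dialect (default
'+' → LEFT, '−' → RIGHT). Junctions store break ends in canonical order
(lexicographic chromosome, then position, then orientation), which makes
ids, clustering and all downstream output deterministic. Simple classes
follow from orientations: intrachromosomal LEFT-at-low/RIGHT-at-high is
DEL-like, the converse DUP-like, equal orientations INV-like,
interchromosomal TRA. Junction span is |pos2 − pos1|, binned at
[1 Mbp, 10 Mbp) boundaries (half-open middle class).

## Gap segments and reciprocal pairs

A gap-segment candidate pairs two break ends that are (a) on one
chromosome with gap length hi − lo + 1 ≤ 1 Mbp, (b) from distinct
junctions, (c) oppositely oriented, and (d) reference-consecutive (no
third break end strictly between). Polarity is (+) iff the low break end
retains its right side — the junctions attach to the gap itself, and
copy-number mass balance predicts a gain over the gap; (−) gaps lose a
copy. Numerical choices:

- **Gap length** is hi − lo + 1 for both polarities. The thresholds act on
  orders of magnitude, so the one-base convention is immaterial; a single
  monotone definition keeps the caller simple.
- **Coincident break ends** (equal positions, opposite orientations) are
  ordered with the RIGHT-oriented end as the low end, giving a one-base
  (+) gap; this keeps the polarity map total and deterministic.
- **Per-break-end filter:** when a break end admits several candidates it
  keeps only its shortest gap (ties to the leftmost partner), and a
  candidate survives only if both its ends keep it. Without this a single
  junction can join more than two gaps through chains of nearby break
  ends, which would dissolve cyclic two-gap clusters into larger blobs.
  A consequence: an intrachromosomal pair whose two loci lie within 1 Mbp
  of each other can be suppressed by the (shorter) inter-locus segment;
  pairs with loci separated by more than the gap cap are unaffected.
- **Background model:** candidate lengths are fit with an exponential
  (MLE rate = 1/mean, minimum 10 candidates; with fewer, the model is
  skipped and the length cap alone governs). Left-tail p-values
  1 − exp(−rate·length) are BH-adjusted; the default pipeline uses the
  model as annotation/confirmation of the 1-Mbp cap rather than as a
  filter (a CLI flag enables filtering at a chosen FDR).

Clusters are connected components of the bipartite junction–gap graph. A
cluster is cyclic when every junction touches exactly two gaps; cyclic
two-junction/two-gap clusters are rPairs typed by gap polarities
(+/+ rDup, −/− rDel, +/− rDelDup). Copy-number consistency per gap
compares the gap's total CN against both flanks (gain for (+), loss for
(−); ties inconsistent; missing coverage unknown).

## Derivative walks and phasing

Reconstructions are expressed as walks — ordered, oriented reference
segments joined by junctions. For a junction, the retained flank of each
break end extends either to a window boundary (100 kbp for barcode
scoring, matching the molecule scale) or to the chromosome end (for
centromere typing). An rDup admits two cis options (the copy-paste can
run through either (+) gap, leaving that gap's own locus intact) plus one
trans set of two derivatives; an rDelDup one cis option (through the (+)
gap, with the (−) gap absent); an rDel only the trans set. Across any
returned walk set each (+) gap interval appears exactly twice, each (−)
gap zero times, and every other local base once — this conservation is
enforced by tests on full-length walks.

**Imputation.** cis iff the relevant log10 gap length is below 3.5 (rDup:
the smaller of the two; rDelDup: the (+) gap); rDel is always trans. The
rule is a deterministic step function; only crossing 10^3.5 flips the
call.

**Barcode phasing.** Molecule intervals are projected onto each candidate
walk's coordinates (a molecule piece maps to every occurrence of a
repeated segment), merged, and a junction at walk coordinate c counts as
spanned when a merged projection covers at least `min_side_overlap`
(default 1 kbp) on each side of c. A barcode supports a walk when it spans
all of the walk's junctions — both for a cis walk, one for each trans
derivative. The phase is the argmax over each individual cis walk's
support and the two trans walks' supports summed; ties (including zero
evidence) are ambiguous rather than defaulting to cis. The summed-trans
comparison is deliberately asymmetric: under a long-gap cis truth,
single-junction molecules accrue to the trans side, which is why imputable
cis events (short gaps) are the regime where barcode phasing is sharp.
The 1-kbp side overlap guards against molecules that end exactly at a
breakpoint; it must stay below the shortest gap plus window, which holds
for all defaults.

**Centromere typing.** The two hypothetical trans derivatives are built
from junction orientations only (phase is not an input, so cis loci are
typed too) with flanks extended to chromosome ends. A segment carries a
centromere copy when it covers the centromere midpoint; type I iff both
derivatives carry exactly one copy, else type II (acentric or dicentric
products). Midpoint coverage makes the count robust to break ends landing
inside a centromere interval. Missing centromere annotation yields NA.

## Homeology

Around each break end a 200-bp window is scanned; each of the 200
positions owns a complete centred 41-mer (the extracted sequence is
window + bin − 1 = 240 bases). Entry (i, j) of the similarity matrix is
1 − d/41 with d the Levenshtein distance between 41-mers (computed with
edlib; the search is capped just past the binarization cut, flooring
deeper mismatches at 1 − 10/41 without affecting any entry at or above
threshold). The second window is reverse-complemented when the two
break-end orientations imply opposite fusion strands (INV-like, and TRA
with equal orientations): annealing-competent sequences must be compared
in fusion orientation. The matrix is binarized at ≥ 0.8, components are
labelled with 8-connectivity (diagonal runs survive single-pixel jitter),
and each component's linearity is the Pearson r² of its pixel indices
(single pixels and axis-aligned lines score 0, as Pearson r is undefined
there and they cannot represent a diagonal run).

Two summary quantities are reported. `homeology_len` is the pixel count of
the largest component with r² ≥ 0.9, and drives the homeologous-junction
cut (> 10). Because shifted 41-mer pairs inside a high-identity tract also
clear the 0.8 cut (two indels re-align them), the winning component is a
band several pixels thick, so its pixel count exceeds the tract length —
roughly threefold for near-exact repeats. `homeology_span` is the same
component's extent along the first window in bases, i.e. the length of
the contiguous stretch of ≥ 80 %-similar sequence; it tracks the planted
tract length to within about one bin and is the right quantity to compare
against a physical repeat length. Homeologous deletions are DEL-like
junctions with span > 1 kbp and `homeology_len` > 10.

Note on thresholds: raising the similarity cut always shrinks the
binarized pixel set, but the reported length is not globally monotone in
the cut — lowering it can merge a clean diagonal into a blob that fails
the linearity filter. On diagonal-signal matrices (the operating regime)
the length is monotone, and the tests check exactly that.

## Scar features and classification

- Microhomology of a deletion with break ends p1 < p2: the largest
  k ≤ 25 with ref[p1..p1+k−1] = ref[p2..p2+k−1] (the deleted prefix versus
  the 3′ flank). The small-deletion denominator for the microhomology
  fraction is deletions with span ≤ 10 kbp.
- LOH: minor CN = 0 and major CN > 0; homozygous deletion: total CN = 0
  (not LOH); adjacent same-label segments merged. HRD-LOH index: LOH
  segments longer than 15 Mbp but shorter than their chromosome.
- Duplication size gate: 10–100 kbp by default, with a 1–100-kbp
  alternative selectable; both bounds inclusive.
- Signature exposures (SNV3, SNV8, RS3, RS5) are accepted as input columns
  and never computed — signature fitting is outside this package's scope.
  The classifier trains on whichever feature columns are present.
- Classifier: a 500-tree random forest (scikit-learn, fixed seed recorded
  with the model) over the three classes BRCA1d/BRCA2d/HRP; B1 and B2 are
  the tree-vote probabilities of the two deficient classes and a sample is
  positive when B1 + B2 > 0.5. Feature importance is permutation
  importance on a held-out set over 30 repeats.

## Synthetic data: what it emulates, and what it does not

The generator produces the exact object the analyses consume, with truth:

- **References** are i.i.d. bases at a chosen GC (default 0.41), with a
  centromere at each chromosome's midpoint. Real genomes have repeats,
  segmental duplications and mappability structure that i.i.d. sequence
  lacks; a zero false-call homeology null here therefore bounds only the
  algorithm's intrinsic false-positive rate, not its behaviour in
  repeat-rich regions.
- **Planted reciprocal pairs** are interchromosomal with both loci on
  q-arms; the direct junction pairing realises type I and the inverted
  pairing type II under centromere counting. Gap-length regimes follow the
  study conditions: cis events pair a long gap with a sub-threshold short
  gap ("long–short"), trans events use two long gaps ("long–long"), and
  rDels carry few-bp gaps like balanced translocations. Copy number is an
  integer purity-1 track (baseline 1+1, 2+1 over (+) gaps, 1+0 over (−)
  gaps); tumour purity, subclonality and noisy segmentation are not
  modelled. Background junctions are scattered with 2 Mbp of clearance
  from planted gaps and just over 1 Mbp from each other, so truth labels
  are unambiguous and no background gap candidates arise.
- **Linked reads** are molecules sampled uniformly along derivative walks,
  with exponential lengths scaled so the post-truncation (≥ 500 bp) median
  is 24.4 kbp — the generator matches the reported median molecule scale,
  since only a median is a stated condition and the length law itself is
  not. Each molecule carries a unique barcode and is split at walk
  junctions into reference intervals. Real linked-read libraries multiplex
  several molecules per barcode and have read-level gaps along molecules;
  neither affects the molecule-level support definition used here.
- **Homeology fixtures** write a random tract straddling one break end and
  a degenerate copy straddling the other. Substitutions are placed at a
  fixed period with a random phase rather than i.i.d.: at 85 % identity,
  i.i.d. draws leave ~1 in 6 tracts with a local window below the 80 %
  cut — honest non-detections that would make truth labels stochastic.
  Periodic placement makes realized identity a guaranteed local property,
  so the planted truth (detectable or not) is exact. Identities below 0.8
  are planted with truth marking expected non-detection.

Passing tests on these fixtures demonstrate the correctness of the
topology, phasing, typing, homeology and feature logic under controlled
conditions; they do not certify caller-noise robustness, purity/ploidy
handling, or repeat-context specificity on real genomes.

## Problem sizes and determinism

The test and acceptance workloads use scaled-down but structurally
faithful problems: 200 random junction sets of up to 20 junctions for
oracle equivalence, 50 planted events (plus 30 background junctions) on a
14-chromosome 40-Mbp-per-chromosome genome for recovery, 100 planted
rPairs at 80× physical coverage for barcode phasing, 1–1.5-Mbp references
with 500 random junctions for the homeology null, n = 5000 for background
calibration, and 60-per-class cohorts for the classifier. Every generator
and model fit takes an explicit seed, and all outputs are byte-stable
given one; the permuted-label null is reported as the mean held-out AUROC
over 20 refits because a single permutation's AUROC is dominated by how
its labels land on the few feature clusters.
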