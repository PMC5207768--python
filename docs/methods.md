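# Methods

This note documents the models and procedures implemented in `srnafrac`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Coordinates and read records

All intervals are 0-based half-open internally; GFF3's 1-based closed
convention is converted exactly at the I/O boundary. The biological 5′ end of
a minus-strand alignment is its rightmost aligned base. Libraries are
collapsed: each `AlignmentRecord` carries a `copies` multiplicity and every
counting operation sums copies, never records. One reported placement per
read is assumed (multi-mapper resolution is an upstream alignment concern).

## Preprocessing and the rRNA-fragment internal control

Adapter trimming truncates at the leftmost exact match of a 3′ adapter prefix
(defaults `TGGAATTCT`, `AGATCGGAA`; no mismatch tolerance — error-tolerant
trimming belongs upstream). Size selection keeps 18–42 nt inclusive. Reads
overlapping annotated rRNA/tRNA/snoRNA loci by ≥ 1 nt are removed; removed
reads of length 18–41 nt overlapping a 45S rRNA locus accumulate into the
library's rRNA-fragment count. The 45S precursor loci (containing 5.8S, 18S
and 25S) are the counting unit; 5S is excluded (it is not in the precursor).

Two normalizations are derived per library:

* `RPMR = raw / (rRNA fragment count / 1e6)` — internal control;
* `TPM  = raw / (kept genome-matched reads after structural filtering / 1e6)`.

Each library uses its own fragment count; no cross-library smoothing. The
premise is that ribosome (hence rRNA-fragment) content is comparatively
stable across fractions while small-RNA composition is not. Ratios of
normalized values are formed after adding a pseudocount of 0.5 to raw counts
(before dividing); this keeps ratios finite and symmetric and makes one stray
read in an empty feature worth at most log2(3) in log space.

## Window counting and DSR calling

The genome is tiled into consecutive, non-overlapping 100-bp windows (the
last window of a chromosome may be short). A read belongs to the single
window containing its strand-aware 5′ end and to its size class
(21/22/23/24 nt; other lengths are tallied separately and excluded from
testing). Windows with summed raw counts < 5 across all samples of a size
class are excluded (independent filtering; configurable).

Differential calling uses a moderated two-sample t-test on
`y = log2((raw + 0.5) / rpmr_divisor)`:

* per-window pooled variance over nA + nB − 2 df,
* shrunk toward the across-window mean variance within the size class with a
  prior weight of 4 pseudo-observations,
* t computed with nA + nB − 2 + 4 df,
* BH-FDR within each size class,
* hyper ⇔ FDR < 0.05 ∧ fold change > 2 ∧ B > A (fold change on pseudocounted
  RPMR means); hypo symmetric.

This is a deliberately self-contained replacement for a negative-binomial
GLM: it is exactly symmetric under condition swap, calibrated on NB null data
at the dispersions used here (null p < 0.05 fraction ≈ 0.03–0.04 at
dispersion 0.1, 3 vs 3), and powerful at 4-fold effects with ≥ 50 expected
counts (recall ≈ 0.98). No fidelity to DESeq2's estimates is claimed.
RPMR (not size factors) is the normalization inside the test because library
composition differs drastically between the compared fractions — that is the
point of the design.

## miRNA quantification and isomiR labels

Matching is coordinate-based against mature annotations: a read counts toward
a miRNA iff it lies on the same chromosome and strand and |d5| ≤ 1 and
|d3| ≤ 1, where d5/d3 are end offsets in RNA orientation (negative d5 =
5′ extension, positive d3 = 3′ extension). When the read carries a sequence
and a genome is supplied, the sequence must match the genome at the aligned
interval. The label is `m_{d5}_{d3}`; categories: (0,0) annotated, (−1,0)
5′ extension, (0,+1) 3′ extension, (+1,0) 5′ trim, (0,−1) 3′ trim, both ends
nonzero → shifted. The tolerance is per-end (so `m_-1_1`, a 2-nt net length
change, is admitted; `m_1_2` requires tolerance ≥ 2). A read within tolerance
of several overlapping annotations goes to the smallest |d5| + |d3|, ties to
the lexicographically first id (logged). `read_length = annotated_length −
d5 + d3` holds for every counted read by construction.

Enrichment ratios (M/T, MBP/TP) divide pseudocounted RPMR values computed
with each library's own factor.

## Phasing

Strand unification maps a plus-strand read to its 5′ position and a
minus-strand read with 5′ end x to `x − (cycle − overhang − 1)` (x − 18 for
21-nt cycles and 2-nt overhangs), chosen so the two strands of a perfect
Dicer duplex collapse onto one position. Only reads of length = cycle enter
by default (21-nt phasing; configurable).

For anchor a the window is `[a, a + cycle · window_cycles)` — downstream
only, matching trigger-cleavage-initiated phasing; the anchor slides by 1 nt
and only anchors whose full window fits in the region are scored. With P =
copies on the anchor's phase, U = copies off phase, n = occupied phase
positions:

`score = (n − 2) · ln(1 + 10 · P / (1 + U))`, defined only when n > 3.

The printed form of this formula is ambiguous about grouping; the adopted
parse multiplies the P/(1+U) ratio by 10. The alternative parse
`(n−2)·ln((1+10P)/(1+U))` is available behind the `alt_parse` flag.
Undefined scores are reported as absent (NaN), never zero, so thresholding
cannot call n ≤ 3 anchors.

**Calling threshold.** On register-free data the ratio `10P/(1+U)` converges
to 10/(cycle−1) ≈ 0.5, so the null score plateaus near `(n−2)·ln(1.5) ≈ 3.2`
with sampling noise reaching ~6 at realistic depth — the null level is nearly
depth-independent, so a fixed threshold is meaningful. The default threshold
of **10** sits between that plateau and the scores of genuinely phased loci
(≈ 30–40 at 80% phased reads). It is exposed in `PhasingParams` and recorded
in output headers.

Register distributions count unified 5′ ends by `(position − cleavage_site)
mod 21` along the direction of phasiRNA production; register 0 is the first
nucleotide of the 3′ cleavage fragment. The distribution is flagged
low-confidence when the prominent register's fraction is below 2/cycle,
i.e. indistinguishable from uniform.

TAS locus quantification counts reads whose aligned interval is contained in
the locus ("located within"; boundary-straddlers excluded), on either strand,
summed separately per size class (21/22/23/24 nt).

## Ribo-seq

Footprints are assigned to a feature when ≥ 80% of the read length (the
denominator is the read, not the feature) overlaps the category's intervals;
the comparison is ≥, exact at the boundary (17/21 qualifies, 16/21 does not).
UTR categories are tested before exon — a UTR label wins only when the read
clears the threshold within the UTR subinterval itself — then exon, then
intron; otherwise intergenic. Footprints are filtered to 25–35 nt by default
(the monosome gel cut), configurable.

The protected boundary is operationalized (the underlying observation is
visual): per-nucleotide transcript coverage is smoothed with a centered
moving average (default window 15 nt, `mode='nearest'` at the ends) and the
protected end is the largest coordinate with smoothed coverage ≥ 10% of the
smoothed maximum. On an ideal coverage step the recovered end is within half
the smoothing window of the step, for steps at least one window from the
transcript ends. Uniform coverage yields a protected end at the last
position — "no boundary". Parameters are recorded in every result.

## Synthetic data: what it emulates and what it does not

The generator plants, deterministically per seed, on two 200-kb chromosomes:
an 8-kb 45S rRNA locus plus tRNA/snoRNA loci, 30 MIR mature sites
(lognormal abundance weights; per-locus isoform category probabilities,
default 86% annotated / 10% 3′-extension / 1% each of the other routes),
6 TAS-like loci (600 bp, cleavage site 150 bp in, phased fraction 0.8 over
10 cycles — matching the 10-cycle scoring window and typical DCL
processivity — emitted as both strands of 2-nt-overhang duplexes), 200
P4siRNA windows of dispersed 24-nt reads, and 20 three-exon gene models with
UTRs.

A library draws a fixed read depth multinomially from absolute per-class
weights (T baseline: miRNA 0.25, tasiRNA 0.05, P4siRNA 0.45, rRNA fragments
0.20, background 0.05) scaled by a per-compartment enrichment map (defaults:
miRNA and tasiRNA ×3 in M/MBP/ER-IP, ×0.5 in FP; P4siRNA ×0.1 in M/MBP).
Fixed-depth sampling from shifted absolute abundances is exactly what makes
total-read normalization misleading while leaving miRNA:rRNA ratios intact —
the phenomenon RPMR exploits. P4siRNA per-window counts are
negative-binomially overdispersed (gamma-Poisson, dispersion 0.1); miRNA/TAS
locus counts and the rRNA-fragment count are multinomial shares, reflecting
the premise that ribosome content is stable. The count-level window generator
used for DSR calibration applies the same NB law directly.

Ribo-seq simulation places 25–35-nt footprints uniformly over gene CDS
intervals and over the short ORF ending at the cleavage site of TAS
transcripts, with a 2% leakage rate elsewhere in the transcript.

Not emulated: hairpin folding or any sequence realism (the genome is random),
RdRP/DCL biochemistry, alignment artifacts (multi-mappers, mismatches),
5′-nucleotide biases, and ligation biases. Passing tests therefore
demonstrate that the *computations* recover planted truth under the assumed
statistical structure — not that the biology of any real library satisfies
those assumptions.

## Problem sizes

Tests and the acceptance script run at desk scale chosen for tight recovery
bands at modest cost: library depth 1e5 for normalization/enrichment checks
(3 replicate pairs), 2,000 reads per locus for PHAS detection (20 phased +
200 null loci), 500 reads per locus for register recovery (100 + 100 trials),
2,500 null and 1,000 + 1,000 power windows for DSR calibration (3 vs 3
replicates), n = 10,000 for isoform-fraction and ribo-composition recovery,
and 100 boundary fixtures of 800 footprints each.

## Known limitations

* The moderated t-test is calibrated for the dispersion regime it is tested
  in; strongly heteroscedastic windows (dispersion varying by orders of
  magnitude within a size class) would erode the single-prior shrinkage.
* The phasing scan scores only anchors whose full 10-cycle window fits in the
  region, so the last `cycle·window_cycles − 1` positions of a region are
  unscored; anchors up to one window-span upstream of a phased run can be
  called because their window reaches it.
* The boundary detector assumes a single dominant protected segment;
  multi-ORF transcripts would need per-segment analysis.
* Window counting materializes the full tiling in memory — appropriate for
  the intended genome sizes (plant nuclear genomes at 100-bp resolution), not
  for e.g. 100-Mb windows at 1-bp resolution.
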