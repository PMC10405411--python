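# Methods

This note documents the generative models, statistical procedures,
parameter defaults and numerical choices behind `dicerscope`, and what
the validation on synthetic data does and does not establish.

## Coordinate conventions

All internal coordinates are 0-based, half-open. GFF3 is written and
read 1-based inclusive; the conversion happens only at file
boundaries. Alignment strand `-` means the read equals the reverse
complement of `reference[start:start+length]`; the 5′ end of a
placement is `start` on `+` and `start+length−1` on `−`.

## The Dicer duplex model

A Dicer product is a duplex of two equal-length strands, size
*k* ∈ {20, 21, 22} drawn from `size_weights` (default
{20: 0.1, 21: 0.6, 22: 0.3}, matching a 21-dominant, 22-second product
profile). A duplex cut at plus-strand position *c* occupies
[*c*, *c*+*k*) on the plus strand and [*c*−2, *c*+*k*−2) on the minus
strand; the 2-nt offset is the 3′ overhang on both ends and is fixed —
it is the chemical signature the analysis relies on. Cut positions are
uniform over the double-stranded region: no hotspot or sequence
preference is modelled, consistent with processing being observed
uniformly across hairpin stems. One strand of each duplex is
"sequenced", chosen with probability `strand_emission` (default 0.5).

On a hairpin the double-stranded region is the stem: the cut parameter
*c* ranges over [2, arm−*k*], which keeps both duplex strands inside
the arms. The arm-2 product of a hairpin duplex is itself a plus-sense
substring of the same transcript (the arms are exact reverse
complements), which has an important alignment consequence: every
stem-derived read maps twice, once per arm, on opposite strands with
weight ½ each. `loop_leak` is the probability that a draw treats
stem+loop as one double-stranded region (*c* ∈ [2, arm+loop−*k*]):
`loop_leak = 0` gives strict loop exclusion, `loop_leak = 1` gives
uniform processing across the boundary, and intermediate values
interpolate. A forced-overlap interpretation was rejected because it
would pile products onto the loop and make "loop processed like stem"
unattainable.

Background degradation reads (fraction `background_fraction`, lengths
uniform on 17–24 nt) are drawn from a transcript pool in proportion to
transcript length, on the transcript's own strand. When no pool is
supplied, an unrelated decoy transcript is synthesised, so background
never maps to the substrate under study — background represents
degradation of *other* cellular RNA, which is what makes the
stem-derived fraction of a `background_fraction = 0.3` library come
out at ≈ 0.7.

## The replicon model

The replicon is a 477-nt replicase-amplified RNA. Each molecule is
independently mutated at `per_site_mutation_rate = 0.03` per site (the
observed single-nucleotide variant frequency in replicon progeny,
interpreted as an independent per-site substitution probability), and
only an `accessibility = 0.01` fraction of molecules is exposed to
Dicer — the membrane-protection parameter. Each exposed molecule
yields one duplex read; mutation counts within each read are recorded
in provenance. A 21-nt read therefore carries at least one variant
with probability 1 − 0.97²¹ ≈ 0.473, which is why replicon reads are
aligned allowing one mismatch. Reads with ≥ 2 variants (≈ 12%) remain
unmapped, mirroring the analysis choice rather than defeating it. The
strand asymmetry of real replicon sRNA populations is not modelled;
both duplex strands are emitted with equal probability.

## The minigenome

Four chromosomes (6.0, 4.0, 4.6, 6.5 kb) carry eleven genes covering
every locus archetype: three plain genes; a sense/antisense pair
overlapping by 500 nt on opposite strands; a convergent pair separated
by a 150-nt gap; a gene with unannotated antisense transcription at
fraction 0.2 of sense; and a repeat element with three identical
400-nt copies at 5× baseline expression. Repeat copies share one
sequence, so their reads multi-map with weight ⅓.

Double-stranded RNA forms at: the annotated overlap of the antisense
pair; the intersection of the convergent pair's readthrough-extended
transcripts (extension 300 nt, crossing the gap and reaching 150 nt
into each gene); and the whole body of the hidden-antisense gene,
weighted by its antisense fraction. Genome-wide sRNA libraries
allocate Dicer reads across these regions in proportion to region
weight, with `background_fraction = 0.1` degradation reads from
expressed transcripts (expression × length weights). Plain genes and
repeats therefore receive only sense-strand degradation fragments —
repeats at elevated abundance.

RNA-seq reads (default 50 nt, stranded) are allocated per gene by a
multinomial with expression × length weights, positions uniform within
the transcript. Readthrough members extend 30% of their transcripts
past the 3′ end; hidden-antisense genes emit antisense-strand reads at
their configured fraction.

## Alignment

The aligner returns *all* placements at the minimal achievable
mismatch count (≤ 1), over both strands of every reference, each
weighted 1/(number of placements); if any perfect placement exists,
1-mismatch placements are suppressed (best-stratum semantics).
Implementation: exact substring hash indices per read length, with
one-substitution enumeration for the mismatch stratum — an exact
algorithm, verified placement-for-placement against a brute-force scan
of every offset and strand. Ordering is lexicographic (reference,
start, strand). Adapter trimming takes the leftmost exact match of
≥ 8 nt of the adapter prefix and then applies the [17, 24]-nt insert
window; no error-tolerant adapter matching is attempted because the
synthetic reads carry exact adapters.

ppm normalisation defaults to the total library size as denominator;
the mapped-weight denominator is reported alongside wherever the
distinction matters (the stem-derived fraction reports both).

## Loop-boundary detection

For a candidate boundary *b* and window *w* (default 20 nt ≈ one
product length), the strand-summed 5′-end counts in [*b*−*w*, *b*) and
[*b*, *b*+*w*) (rounded to integers) form one row of a 2×2 Fisher
exact table; the other row is the equal-occupancy reference (*w*, *w*).
This is a simple, exactly computable null with testable type-I error.
The scan evaluates every position within ±*w* of each annotated loop
edge, keeps the minimum-p position per edge, and Bonferroni-multiplies
by the number of scanned positions (ties broken toward the annotated
edge).

The strand-summed profile matters: because stem reads map to both
arms, minus-strand placements put 5′ ends within ~2 nt of the loop
edge, while plus-strand 5′ ends stop a product length short of it.
Summing strands makes the detected boundary land within ~2 nt of the
true edge; a plus-only profile would be offset by ~*k*. At 20,000 stem
reads the scan localises both edges of the default 275/79 hairpin to
within ±5 nt essentially always; under uniform processing
(`loop_leak = 1`) the Bonferroni-corrected scan stays below the 0.05
rejection level in far more than 90% of replicates (the residual
signal near an edge under the null is a ≤ 1.5× multi-mapping density
step, well inside the test's tolerance). Null calibration replicates
use 5,000-read libraries; power replicates use the stated 20,000.

## Antisense classification

Per locus, 21- and 22-nt sRNA placements are assigned by 5′-end
containment (avoiding double counting at overlapping loci), split into
sense/antisense relative to the annotated strand, and scaled to ppm.
Stranded RNA-seq coverage is averaged over the locus. The decision
cascade requires antisense sRNA ≥ `min_ppm` (default 5 ppm) for any
non-`none` call, then:

1. annotated opposite-strand overlap and symmetry
   2·min(s,a)/(s+a) ≥ `min_symmetry` (default 0.2) →
   `annotated_antisense_pair`;
2. a convergent neighbour within `max_gap` (default 300 nt) with
   antisense coverage over ≥ `min_intergenic_cover` (default 50%) of
   the intergenic gap → `readthrough_overlap`;
3. antisense RNA-seq coverage ≥ `min_antisense_rna` (default
   0.1 reads/nt) → `novel_antisense`;
4. otherwise `none`.

All four thresholds are explicit knobs, not reconstructions of
published cutoffs (none were stated for the original locus tables).
The cascade is monotone in `min_ppm` by construction: raising it can
only move calls toward `none`.

## Differential expression

Median-of-ratios size factors (geometric-mean pseudo-reference over
genes with nonzero counts in all samples), normalized baseMean, log2
fold change of condition means with a 0.5 pseudo-count, and a Wald
statistic using the NB variance μ + αμ² of each condition mean.

Dispersion is method-of-moments — pooled within-condition variance
versus the normalized mean — with two floors: a numerical floor of
1e-8, and the genome-wide *median* of the per-gene moment estimates.
The second floor is essential with few replicates: a 3v3 per-gene
moment estimate is so noisy that chance-underdispersed genes would
otherwise collapse to Poisson variance and produce arbitrarily extreme
z-scores on a pure null (observed down to p ≈ 1e-29; ~4% of null genes
flagged after BH). Flooring at the median restores calibration
(≈ 0% of 2,000 null NB genes flagged at padj < 0.05) while leaving
homogeneous small-dispersion data untouched — in the Poisson-limit
validation grid the median itself sits at the numerical floor, so the
grid is unaffected. No shrinkage toward a mean–dispersion trend,
Cook's distance filtering or independent filtering is applied.

In the small-dispersion limit, Wald p-values agree with the exact
two-sample Poisson test (conditional binomial on the totals,
p₀ = 1/2) to |Δp| ≤ 0.02 over a 50-gene grid with group totals of
1,500–2,200. The grid is ratio-symmetric (26 null genes plus 12
mirrored up/down pairs) so that the size factors are exactly 1 — the
regime in which that oracle is the matching null; at totals below
~200 the binomial's discreteness alone exceeds the bound, so the
agreement claim is about the moderate-count Poisson limit, not about
tiny counts.

Two properties of median-of-ratios normalisation are worth stating
explicitly because they bound what the test can promise. First,
rescaling one of *m* samples by λ shifts the geometric-mean
pseudo-reference by λ^(1/m); the common factor cancels exactly in fold
changes but leaks through the pseudo-count and the dispersion floor,
so single-sample-scaling invariance holds to ~1e-3 on log2FC (and
~1e-2 on p for overdispersed genes), not to machine precision.
Second, the normalisation absorbs fold changes shared by a large
fraction of genes: with 20% of genes at a common FC = 4 the recovered
log2FC is biased by about −0.06; the effect-size validation therefore
embeds its 100 FC = 4 genes (control mean 1000, dispersion 0.005 —
technical-replicate-grade variability, 3v3) among 900 stable genes,
recovering log2FC = 2 ± 0.2 for ≥ 95% of them.

Significance uses padj < 0.05 ∧ baseMean > 50 ∧ |log2FC| > 0.585
(fold change 1.5). ΔΔCt is
(Ct_target,treated − Ct_ref,treated) − (Ct_target,control −
Ct_ref,control), with relative expression 2^(−ΔΔCt).

## Pipeline defaults and problem sizes

One integer seed drives everything; per-stage generators are derived
deterministically from it, so identical config + seed give
byte-identical outputs. Default depths: 100,000 genome sRNA reads,
30,000 hairpin-library reads (30% background), 20,000 replicon
molecules at 1% accessibility, 200,000 RNA-seq reads for antisense
detection, and 3+3 replicates of 30,000 reads for differential
expression, where induction halves the repeat element's expression and
reduces the hidden-antisense gene to 0.35× (chosen so that the
compositional shift of the unchanged genes stays clearly below the
fold-change cutoff). A full default run takes well under a minute on
one CPU. The acceptance script uses 50 power replicates and 100 null
replicates for the boundary statistics; the test suite uses the full
100/200.

## What the synthetic validation shows — and does not

Passing tests establish that each stage implements its stated model
exactly (duplex geometry, aligner placements, Fisher tables, BH
step-up) and that the statistical procedures are calibrated and
powered *under the generator's assumptions*: uniform cut positions,
exact arm complementarity, mismatches only from replicon variation,
exact adapters, no ligation or sequencing-error bias, no positional
coverage bias in RNA-seq. Real libraries violate several of these —
sequence-biased Dicer cleavage, imperfect hairpin folding, RNA
structure effects on ligation, 3′ modifications — so the quantitative
guarantees (e.g., ±5 nt boundary localisation, diagonal class
recovery at the default depths) should be read as properties of the
method under clean conditions, not as performance claims on real data.
Dataset-scale headline numbers from deep sequenced libraries are out
of reach at these problem sizes by design.

## Known limitations

* Ungapped, ≤ 1-mismatch alignment only; no BAM emission; indices are
  rebuilt per run (fine at minigenome scale, not genome scale).
* The NB test has no dispersion shrinkage trend and no covariates.
* The boundary test's equal-occupancy reference row is a pragmatic
  null, not a likelihood-derived one; its conservatism grows with
  window counts.
* Multi-mapping is handled by uniform fractional weights; no
  rescue/EM reassignment.
* The replicon strand asymmetry seen in real data is not modelled.
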