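# Methods

## Coordinates and conventions

All intervals are 0-based, half-open (BED convention). The center of an
interval is `floor((start + end) / 2)`; resizing around the center is
left-biased on parity mismatches, so a resize-and-restore round trip moves
the center by at most 1 bp. Reads are reduced to their 5′-end positions
for all shifting and coverage operations; the MNase-style 3′-ward shift
moves plus-strand reads right and minus-strand reads left by the given
distance (55 bp by default, half a core nucleosome, centering dyad
signal). Oriented operations (flanks, meta-profiles, π profiles) flip
minus-strand regions so positive offsets always point downstream of
transcription; unstranded regions are rejected where orientation matters
and treated as plus where it does not (meta-profiles).

## Ubiquity calling

The input is an elements × biosamples matrix of DNase signal Z-scores.
A signal is *high* when Z > 1.64 — strictly, matching the one-sided 5%
standard-normal quantile — and an element is *ubiquitous* when it is high
in at least `min_samples` biosamples (inclusive). When `min_samples` is
not given it defaults to `ceil(0.95 · n_biosamples)`, which generalizes
the fixed compendium thresholds (500 of 517 human, 90 of 94 mouse
biosamples). cCRE classes follow the precedence PLS → pELS → dELS →
DNase-H3K4me3 → CTCF-only → DNase-only: PLS needs high H3K4me3 and a TSS
within 200 bp of the element center; pELS/dELS need high H3K27ac and
split at 2 kb TSS distance. The precedence for ambiguous flag
combinations is declared, not inferred from upstream registries.

## Promoter sequence features

Normalized CG content is the observed CG-dinucleotide fraction over its
independence expectation, `fCpG / [(fC + fG)/2]²`, with `fCpG` counted
over the L−1 overlapping dinucleotide windows. `N` positions are excluded
from the mononucleotide denominators and windows touching an `N` from
both the CG count and the window count, so numerator and denominator see
the same effective sequence. The ratio is defined as 0 when no C or G is
present (the numerator is then necessarily 0). Values ≥ 0.5 mark CpG-rich
promoters.

Motifs are position-weight matrices over A/C/G/T with a background model
(uniform by default, overridable with sequence-derived frequencies) and a
multiplicative pseudocount (`background × 0.01` added to every cell, then
renormalized) so matrices with zero counts score finitely. Match scores
are summed log₂ likelihood ratios (bits). Exact p-values are computed by
dynamic programming over the per-position score distribution under the
background:

- matrices up to 10 positions use the exact attainable partial-sum scores
  as the DP state space, so the survival function equals exhaustive
  enumeration bit-for-bit. A discretized DP (scores rounded to 1/1000
  bit) was tried first but cannot track enumeration to 10⁻⁶ wherever two
  sequences land within rounding distance of a threshold, which is common
  in the dense center of the score distribution;
- longer matrices use the 1/1000-bit convolution DP with the query
  threshold lowered by the worst-case accumulated rounding slack, so the
  reported p-value is conservative (never smaller than the exact one).
  At the operating thresholds (10⁻³–10⁻⁵) the slack shifts the effective
  threshold by ~2×10⁻³ bits, negligible against per-position score ranges
  of several bits.

General scans run both strands at p ≤ 10⁻⁴; minus-strand matches are
scored against the reverse-complement matrix and reported on forward
coordinates (under the default uniform background the score distribution
is strand-symmetric). TATA-box calling scans the forward strand only, in
transcription orientation, at p ≤ 10⁻³, and requires a site *starting*
25–35 bp (inclusive at both edges) upstream of the TSS. Cross-species
motif-shift analysis keeps only site pairs significant at p < 10⁻⁵ in
both genomes and reports |d_human − d_mouse| for the distance to the
nearest annotated TSS.

## Transcription

Expression is TPM, logged (natural base) after adding a 0.1 pseudocount.
Quantile normalization equalizes column distributions to the
across-column mean of sorted values; ties within a column receive the
mean of their reference slots, making the operation idempotent and
rank-preserving. The tissue-specificity index of a profile x over N
biosamples is `Σ(1 − xᵢ/max x)/(N − 1)`: 0 for constant profiles, 1 for
one-hot, undefined (NaN, with a warning) for all-zero profiles, and
invariant to positive rescaling.

A TSS peak is classified per biosample from its 5′-end read positions:
fewer than 10 reads → unclassified; if strictly less than half the reads
fall within ±2 nt (a 5-position window) of the summit (maximum-count
position, leftmost on ties) → dispersed; otherwise narrow when the peak
length is ≤ 9 nt and broad when longer. Peak length defaults to the fixed
rPeak interval width — rPeak boundaries are held constant across
biosamples, which makes the narrow/broad split biosample-independent — but
a "read-supported span" alternative (max − min read position + 1) is
available because both readings are plausible. The consensus shape across
biosamples is the modal classified shape, with ties broken
dispersed > broad > narrow; this is the conservative direction for the
dispersed-enrichment contrast and is configurable. Enrichment between
promoter groups is a two-sided Fisher exact test per biosample per shape
with Benjamini–Hochberg correction across all tests; a shape absent from
both groups has equal (zero) proportions and fold 1.

## Nucleotide diversity

Per-site diversity is π = 1 − Σ pᵢ² over the allele frequencies at that
position (maximal at 1 − 1/n for n equifrequent alleles). Regions average
π per position with invariant positions contributing 0. Variants come
from VCF records that pass all filters; indels are excluded; allele
frequencies are taken from the AF INFO field when present, else computed
from genotypes. Profiles average per-bp π in bins over ±2 kb windows,
transcription-oriented.

The group test bootstraps the Welch t-statistic: both groups are pooled,
two pseudo-groups of the original sizes are resampled with replacement
per replicate (10 000 by default), and the empirical p is the fraction of
replicate t values at or above the observed t (one-sided in the larger-t
direction; a two-sided |t| variant is available). This is the standard
null-resampling reading of a pooled bootstrap; resampling *within* groups
would estimate the sampling distribution of the difference rather than a
null, and is used only for the percentile 95% confidence intervals
reported with the group means. Zero exceedances are reported as
"< 1/n_boot".

## Enrichment statistics

Genes are modeled with one or more TSS positions; pseudogene and TEC
biotypes are dropped at load. A gene is assigned ubi-only / nonubi-only /
both / none by which promoter-class elements contain its TSSs — a
partition by construction. The permutation null for the "both" count
relabels a uniformly random subset of all TSSs (of the observed
ubiquitous-label size) per replicate, preserving each gene's TSS count,
and reports the null mean, SD, and a one-sided empirical p for the
observed count being low.

Fisher exact tests are two-sided by the minimum-likelihood rule (sum of
hypergeometric probabilities not exceeding the observed table's, with a
1 + 10⁻⁷ relative guard against floating-point ties); the odds ratio is
the sample estimate a·d/(b·c), infinite when b·c = 0 with a·d > 0.
"Center within 200 bp of a TSS" is inclusive at exactly 200. Loop-anchor
enrichment filters loops to ≥ 4 supporting reads, resizes both promoter
groups to 345 bp (the median promoter-element length, removing the length
difference between groups), and counts ≥ 1 bp overlap. ChIP-bound calls
require a peak overlapping the element by at least half of that peak's
own width *and* a motif site inside the element. Cofactor comparisons
report per-group medians and ubi/non-ubi median ratios (zero denominators
flagged as infinite) and cluster cofactors by average-linkage on
1 − Pearson r; linkage is configurable since nothing pins it down.
Synteny classes take the best-overlapping target element subject to a
half-overlap rule, with deterministic coordinate tie-breaking. Mendelian
gene filtering keeps genes with at least one phenotype string not
starting with "[" (non-diseases) or "{" (multifactorial susceptibilities).
Disease-specific 2×2 tables take explicit marginals, because more than
one construction is defensible.

## Synthetic data

The generators define the study conditions at desk scale on a single
synthetic chromosome with regularly spaced 300-bp elements (10 kb apart)
and one gene per element, the primary TSS at the element center. Defaults:
10 000 elements × 100 biosamples, 400 genes, 1% planted ubiquitous
fraction; high and low Z-scores Normal(5, 1) and Normal(0, 1), putting
> 3 SD between the high mode and the 1.64 cutoff, with planted elements
high in ≥ 95% of biosamples and the rest high in a geometric-tailed few
(the empirical bimodal ubiquity histogram); equal thirds of
narrow/broad/dispersed peak shapes at 50 reads per peak; variant density
0.05/bp inside elements vs 0.01/bp in flanks (the 5× center elevation)
with alternate-allele frequencies Beta(1, 9), a rare-variant-dominated
spectrum whose expected per-site π = 2(E[p] − E[p²]) ≈ 0.164 is available
in closed form for cross-checks; essential and Mendelian gene rates 0.285
and 0.146 (5312/18 633 and 2718/18 633 in the screens the study merged).
CpG-rich promoters are first-order Markov sequences with P(G | C) = 0.45
(normalized CG safely above 0.5); other promoters are AT-rich with
P(G | C) = 0 (complete CpG depletion, mirroring the empirical
zero-CpG tail) and half of them carry a TATAAAAG box planted 30 bp
upstream of the TSS. Housekeeping expression is near-constant
(Normal(100, 2), ~2% CV, so τ stays below 0.1 at ≥ 20 biosamples);
tissue-specific genes are one-hot. Loops anchor on 80% of planted
ubiquitous elements plus background loops, some below the 4-read filter.
The cofactor matrix has two blocks of three cofactors driven by
independent latent promoter activities.

Every generator draws from an independent stream derived from the global
seed and a fixed per-generator stream id, so outputs are byte-stable and
adding a generator cannot perturb the others.

What the generators do **not** emulate: genome-scale element counts,
sequence composition beyond first-order CpG structure, linkage
disequilibrium, chromatin-state correlations between assays, overlapping
genes, and multi-chromosome geometry. Passing round-trip tests therefore
demonstrates the correctness of the statistical machinery under the
planted model, not performance on real compendia.

## Numerical choices and degenerate inputs

Length-matched sampling bins lengths at 25 bp (elements span
150–350 bp, so ~8 bins resolve the distribution without starving any) and
realizes the largest histogram proportional to the reference that the
pool can supply — the scale is the minimum pool/reference ratio over
occupied reference bins. Reference bins the pool cannot serve at all are
dropped with a warning rather than zeroing the whole sample (the literal
"downscale proportionally" rule would return the empty set the moment one
bin is unservable). Candidates are canonically sorted before seeded
sampling so results do not depend on input order.

Profile bins store left-edge offsets covering exactly [−window, +window);
flanks and resizes crossing the chromosome origin are clipped at zero
with warnings; empty region lists, all-zero τ profiles, zero-total
contingency tables and empty read sets raise or warn as documented on
each function. Empirical p-values of zero are reported as "< 1/n" at the
replicate count used. Problem sizes in the analysis scripts and the
acceptance script (10 000 elements, 1000–2000 peaks, 200 variant-bearing
regions, 10 000 bootstrap/permutation replicates) were chosen so every
stage's planted signal is detected with wide margin while a full run
completes in seconds.

## Known limitations

Classification precedence for cCREs, the peak-length reading, the
consensus tie-break, the bootstrap resampling unit, and the STAP-seq
linkage are all declared choices where the underlying procedures are
ambiguous; each is configurable. The motif p-value for long matrices is
conservative rather than exact. Whole-genome background π must be
supplied as a region set rather than recomputed. The pipeline consumes
rPeaks, Z-scores and lifted coordinates as inputs; it does not call
peaks, compute Z-scores from alignments, or run liftover.
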