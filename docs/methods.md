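# Methods

## The measurement model

Each library member ("construct") is a fixed-length regulatory sequence
(default 165 nt) placed immediately upstream of a reporter ATG and
identified by a unique barcode inside the reporter coding region.
Coordinates are 1-based with the ATG "A" at +1 and no zero, so the last
regulatory base is −1 and every transcription start site (TSS) is a
negative integer.

A pooled reaction is sequenced twice: the input DNA pool, and cDNA from
reporter mRNA with a common adaptor (carrying two random ligation
bases) ligated at the cDNA 3′ end. Because the cDNA 3′ end is the mRNA
5′ end, the position where a trimmed RNA read begins inside the
regulatory sequence is a direct observation of one transcript's TSS.

Transcriptional activity of construct *i* in a sample is

    Tx_i = (RNA_i / Σ_j RNA_j) / (DNA_i / Σ_j DNA_j)

with replicate counts **summed before** the ratio. Constructs with
summed DNA < 15 reads are excluded as too noisy to normalize reliably;
`log10 Tx` over the remaining constructs is converted to Z-scores
(population SD, ddof = 0) per sample. The Z-transform makes profiles
comparable across samples whose absolute transcription rates differ,
and is scale-invariant: multiplying all RNA or all DNA counts of a
sample by a constant leaves `tx_z` unchanged. Constructs passing the
DNA filter with zero RNA are reported *inactive* (missing `tx_log10`)
rather than being assigned an arbitrary floor; an optional pseudocount
mode exists for modeling uses that need complete columns.

## Read processing

Pair merging is a simple overlap-consensus merge (unique best overlap
≥ `min_overlap`, mismatch fraction ≤ `max_mismatch_frac`, ambiguous
ties rejected; disagreements resolved by base quality). Adaptor
trimming removes the 3′ adaptor (Hamming scan, ≤ `max_mismatches`,
default 1) plus the adjacent random ligation bases, which are never
counted as transcript sequence. Demultiplexing is exact barcode
matching — conservative by design, since the barcodes are synthetic
and the simulator guarantees pairwise Hamming distance ≥ 3. An RNA
read's regulatory segment must match the assigned construct's
reg_seq suffix (≤ 1 mismatch); a non-matching segment keeps its
barcode assignment for abundance counting (`counts_from="barcode"`,
the default) but is excluded from TSS pileups. Every input read is
accounted for as assigned, unassigned, or rejected, and the tally
asserts that conservation.

## TSS calling

Per construct, QC-passing RNA 5′ positions form a weighted 1D pileup.
Clustering starts at k = min(16, #distinct positions) and decrements k
whenever two cluster representatives lie within 10 bp (inclusive) or
any cluster holds strictly less than 1% of reads; k = 1 always
terminates. The cluster representative is its modal position, ties
breaking to the most upstream — matching single-nucleotide initiation
biology. The primary TSS is the representative of the unique cluster
with read fraction > 0.70 **and** read count > 200 (both strict);
secondaries are other clusters with fraction > 0.10.

The per-k clustering step is solved **exactly** by dynamic programming
over the sorted positions (optimal 1D clusters are contiguous runs),
minimizing the count-weighted within-cluster sum of squares. An
iterated Lloyd-style k-means would serve the same role but is hostage
to initialization and local optima; the DP is deterministic,
initialization-free, and cheap at these sizes (≤ 165 distinct
positions, k ≤ 16). The test suite checks it against an independent
exhaustive partition-search oracle on fuzzed pileups.

## Promoter features

Eight features are extracted per construct with a primary TSS:

| feature | meaning | units / range |
|---|---|---|
| f1 | −35 element best match score | log2-odds bits |
| f2 | −10 element best match score | bits |
| f3 | interaction: product of standardized f1, f2 | — |
| f4 | spacer penalty −&#124;spacer − 17&#124; | {0, −1, −2} |
| f5 | spacer GC fraction | [0, 1] |
| f6 | TSS-region (8 bp downstream) match score | bits |
| f7 | 5′ mRNA folding pseudo-energy, first 50 nt | ≤ 0 |
| f8 | GC fraction of the whole regulatory sequence | [0, 1] |

The −35/−10 matrices (width 6) are discovered de novo by a
one-occurrence-per-sequence EM over the 45 bp upstream of the primary
TSSs of the top 10% most active promoters, deterministically seeded
from the most frequent hexamer. To keep the two elements from
collapsing onto one site, the −10 matrix is sought in the TSS-proximal
half of the window and the −35 matrix in the distal half. Element
placement is a joint scan over all (−35, −10) offset pairs with spacer
length in 17 ± 2 bp, maximizing combined score plus the spacer penalty
(−1 score unit per bp of deviation; the penalty scale is a package
choice, configurable). When no in-range geometry fits the available
window (e.g. a TSS too close to the sequence start), the annotation is
invalid and the construct drops out of the feature matrix.

The built-in folding backend is Nussinov maximum base pairing
(Watson–Crick + GU, hairpin loops ≥ 3 nt, −1 per pair): a
structure-propensity score, not a thermodynamic energy, chosen so the
package is self-contained and exactly testable against exhaustive
structure enumeration. A pluggable `external` backend delegates to
ViennaRNA's MFE when available; features from the two backends are
correlated but not interchangeable between fitted models.

## Activity models

Per species, `tx_z` is regressed on the eight features by OLS on
standardized columns (lstsq; rank-deficient designs fall back to a
λ = 1e-8 ridge with a warning). Model quality is summarized by repeated
random-subsampling cross-validation — default 10% train / 90% test,
10 repeats, seeded — and by the fraction of held-out predictions
within one log10 unit of the measurement (Z-scale predictions are
mapped back to logs via the training-set SD). Pearson r is identical on
the Z and log scales; the within-1-log metric is not, which is why the
inverse transform is explicit.

## Comparative analytics

Profiles are compared over "universally active" constructs — passing
the DNA filter with defined activity in *every* sample. Pairwise
Pearson matrices, PCA (samples as observations, SVD on column-centered
data, component signs fixed by the largest-magnitude loading), and
average-linkage hierarchical clustering on correlation distance
(1 − r, emitted as newick) operate on that matrix. A construct is
species-selective when its raw `Tx` exceeds every other sample's by
more than 10-fold (strict, linear scale). Depletion between an input
and output DNA pool is tested per construct with an exact binomial
test of the output count against the input fraction,
Benjamini–Hochberg corrected; "depleted" additionally requires an
output/input fraction ratio below 0.5. Motifs enriched among depleted
sequences are found by hypergeometric presence/absence tests over all
degenerate 5-mers with at most one N (2,304 patterns — enough to
express restriction sites like CCNGG), BH-corrected and ranked by
fold-enrichment with significance as tie-break (a motif present in
*all* depleted sequences ties on fold with its exact sub-patterns; the
broader, more significant pattern wins).

The choice of an exact binomial test and α = 0.05 is the package's
own; nothing in the statistic depends on it structurally and both are
configurable.

## The simulator, and what it does not emulate

`synthetic_data` generates: random fixed-GC sequences; a configurable
fraction with planted TTGACA/TATAAT pairs (per-construct consensus
degradation with fidelity drawn from U(0.6, 1), spacer from 15–19 bp,
true TSS 7 bp downstream of the −10 start, geometry always leaving a
full 45-bp upstream window); barcodes with pairwise Hamming ≥ 3; true
log10 activities `β·f + N(0, σ)` over standardized truth features with
defaults β = (0.5, 0.6, 0.1, 0.2, −0.1, 0.2, 0.2, −0.4), σ = 0.8 —
−10/−35 strength dominating positively and GC% the strongest negative
weight, with roughly half the activity variance attributable to the
features, and per-species β supported for cross-species runs. Reads:
DNA counts multinomial over a Dirichlet(α = 20)-perturbed pool
(optionally motif-depleted by a factor, or log-normal fitness-skewed);
RNA weights ∝ pool × 10^activity; per-read 5′ ends jittered by a
rounded N(0, 0.5 bp) clipped to the sequence; per-replicate
independent draws; error-free bases by default (an optional
substitution rate exists). All randomness flows from one seed and
FASTQ output is byte-stable.

Passing tests on this generator demonstrate correctness of the
*computations* — counting, normalization, clustering, scanning,
regression — under a generative model that matches the pipeline's
assumptions. They do not demonstrate robustness to real-data phenomena
the generator omits: sequencing and RT errors, PCR duplicates and
amplification bias, cross-hybridizing barcodes, RNA degradation
gradients along the 5′ UTR, template switching, or promoters whose
activity is not a linear function of these eight features.

## Numerical and design choices

* DP cost ties during clustering keep the earliest split; the
  representative tie-break (most upstream modal position) is asserted
  by tests.
* "Within 10 bp" merges inclusively (distance ≤ 10 decrements k), so
  final representatives are > 10 bp apart; the 1% prune and the
  70%/200/10% designation thresholds are strict inequalities.
* Z-scores use population SD for determinism; a sample whose passing
  constructs have zero activity variance is an error, not a silent
  NaN.
* EM motif discovery is deterministic (frequency-seeded); PWM scan
  ties take the smallest offset.
* PCA signs are fixed by forcing each component's largest-magnitude
  loading positive, making scores reproducible across runs.
* `scripts/acceptance.py` measures the pipeline on a 4,000-construct /
  4 × 10⁶-reads-per-kind simulation — sized so that the 10% training
  split of the ~800 promoters with primary TSSs is large enough for
  the cross-validated variance-explained and within-1-log metrics to
  be meaningful — plus smaller targeted simulations for the oracle,
  depletion, and motif-recovery checks.

## Known limitations

* Exact-match demultiplexing discards reads with barcode errors rather
  than rescuing them; the optional Hamming-1 rescue requires pairwise
  barcode distance ≥ 3.
* The spacer penalty scale (−1 bit-equivalent per bp) and the
  half-window separation heuristic for −35/−10 discovery are
  pragmatic defaults, not fitted quantities.
* The Nussinov pseudo-energy ignores stacking, loop entropies and
  dangling ends; use the external backend when thermodynamic energies
  matter.
* Activity models are deliberately linear; systematic curvature in
  feature–activity relationships will show up as unexplained variance,
  not as a warning.
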