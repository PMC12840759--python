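# Methods

## Overlap model

A knockdown table lists cassette-exon events with their inclusion-level
change (delta PSI = PSI_knockdown − PSI_control, fractions in [−1, 1]).
After deduplication by exon identity — (chrom, strand, exon_start,
exon_end), deliberately excluding flanking-exon coordinates so one cassette
exon reported with different flanking pairs counts once — a filter policy
yields the RBP's regulon:

- `hela` policy: |dPSI| > 0.15 (strict), no event-level statistics needed;
- `encode` policy: |dPSI| > 0.10 (strict) and FDR <= 0.05 (inclusive).

The delta-PSI inequality is strict ("greater than"), the FDR bound
inclusive. Rows with missing delta PSI join neither the regulon nor the
universe. Duplicate exons are resolved toward the largest |dPSI| (tie:
smallest FDR, then first occurrence), keeping the strongest evidence that
the exon responds.

For a pair of regulons the overlap m is referred to the hypergeometric
distribution over N, the size of the **union** of the two deduplicated
unfiltered universes. A "combined" universe could also be read as the sum
of the two sizes; the union is the only reading compatible with drawing
two subsets from one finite set, so it is the default and the sum variant
is available via `universe_mode="sum"` for sensitivity analysis. The
survival function P(X >= m) is computed in log space (gammaln terms summed
with logsumexp) and clamped to [0, 1]; m = 0 gives exactly 1 and
m > min(M, n) exactly 0. Pairs with m = 0 carry status `no_overlap`,
distinguished from tested-but-insignificant, reproducing the three-state
matrix colouring. No multiple-testing correction is applied by default
(the analysis uses raw p <= 0.05 over all pairs); a Benjamini–Hochberg
mode exists behind `correction="bh"`.

The interdependence matrix reports, per row RBP r: row_total(r) = number
of r's affected exons shared with at least one other RBP, cell (r, c) =
100·|affected(r) ∩ affected(c)| / row_total(r), and the per-RBP
interdependent fraction 100·row_total(r)/|affected(r)|. Cells are kept at
full precision; `rounded()` gives the integer display form. Clustering of
the matrix uses Euclidean distance with complete linkage
(scipy.cluster.hierarchy); rows enter in lexicographic RBP order, which
fixes tie-breaking, and the undefined diagonal is treated as 0.

## Direction and multiplicity

A knockdown that decreases inclusion marks the RBP as a wildtype enhancer
of that exon; an increase marks a silencer. Direction is taken per RBP
from the table that defines its regulon, so a shared exon may legitimately
count "increase" for one RBP and "decrease" for another. Each RBP is
summarised over three populations: all affected exons, the independent
population (exons of pooled multiplicity 1) and the interdependent
population (multiplicity >= 2). Zero delta PSI cannot pass a strict
positive threshold, so no tie category exists.

Pooling all regulons of one cell line gives each exon its multiplicity
(number of affecting RBPs) and sign multiset. An exon is `increase_only` /
`decrease_only` when all its responses agree, `both` otherwise;
multiplicity-1 exons are never `both`. Wildtype PSI disagreements between
source tables for one exon (different control batches) are resolved by the
mean — wildtype inclusion is a property of the cell line and residual
differences are noise.

The wildtype-inclusion contrast uses 40 histogram bins on [0, 1] and an
"intermediate inclusion" window fixed at PSI in [0.35, 0.65] (the window
is a config knob; intermediate means "around one-half included").

## Feature trends

Exon features (exon length, flanking intron lengths, MaxEnt-style 5'/3'
splice-site scores in bits, PhyloP conservation) are consumed as a
precomputed per-exon table; the package never computes them from sequence.
Exons are binned by multiplicity, empty bins dropped, and the **bin mean**
of each feature regressed on the bin's multiplicity by ordinary least
squares, unweighted by default with a bin-size-weighted variant behind a
flag. Genome-wide reference values (e.g. a median 5'ss score) are accepted
as config input and echoed into the output, never computed.

Calibration caveat: with per-exon noise, bin means are heteroscedastic —
the multiplicity-1 bin holds orders of magnitude more exons than bin 9 —
and the unweighted fit's t-based p-values are then only approximate (the
package's own calibration experiment shows they are non-uniform under a
strongly skewed bin-size profile). The null-calibration experiment in
`validation.null_slope_ks_pvalue` therefore runs on balanced bins, where
the fit's sampling assumptions hold and the p-values are uniform; under
skewed bins the slope estimate remains unbiased and its 95% CI still
covers a planted slope in >= 90% of replicates (measured 94/100 at design
time), but p-values near the threshold deserve caution, or the weighted
variant.

## Synthetic data generator

The generator emulates a 30-knockdown compendium so that every pipeline
stage can be tested against planted truth. Defaults (one choice each,
fixed):

- 30 RBPs, families assigned round-robin (SR / hnRNP); regulon sizes
  log-uniform over [3, 300] exons — the observed span from broad to
  near-silent regulators;
- universe of 20 000 candidate cassette exons, the order of magnitude of a
  skipped-exon rMATS output, on synthetic chromosomes with non-overlapping
  coordinates consistent with the feature table's exon/intron lengths;
- overlap structure: each affected exon is assigned to k RBPs
  (capacity-weighted, sampled without replacement), with P(k=1) = 0.75 and
  the remainder decaying geometrically (factor 0.55) up to k = 9, plus a
  small explicit ladder of high-multiplicity exons (20×3 … 1×9) so the
  deepest bins are always populated. Disjoint pairwise blocks — available
  via `planted_pairs` for exact-recovery experiments — cannot by
  themselves make most pairs overlap while keeping >70% of exons
  single-RBP, because each planted shared exon consumes capacity from
  exactly two regulons; the multiplicity-tail model spreads shared exons
  across many pairs at once, reproducing both marginals;
- response directions: per (exon, RBP) Bernoulli draws with
  P(decrease) = 0.75 for SR-family and 0.35 for hnRNP-family regulators
  (SR knockdowns preferentially lose inclusion, hnRNPs gain);
- effect sizes: |dPSI| = 0.15 + (headroom − 0.15) · Beta(2, 5), a
  right-skewed distribution of knockdown effects, always strictly above
  the 0.15 filter; background rows draw |dPSI| < 0.1495. FDR is emitted
  for every row (affected <= 0.05, background > 0.05) so the `encode`
  policy is exercised on the same tables;
- wildtype PSI: mixture 0.5·Beta(1,9) + 0.5·Beta(9,1) (bimodal, exons
  mostly near 0 or 1) with an intermediate Beta(5,5) component whose
  weight rises linearly from 0 at multiplicity 1 to 0.4 at multiplicity
  >= 4. The direction is drawn first and the PSI mixture truncated to the
  feasible window (a 0.15 decrease needs PSI > 0.16, an increase
  PSI < 0.84): this keeps the planted direction bias exactly recoverable,
  at the cost that the wildtype-PSI marginal is mildly reshaped near its
  extremes; mixed-direction multi-RBP exons are thereby confined to
  intermediate inclusion, which is also the planted Fig-style contrast;
- exon features: linear models intercept + slope·multiplicity + Gaussian
  noise, with defaults ss5 8.5 − 0.4·k (sd 1.0), PhyloP 2.0 − 0.08·k
  (sd 0.5), ss3 flat, exon length 130 + 4·k nt (sd 40), upstream intron
  3000 − 120·k nt (sd 1200), downstream intron flat;
- extra cell lines: each base-line regulon is resampled with a keep
  probability (`resample_fraction`) and rescaled (`size_scale`), then
  refilled with line-specific exons; directions and PSI are redrawn per
  line. The analysis drivers use HeLa (1.0/1.0) plus two ENCODE-like lines
  (0.2/0.5), emulating stringently batch-corrected compendia that detect
  fewer, largely different events.

All randomness flows through one PCG64 generator seeded from the config,
so outputs are byte-identical across runs and platforms. `null_resample`
draws regulons of fixed sizes independently from the universe — overlap
then arises only by chance — to calibrate the pair test's false-positive
rate.

What the generator does **not** emulate: real genomic sequence and true
MaxEnt/PhyloP scoring, correlated effect sizes between co-regulating
factors, read-level noise or rMATS's inference, expression-level indirect
effects, and liftover issues between genome builds. Passing tests
demonstrate that the pipeline recovers structure of this planted kind;
they do not certify discovery performance on real compendia.

## Problem sizes and numerical choices

The validation experiments use: null calibration — 5 replicates × 435
pairs (2175 null pairs, 30 regulons of log-uniform size in a 5000-exon
universe); planted-pair power — 200 replicates at the minimum interesting
condition (sizes 30/30, 10 shared exons, Jaccard 0.2, universe 5000);
slope recovery — 100 replicates of a 14-RBP compendium (200 exons per
regulon, 4000-exon universe) with 25 exons planted in every multiplicity
bin from 2 to 9, so each bin mean rests on a reasonable sample — with the
default ladder's near-empty top bins the unweighted CI covers only ~88%
(measured at design time), another face of the heteroscedasticity caveat
above; null
p-value calibration — 200 replicates on 9 balanced bins of 40 exons. The
survival function is verified against exact integer enumeration for every
(m, N, M, n) with N <= 25 to 1e-12. Degenerate inputs: empty regulons test
as m = 0, p = 1; all-shared regulons give p = 1 (an overlap that certain
can never be evidence); clustering requires at least two rows and treats a
single-column matrix as unclusterable on the column axis.

## Known limitations

- The hypergeometric model conditions on regulon sizes and assumes
  exchangeable exons; compositional structure in real universes (gene
  expression filters, detectability) can inflate overlap beyond chance for
  reasons other than co-regulation.
- With raw p <= 0.05 over 435 pairs, ~22 false positives are expected
  under the global null; the BH mode exists but changes the analysis.
- Cross-line exon comparisons require one genome build; no liftover is
  attempted.
- The indirect-effect scan flags knockdowns that alter another factor's
  splicing; it cannot attribute any specific shared exon to an indirect
  path.
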