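# spliceinterdep

Interdependent regulation of cassette-exon splicing by SR and hnRNP
splicing factors, quantified from RNA-binding-protein (RBP) knockdown
differential-splicing tables.

## The problem

Knocking down a splicing factor changes the inclusion level (PSI, percent
spliced in) of a set of cassette exons — that factor's *regulon*. When the
regulons of two factors share more exons than chance allows, the pair
*interdependently regulates* splicing. For RBPs A and B with filtered
regulon sizes M and n over a combined unfiltered universe of N exons, the
package tests the observed overlap m with the hypergeometric survival
function

    P(X >= m) = 1 - sum_{i=0}^{m-1} C(M, i) C(N - M, n - i) / C(N, n)

declaring a pair significant at p <= 0.05. Around this statistic the
package provides the full analysis a knockdown compendium supports:

- reading/writing rMATS-style skipped-exon tables (dialect-aware: percent
  vs fraction PSI, delta-PSI sign conventions, replicate lists),
  deduplication by exon identity (chrom, strand, start, end);
- regulon filtering (|dPSI| > 0.15, or |dPSI| > 0.10 with FDR <= 0.05 for
  datasets with event-level statistics);
- all-pairs overlap testing, the row-normalised interdependence matrix and
  its Euclidean/complete-linkage clustering;
- enhancer/silencer direction summaries per RBP over total, independent
  (multiplicity 1) and interdependent (multiplicity >= 2) exon populations;
- regulator multiplicity per exon, direction-consistency by multiplicity,
  wildtype-PSI distributions of independent vs interdependent exons, and
  linear trends of exon features (MaxEnt-style splice-site scores, PhyloP
  conservation, exon/intron lengths) against multiplicity;
- cross-cell-line comparisons (relative importance, shared significant
  pairs, regulon Jaccard) and cross-regulation scans (knockdowns that
  change another splicing factor's exons);
- a synthetic-data generator with planted ground truth (regulon sizes,
  pair overlaps, direction biases, bimodal wildtype PSI, feature trends)
  that makes every stage testable without downloads.

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
30-RBP compendium (HeLa-like base line plus two ENCODE-like lines) and
write their tables under `results/`:

```sh
cd analysis
python 01_simulate_knockdowns.py
python 03_pair_interdependence.py
python 05_multiplicity_features.py
```

prints (seed 2026):

```
229/435 pairs significant at p <= 0.05 (53%); 173 pairs share no exon
most interdependent regulator: SRSF14 (86% of its exons shared); least: hnRNPX04 (29%)
75% of affected exons respond to a single RBP; up to 9 RBPs act on one exon
intermediate wildtype inclusion (PSI 0.35-0.65): 4.5% of independent vs 39.5% of interdependent exons
ss5_score: slope -0.407 per added RBP (95% CI -0.494..-0.321, p=1.1e-05)
```

Reading: 30 regulators give 435 unordered pairs, of which 229 overlap more
than the hypergeometric null allows; most exons answer to a single
regulator, but a tail of exons is shared by up to nine; interdependently
regulated exons sit at intermediate wildtype inclusion far more often than
independently regulated ones; and the 5' splice-site score declines by
about 0.4 bits per additional regulator — all structure the generator
planted and the pipeline recovers.

The same stages are scriptable (`splice-interdep simulate|filter|pairs|
matrix|direction|multiplicity|features|context|run`) or callable from
Python:

```python
import spliceinterdep as si

ds = si.generate(si.SyntheticConfig(seed=1))
regs = [si.apply_filter(si.deduplicate(t), si.HELA_POLICY)
        for t in ds.tables["HeLa"].values()]
results = si.all_pairs(regs, alpha=0.05)
```

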