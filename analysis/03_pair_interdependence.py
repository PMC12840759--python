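#!/usr/bin/env python
"""Hypergeometric co-regulation test for all RBP pairs; build the matrix.

For every unordered pair the overlap of filtered regulons is tested
against the hypergeometric expectation over the combined unfiltered
universe.  Writes pair_results.tsv, interdependence_matrix.tsv and the
complete-linkage row/column order, and reports the share of significant
pairs.
"""

import json

from common import results_dir, study_regulons
from spliceinterdep.interdependence import (
    all_pairs,
    build_matrix,
    cluster_matrix,
    pairs_frame,
)


def main() -> None:
    regs = study_regulons("HeLa")
    results = all_pairs(regs, alpha=0.05)
    out = results_dir()
    pairs_frame(results).to_csv(out / "pair_results.tsv", sep="\t", index=False,
                                float_format="%.6g")

    matrix = build_matrix(regs, results)
    matrix.cells.to_csv(out / "interdependence_matrix.tsv", sep="\t",
                        float_format="%.6g")
    clust = cluster_matrix(matrix)
    (out / "cluster_order.json").write_text(
        json.dumps({"rows": clust.row_order, "columns": clust.col_order}, indent=2)
    )

    n_sig = sum(r.significant for r in results)
    n_gray = sum(r.status == "no_overlap" for r in results)
    print(f"{n_sig}/{len(results)} pairs significant at p <= 0.05 "
          f"({100 * n_sig / len(results):.0f}%); {n_gray} pairs share no exon")
    frac = matrix.per_rbp_interdependent_fraction
    hi = max(frac, key=frac.get)
    lo = min(frac, key=frac.get)
    print(f"most interdependent regulator: {hi} ({frac[hi]:.0f}% of its exons shared); "
          f"least: {lo} ({frac[lo]:.0f}%)")
    print(f"tables -> {out / 'pair_results.tsv'}, {out / 'interdependence_matrix.tsv'}")


if __name__ == "__main__":
    main()
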