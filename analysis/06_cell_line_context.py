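#!/usr/bin/env python
"""Cross-cell-line comparison and indirect-effect (cross-regulation) scan.

Compares relative RBP importance between the HeLa-like and ENCODE-like
lines, intersects the significant pairs across lines, measures per-RBP
regulon overlap (Jaccard) between lines, and scans each knockdown table
for splicing changes in other splicing factors' genes.
"""

import pandas as pd

from common import LINE_POLICIES, results_dir, study_dataset, study_regulons
from spliceinterdep.context import (
    cross_line_exon_overlap,
    detect_cross_regulation,
    relative_importance,
    shared_significant_pairs,
)
from spliceinterdep.interdependence import all_pairs
from spliceinterdep.io import deduplicate


def main() -> None:
    ds = study_dataset()
    out = results_dir()

    counts = pd.DataFrame(
        [
            {"rbp_name": r.rbp_name, "cell_line": line, "n_affected": r.n_affected}
            for line in LINE_POLICIES
            for r in study_regulons(line)
        ]
    )
    imp = relative_importance(counts)
    imp.to_csv(out / "relative_importance.tsv", sep="\t", index=False, float_format="%.6g")
    tops = imp.loc[imp.groupby("cell_line")["relative_importance"].idxmax()]
    print("most influential RBP per line:",
          ", ".join(f"{r.cell_line}: {r.rbp_name}" for r in tops.itertuples()))

    results_by_line = {line: all_pairs(study_regulons(line)) for line in LINE_POLICIES}
    shared = shared_significant_pairs(results_by_line)
    for line, frac in shared.per_line_significant_fraction.items():
        print(f"{line}: {100 * frac:.0f}% of pairs significant")
    print(f"{len(shared.shared)} pairs significant in all three lines")

    regs_by_line = {
        line: {r.rbp_name: r for r in study_regulons(line)} for line in LINE_POLICIES
    }
    overlap = cross_line_exon_overlap(regs_by_line)
    overlap.to_csv(out / "cross_line_overlap.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"median cross-line regulon Jaccard: {overlap.jaccard.median():.3f} "
          "(exon selection is largely line-specific)")

    gene_map = {r: list(g) for r, g in ds.truth.rbp_gene_map.items()}
    tables = [deduplicate(t) for t in ds.tables["HeLa"].values()]
    cross, auto = detect_cross_regulation(tables, gene_map)
    rows = [
        {"knocked_down_rbp": h.knocked_down_rbp, "responding_rbp": h.responding_rbp,
         "n_responding_exons": h.n_responding_exons,
         "max_abs_delta_psi": h.max_abs_delta_psi, "autoregulation": is_auto}
        for hits, is_auto in ((cross, False), (auto, True)) for h in hits
    ]
    pd.DataFrame(rows).to_csv(out / "cross_regulation.tsv", sep="\t", index=False,
                              float_format="%.6g")
    print(f"{len(cross)} cross-regulation hits (knockdown changes another "
          f"splicing factor's exons), {len(auto)} candidate autoregulation events")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
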