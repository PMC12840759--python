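#!/usr/bin/env python
"""Enhancer/silencer tendencies per RBP over total vs independent exons.

A knockdown-induced inclusion loss marks the RBP as a wildtype enhancer of
that exon, a gain as a silencer.  Writes results/direction_summary.tsv and
contrasts the SR and hnRNP family tendencies across populations.
"""

from common import results_dir, study_dataset, study_regulons
from spliceinterdep.direction import direction_table
from spliceinterdep.multiplicity import build_multiplicity


def main() -> None:
    regs = study_regulons("HeLa")
    profile = build_multiplicity(regs)
    table = direction_table(regs, profile)
    out = results_dir() / "direction_summary.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.6g")

    fams = study_dataset().truth.families
    table["family"] = table["rbp_name"].map(fams)
    for fam in ("SR", "hnRNP"):
        for pop in ("total", "independent"):
            sub = table[(table.family == fam) & (table.population == pop)]
            sub = sub[sub.n_exons > 0]
            mean_dec = (sub.pct_decrease * sub.n_exons).sum() / sub.n_exons.sum()
            print(f"{fam:5s} {pop:12s}: {mean_dec:.0f}% of exons lose inclusion "
                  f"on knockdown (enhancer-like)")
    print(f"direction table -> {out}")


if __name__ == "__main__":
    main()
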