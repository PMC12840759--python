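#!/usr/bin/env python
"""Multiplicity bins, direction consistency, PSI distributions, feature trends.

Pools all HeLa regulons, counts how many RBPs affect each exon, and
characterises the bins: consistency of the response direction, wildtype
inclusion of independent vs interdependent exons, and linear trends of
splice-site strength / conservation / lengths against multiplicity.
"""

import json

from common import results_dir, study_dataset, study_regulons
from spliceinterdep.multiplicity import (
    build_multiplicity,
    direction_consistency,
    feature_trend,
    inclusion_distributions,
)


def main() -> None:
    ds = study_dataset()
    regs = study_regulons("HeLa")
    profile = build_multiplicity(regs)
    out = results_dir()

    counts = profile.counts_table()
    counts.to_csv(out / "multiplicity_histogram.tsv", sep="\t", index=False)
    frac1 = counts.n_exons[counts.n_rbps == 1].sum() / counts.n_exons.sum()
    print(f"{100 * frac1:.0f}% of affected exons respond to a single RBP; "
          f"up to {counts.n_rbps.max()} RBPs act on one exon")

    direction_consistency(profile).to_csv(
        out / "direction_consistency.tsv", sep="\t", index=False, float_format="%.6g"
    )

    dist = inclusion_distributions(profile)
    dist.frame().to_csv(out / "inclusion_distributions.tsv", sep="\t", index=False)
    print(f"intermediate wildtype inclusion (PSI 0.35-0.65): "
          f"{100 * dist.independent_intermediate_fraction:.1f}% of independent vs "
          f"{100 * dist.interdependent_intermediate_fraction:.1f}% of interdependent exons")

    trends = feature_trend(profile, ds.features)
    (out / "feature_trends.json").write_text(
        json.dumps({k: t.to_dict() for k, t in trends.items()}, indent=2)
    )
    for name in ("ss5_score", "phylop"):
        t = trends[name]
        print(f"{name}: slope {t.slope:+.3f} per added RBP "
              f"(95% CI {t.ci95[0]:+.3f}..{t.ci95[1]:+.3f}, p={t.p_value:.2g})")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
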