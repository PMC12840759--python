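"""Self-contained validation experiments over the analysis pipeline.

Each function recomputes one headline quantity from scratch by running the
package on freshly generated data: pair-count combinatorics, worked
interdependence-matrix cells, exactness of the hypergeometric survival
function, false-positive calibration and detection power of the pair test,
filter fidelity, and recovery/calibration of the exon-feature regression.
Used by the acceptance script and mirrored by the acceptance test suite.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import HELA_POLICY, Regulon, apply_filter
from .interdependence import all_pairs, build_matrix, hypergeom_sf, test_pair
from .io import FEATURE_COLUMNS, deduplicate, feature_index
from .multiplicity import (
    ExonMultiplicity,
    MultiplicityProfile,
    build_multiplicity,
    feature_trend,
    inclusion_distributions,
)
from .simulate import SyntheticConfig, generate, null_resample

__all__ = [
    "count_all_pairs",
    "worked_matrix_cells",
    "hypergeom_max_abs_error",
    "null_rejection_rate",
    "planted_pair_power",
    "filter_fidelity",
    "slope_ci_coverage",
    "null_slope_ks_pvalue",
    "study_profile",
]


def count_all_pairs(n_rbps: int = 30, seed: int = 0) -> int:
    """Number of unordered pair tests produced for ``n_rbps`` regulons."""
    cfg = SyntheticConfig(
        seed=seed, n_rbps=n_rbps, universe_size=2000, planted_multiplicity={}
    )
    regs = next(iter(null_resample(cfg, 1)))
    return len(all_pairs(regs))


def _toy_regulon(name: str, affected, universe) -> Regulon:
    return Regulon(
        rbp_name=name, cell_line="toy", policy=HELA_POLICY,
        affected=frozenset(affected), directions={k: "decrease" for k in affected},
        universe=frozenset(universe),
    )


def worked_matrix_cells() -> dict:
    """Interdependence-matrix cells for three canonical overlap fixtures.

    * an RBP with 9 affected exons, all shared, 4 of them with one partner;
    * an RBP with 137 affected exons, 3 shared with a given partner;
    * an RBP whose every affected exon is shared with one partner.
    Returns the rounded percentage cells.
    """
    universe = range(5000)
    mat_a = build_matrix([
        _toy_regulon("row", range(9), universe),
        _toy_regulon("partner", range(4), universe),
        _toy_regulon("rest", range(4, 9), universe),
    ])
    mat_b = build_matrix([
        _toy_regulon("row", range(137), universe),
        _toy_regulon("partner", range(3), universe),
        _toy_regulon("rest", range(3, 137), universe),
    ])
    mat_c = build_matrix([
        _toy_regulon("row", range(10), universe),
        _toy_regulon("partner", range(10), universe),
    ])
    return {
        "pct_shared_4_of_9": float(round(mat_a.cells.loc["row", "partner"])),
        "pct_shared_3_of_137": float(round(mat_b.cells.loc["row", "partner"])),
        "pct_fully_interdependent": float(
            round(mat_c.per_rbp_interdependent_fraction["row"])
        ),
    }


def _exact_sf(m: int, N: int, M: int, n: int) -> Fraction:
    """P(X >= m) by exact integer enumeration (independent arithmetic route)."""
    if m <= 0:
        return Fraction(1)
    hi = min(M, n)
    if m > hi:
        return Fraction(0)
    tail = sum(comb(M, i) * comb(N - M, n - i) for i in range(m, hi + 1))
    return Fraction(tail, comb(N, n))


def hypergeom_max_abs_error(max_universe: int = 25) -> float:
    """Worst |sf - exact| over every (m, N, M, n) with N <= max_universe."""
    worst = 0.0
    for N in range(max_universe + 1):
        for M in range(N + 1):
            for n in range(N + 1):
                for m in range(min(M, n) + 2):
                    err = abs(hypergeom_sf(m, N, M, n) - float(_exact_sf(m, N, M, n)))
                    worst = max(worst, err)
    return worst


def null_rejection_rate(
    seed: int = 0, n_replicates: int = 5, alpha: float = 0.05
) -> dict:
    """False-positive rate of the pair test on independently drawn regulons.

    30 regulons of log-uniform size in [3, 300] over a 5000-exon universe
    per replicate; 5 replicates give 2175 null pairs.
    """
    cfg = SyntheticConfig(
        seed=seed, n_rbps=30, universe_size=5000, planted_multiplicity={}
    )
    n_rej = n_tot = 0
    for regs in null_resample(cfg, n_replicates):
        for r in all_pairs(regs, alpha=alpha):
            n_rej += r.significant
            n_tot += 1
    return {"rate": n_rej / n_tot, "n_pairs": n_tot}


def planted_pair_power(seed: int = 0, n_replicates: int = 200) -> dict:
    """Detection power for a planted pair at the stated minimum condition.

    Regulon sizes 30/30 sharing 10 exons (Jaccard 0.2) in a 5000-exon
    universe; each replicate runs the full path (tables -> dedup -> filter
    -> pair test).
    """
    detected = 0
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            seed=seed * n_replicates + rep + 1, n_rbps=2, universe_size=5000,
            regulon_sizes=[30, 30], planted_multiplicity={},
            planted_pairs=[("SRSF01", "hnRNPX01", 10)],
        )
        ds = generate(cfg)
        a, b = (
            apply_filter(deduplicate(t), HELA_POLICY)
            for t in ds.tables["HeLa"].values()
        )
        detected += test_pair(a, b, alpha=0.05).significant
    return {"power": detected / n_replicates, "n_replicates": n_replicates}


def filter_fidelity(seed: int = 0) -> dict:
    """Exact recovery of planted affected sets plus threshold boundary behaviour."""
    cfg = SyntheticConfig(seed=seed, n_rbps=8, universe_size=2000, planted_multiplicity={})
    ds = generate(cfg)
    n_exact = 0
    for rbp, table in ds.tables["HeLa"].items():
        reg = apply_filter(deduplicate(table), HELA_POLICY)
        n_exact += reg.affected == ds.truth.lines["HeLa"].affected[rbp]
    from .filtering import ENCODE_POLICY, FilterPolicy
    from .io import KnockdownTable, SkippedExonRecord

    def rec(start, delta, fdr):
        return SkippedExonRecord(
            gene_id="G", gene_symbol="g", chrom="chr1", strand="+",
            exon_start=start, exon_end=start + 100, upstream_es=0, upstream_ee=50,
            downstream_es=start + 200, downstream_ee=start + 250,
            psi_control=0.5, psi_kd=0.5 + delta, delta_psi=delta, fdr=fdr,
        )

    boundary = KnockdownTable.from_records(
        "B", [rec(100, 0.15, 0.5), rec(300, 0.15 + 1e-6, 0.5)], cell_line="toy"
    )
    hela_reg = apply_filter(boundary, HELA_POLICY)
    fdr_tab = KnockdownTable.from_records(
        "B", [rec(100, 0.12, 0.05), rec(300, 0.12, 0.05 + 1e-6)], cell_line="toy"
    )
    encode_reg = apply_filter(fdr_tab, ENCODE_POLICY)
    return {
        "fraction_regulons_recovered": n_exact / cfg.n_rbps,
        "delta_at_threshold_excluded": len(
            [k for k in hela_reg.affected if k.exon_start == 100]
        ) == 0,
        "delta_above_threshold_included": len(
            [k for k in hela_reg.affected if k.exon_start == 300]
        ) == 1,
        "fdr_at_bound_included": len(
            [k for k in encode_reg.affected if k.exon_start == 100]
        ) == 1,
        "fdr_above_bound_excluded": len(
            [k for k in encode_reg.affected if k.exon_start == 300]
        ) == 0,
    }


def slope_ci_coverage(seed: int = 0, n_replicates: int = 100) -> dict:
    """How often the ss5 trend's 95% CI covers the planted slope.

    Full generated path per replicate: 14 RBPs of 200 exons each over a
    4000-exon universe, with every multiplicity bin from 2 to 9 planted
    with 25 exons so each bin mean rests on a reasonable sample (a bin of
    one exon makes the unweighted fit's CI undercover; see methods note).
    """
    covered = 0
    slopes = []
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            seed=seed * n_replicates + rep + 1, n_rbps=14, universe_size=4000,
            regulon_sizes=[200] * 14,
            planted_multiplicity={k: 25 for k in range(2, 10)},
        )
        ds = generate(cfg)
        prof = build_multiplicity(ds.truth.regulons())
        t = feature_trend(prof, ds.features)["ss5_score"]
        planted = ds.truth.feature_models["ss5_score"].slope
        covered += t.ci95[0] < planted < t.ci95[1]
        slopes.append(t.slope)
    return {
        "coverage": covered / n_replicates,
        "mean_slope": float(np.mean(slopes)),
        "planted_slope": -0.4,
        "n_replicates": n_replicates,
    }


def _balanced_profile(n_per_bin: int = 40, kmax: int = 9) -> MultiplicityProfile:
    per = {}
    i = 0
    for k in range(1, kmax + 1):
        for _ in range(n_per_bin):
            per[i] = ExonMultiplicity(
                rbps=tuple(f"R{j}" for j in range(k)),
                signs=("increase",) * k,
                psi_control=None,
            )
            i += 1
    return MultiplicityProfile(per)


def null_slope_ks_pvalue(seed: int = 0, n_replicates: int = 200) -> dict:
    """KS uniformity of trend p-values for a feature with no planted slope.

    Calibrates the regression under its own sampling assumptions: balanced
    multiplicity bins with iid per-exon noise (unequal bins make the
    unweighted bin-mean fit heteroscedastic and only approximately
    calibrated; see the methods note).
    """
    prof = _balanced_profile()
    keys = list(prof.per_exon)
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_replicates):
        data = {c: 8.0 + rng.normal(0.0, 1.0, len(keys)) for c in FEATURE_COLUMNS}
        feats = pd.DataFrame(data, index=pd.Index(keys))
        pvals.append(feature_trend(prof, feats)["ss5_score"].p_value)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n_replicates": n_replicates}


def study_profile(seed: int = 0) -> dict:
    """Headline statistics of one default study-scale synthetic run.

    Full path: generated tables -> dedup -> filter -> pairs -> multiplicity
    -> inclusion distributions, with the conservation invariants asserted.
    """
    ds = generate(SyntheticConfig(seed=seed))
    regs = [
        apply_filter(deduplicate(t), HELA_POLICY)
        for t in ds.tables["HeLa"].values()
    ]
    results = all_pairs(regs, alpha=0.05)
    profile = build_multiplicity(regs)
    counts = profile.counts_table().set_index("n_rbps")["n_exons"]
    union = set().union(*(r.affected for r in regs))
    assert counts.sum() == len(union), "multiplicity bins must conserve the union"
    dist = inclusion_distributions(profile)
    return {
        "n_pairs": len(results),
        "pct_pairs_significant": 100.0 * np.mean([r.significant for r in results]),
        "pct_exons_single_rbp": 100.0 * counts.get(1, 0) / counts.sum(),
        "max_rbps_per_exon": int(counts.index.max()),
        "intermediate_fraction_independent": dist.independent_intermediate_fraction,
        "intermediate_fraction_interdependent": dist.interdependent_intermediate_fraction,
    }
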