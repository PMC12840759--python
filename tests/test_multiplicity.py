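from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spliceinterdep as si
from spliceinterdep.filtering import HELA_POLICY, Regulon
from spliceinterdep.io import FEATURE_COLUMNS, feature_index
from spliceinterdep.multiplicity import (
    ExonMultiplicity,
    MultiplicityProfile,
    bin_feature_summary,
    build_multiplicity,
    direction_consistency,
    feature_trend,
    inclusion_distributions,
)


def regulon(name, directions, universe, psi=None):
    return Regulon(
        rbp_name=name, cell_line="HeLa", policy=HELA_POLICY,
        affected=frozenset(directions), directions=dict(directions),
        universe=frozenset(universe), psi_control=psi or {},
    )


def profile_from(entries):
    """entries: mapping key -> (signs tuple, psi or None)."""
    return MultiplicityProfile(
        per_exon={
            k: ExonMultiplicity(
                rbps=tuple(f"R{i}" for i in range(len(signs))), signs=tuple(signs), psi_control=psi
            )
            for k, (signs, psi) in entries.items()
        }
    )


class TestBuildMultiplicity:
    def test_shared_exon_counted_once_per_rbp(self):
        universe = range(20)
        regs = [regulon(f"R{i}", {0: "increase", i + 1: "decrease"}, universe) for i in range(3)]
        prof = build_multiplicity(regs)
        assert prof.per_exon[0].count == 3
        assert all(prof.per_exon[k].count == 1 for k in (1, 2, 3))

    def test_disjoint_regulons_all_count_one(self):
        universe = range(20)
        regs = [regulon(f"R{i}", {i: "increase"}, universe) for i in range(4)]
        prof = build_multiplicity(regs)
        assert {e.count for e in prof.per_exon.values()} == {1}

    def test_bins_conserve_the_affected_union(self, small_regulons):
        prof = build_multiplicity(small_regulons)
        union = set().union(*(r.affected for r in small_regulons))
        assert sum(len(v) for v in prof.bins.values()) == len(union)
        assert set(prof.per_exon) == union

    def test_bin_one_is_the_independent_population(self, small_regulons):
        prof = build_multiplicity(small_regulons)
        bin1 = set(prof.bins[1])
        from spliceinterdep.direction import summarize_direction

        n_indep = sum(
            summarize_direction(r, prof, "independent").n_exons for r in small_regulons
        )
        assert n_indep == len(bin1)

    def test_psi_control_averaged_across_sources(self):
        universe = range(10)
        a = regulon("A", {0: "increase"}, universe, psi={0: 0.4})
        b = regulon("B", {0: "decrease"}, universe, psi={0: 0.6})
        prof = build_multiplicity([a, b])
        assert prof.per_exon[0].psi_control == pytest.approx(0.5)

    def test_mixed_cell_lines_rejected(self):
        a = regulon("A", {0: "increase"}, range(5))
        b = Regulon("B", "K562", HELA_POLICY, frozenset({1}), {1: "increase"}, frozenset(range(5)))
        with pytest.raises(ValueError, match="cell line"):
            build_multiplicity([a, b])


class TestDirectionConsistency:
    def test_exclusive_and_mixed_sign_classes(self):
        prof = profile_from({
            0: (("increase", "increase"), None),
            1: (("increase", "decrease", "decrease"), None),
            2: (("decrease",), None),
        })
        frame = direction_consistency(prof).set_index("n_rbps")
        assert frame.loc[2, "pct_increase_only"] == pytest.approx(100.0)
        assert frame.loc[3, "pct_both"] == pytest.approx(100.0)
        assert frame.loc[1, "pct_both"] == 0.0

    def test_both_fraction_is_zero_in_bin_one(self, small_regulons):
        frame = direction_consistency(build_multiplicity(small_regulons))
        assert frame.set_index("n_rbps").loc[1, "pct_both"] == 0.0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_independent_coin_flip_signs_match_closed_form(self, k):
        # P(both directions among k fair sign flips) = 1 - 2 * 0.5^k
        rng = np.random.default_rng(17)
        n = 4000
        entries = {
            i: (tuple(rng.choice(["increase", "decrease"], k)), None) for i in range(n)
        }
        frame = direction_consistency(profile_from(entries)).set_index("n_rbps")
        expected = 1 - 2 * 0.5**k
        se = np.sqrt(expected * (1 - expected) / n)
        assert frame.loc[k, "pct_both"] / 100 == pytest.approx(expected, abs=3 * se)


class TestInclusionDistributions:
    def test_bimodal_mixture_has_low_intermediate_fraction(self):
        rng = np.random.default_rng(8)
        n = 4000
        psis = np.where(rng.random(n) < 0.5, rng.beta(1, 9, n), rng.beta(9, 1, n))
        prof = profile_from({i: (("increase",), float(p)) for i, p in enumerate(psis)})
        d = inclusion_distributions(prof)
        # closed form: mixture mass on [0.35, 0.65] from the Beta CDFs
        expected = 0.5 * (
            stats.beta.cdf(0.65, 1, 9) - stats.beta.cdf(0.35, 1, 9)
            + stats.beta.cdf(0.65, 9, 1) - stats.beta.cdf(0.35, 9, 1)
        )
        assert expected < 0.05
        assert d.independent_intermediate_fraction < 0.10
        assert d.independent_intermediate_fraction == pytest.approx(expected, abs=0.02)

    def test_intermediate_component_raises_interdependent_fraction(self):
        rng = np.random.default_rng(9)
        n = 3000
        indep = np.where(rng.random(n) < 0.5, rng.beta(1, 9, n), rng.beta(9, 1, n))
        u = rng.random(n)
        inter = np.where(
            u < 0.3, rng.beta(5, 5, n),
            np.where(rng.random(n) < 0.5, rng.beta(1, 9, n), rng.beta(9, 1, n)),
        )
        entries = {i: (("increase",), float(p)) for i, p in enumerate(indep)}
        entries.update(
            {n + i: (("increase", "decrease"), float(p)) for i, p in enumerate(inter)}
        )
        d = inclusion_distributions(profile_from(entries))
        assert d.interdependent_intermediate_fraction > d.independent_intermediate_fraction

    def test_degenerate_all_intermediate(self):
        prof = profile_from({i: (("increase",), 0.5) for i in range(5)})
        d = inclusion_distributions(prof)
        assert d.independent_intermediate_fraction == 1.0

    def test_no_psi_at_all_is_an_error(self):
        prof = profile_from({0: (("increase",), None)})
        with pytest.raises(ValueError, match="PSI"):
            inclusion_distributions(prof)

    def test_sparse_psi_coverage_warns(self):
        entries = {i: (("increase",), 0.2 if i == 0 else None) for i in range(10)}
        with pytest.warns(UserWarning, match="missing"):
            inclusion_distributions(profile_from(entries))

    def test_histograms_count_every_exon_with_psi(self, small_regulons):
        prof = build_multiplicity(small_regulons)
        d = inclusion_distributions(prof)
        assert d.independent_hist.sum() == d.n_independent
        assert d.interdependent_hist.sum() == d.n_interdependent
        assert d.n_independent + d.n_interdependent == len(prof.per_exon)


def features_for(profile, rng, slope=0.0, intercept=8.0, sd=1.0):
    keys = list(profile.per_exon)
    counts = np.array([profile.per_exon[k].count for k in keys], dtype=float)
    data = {}
    for col in FEATURE_COLUMNS:
        data[col] = intercept + slope * counts + rng.normal(0, sd, len(keys))
    idx = feature_index(keys) if isinstance(keys[0], tuple) else pd.Index(keys)
    return pd.DataFrame(data, index=idx)


class TestFeatureTrend:
    def test_planted_negative_slope_recovered(self, small_dataset, small_regulons):
        prof = build_multiplicity(small_regulons)
        trends = feature_trend(prof, small_dataset.features)
        t = trends["ss5_score"]
        planted = small_dataset.truth.feature_models["ss5_score"].slope
        assert t.ci95[0] < planted < t.ci95[1]
        assert t.slope < 0

    def test_constant_feature_has_zero_slope(self):
        prof = profile_from(
            {i: (tuple(["increase"] * (1 + i % 4)), None) for i in range(40)}
        )
        feats = features_for(prof, np.random.default_rng(0), sd=0.0)
        trends = feature_trend(prof, feats)
        assert trends["ss5_score"].slope == 0.0
        assert trends["ss5_score"].r_squared == 0.0

    def test_matches_scipy_linregress_on_bin_means(self):
        prof = profile_from(
            {i: (tuple(["increase"] * (1 + i % 5)), None) for i in range(60)}
        )
        feats = features_for(prof, np.random.default_rng(1), slope=-0.3)
        trends = feature_trend(prof, feats)
        summary = bin_feature_summary(prof, feats)
        ref = stats.linregress(summary["n_rbps"], summary["ss5_score"])
        t = trends["ss5_score"]
        assert t.slope == pytest.approx(ref.slope)
        assert t.p_value == pytest.approx(ref.pvalue)
        assert t.stderr == pytest.approx(ref.stderr)

    def test_too_few_bins_rejected(self):
        prof = profile_from({0: (("increase",), None), 1: (("increase", "decrease"), None)})
        feats = features_for(prof, np.random.default_rng(2))
        with pytest.raises(ValueError, match="bins"):
            feature_trend(prof, feats)

    def test_exons_missing_from_feature_table_are_dropped(self):
        prof = profile_from(
            {i: (tuple(["increase"] * (1 + i % 3)), None) for i in range(30)}
        )
        feats = features_for(prof, np.random.default_rng(3)).iloc[:20]
        summary = bin_feature_summary(prof, feats)
        assert summary["n_exons"].sum() == 20

    def test_reference_values_echoed(self):
        prof = profile_from(
            {i: (tuple(["increase"] * (1 + i % 4)), None) for i in range(40)}
        )
        feats = features_for(prof, np.random.default_rng(4))
        trends = feature_trend(prof, feats, reference_values={"ss5_score": 8.77})
        assert trends["ss5_score"].reference == 8.77
        assert trends["phylop"].reference is None

    def test_weighted_variant_runs_and_differs(self):
        counts = [1] * 50 + [2] * 20 + [3] * 6 + [4] * 4
        prof = profile_from(
            {i: (tuple(["increase"] * c), None) for i, c in enumerate(counts)}
        )
        feats = features_for(prof, np.random.default_rng(5), slope=-0.2)
        unw = feature_trend(prof, feats)["ss5_score"]
        w = feature_trend(prof, feats, weighted=True)["ss5_score"]
        assert np.isfinite(w.slope) and np.isfinite(w.p_value)
        assert w.slope != unw.slope
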