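from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import spliceinterdep as si
from spliceinterdep.context import (
    cross_line_exon_overlap,
    detect_cross_regulation,
    relative_importance,
    shared_significant_pairs,
)
from spliceinterdep.filtering import HELA_POLICY
from spliceinterdep.interdependence import PairTestResult
from spliceinterdep.io import KnockdownTable


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["rbp_name", "cell_line", "n_affected"])


class TestRelativeImportance:
    def test_normalised_to_the_line_maximum(self):
        out = relative_importance(counts_frame([("A", "HeLa", 100), ("B", "HeLa", 50)]))
        vals = dict(zip(out["rbp_name"], out["relative_importance"]))
        assert vals == {"A": 1.0, "B": 0.5}

    def test_single_rbp_has_importance_one(self):
        out = relative_importance(counts_frame([("A", "HeLa", 7)]))
        assert out["relative_importance"].iloc[0] == 1.0

    def test_scale_free_within_a_line(self):
        base = counts_frame([("A", "L1", 30), ("B", "L1", 10), ("A", "L2", 5), ("B", "L2", 20)])
        scaled = base.copy()
        scaled.loc[scaled.cell_line == "L1", "n_affected"] *= 13
        a = relative_importance(base)["relative_importance"]
        b = relative_importance(scaled)["relative_importance"]
        np.testing.assert_allclose(a, b)

    def test_all_zero_cell_line_rejected(self):
        with pytest.raises(ValueError, match="no affected"):
            relative_importance(counts_frame([("A", "L1", 0), ("B", "L1", 0)]))

    def test_planted_most_influential_rbp_recovered(self, small_dataset):
        truth = small_dataset.truth
        rows = [
            (rbp, "HeLa", len(aff)) for rbp, aff in truth.lines["HeLa"].affected.items()
        ]
        out = relative_importance(counts_frame(rows))
        top = out.loc[out["relative_importance"] == 1.0, "rbp_name"].tolist()
        expected = max(truth.regulon_sizes, key=truth.regulon_sizes.get)
        assert expected in top


def pair(a, b, p, alpha=0.05):
    return PairTestResult(a, b, m=1, N=100, M=10, n=10, p_value=p,
                          significant=p <= alpha, status="tested")


class TestSharedSignificantPairs:
    def test_intersection_across_lines(self):
        by_line = {
            "L1": [pair("A", "B", 0.01), pair("A", "C", 0.01), pair("B", "C", 0.5)],
            "L2": [pair("A", "B", 0.04), pair("A", "C", 0.9), pair("B", "C", 0.9)],
        }
        res = shared_significant_pairs(by_line)
        assert res.shared == {frozenset(("A", "B"))}
        assert res.per_line_significant_fraction["L1"] == pytest.approx(2 / 3)

    def test_disjoint_significant_sets_share_nothing(self):
        by_line = {
            "L1": [pair("A", "B", 0.01), pair("A", "C", 0.9)],
            "L2": [pair("A", "B", 0.9), pair("A", "C", 0.01)],
        }
        assert shared_significant_pairs(by_line).shared == set()

    def test_shared_is_subset_of_every_line(self, small_dataset):
        regs = {line: small_dataset.truth.regulons(line) for line in ("HeLa",)}
        results = {line: si.all_pairs(r) for line, r in regs.items()}
        res = shared_significant_pairs(results)
        for line, rs in results.items():
            sig = {r.pair for r in rs if r.significant}
            assert res.shared <= sig

    def test_no_common_rbps_rejected(self):
        by_line = {"L1": [pair("A", "B", 0.01)], "L2": [pair("C", "D", 0.01)]}
        with pytest.raises(ValueError, match="no RBPs"):
            shared_significant_pairs(by_line)


def kd_table(make_record, rbp, rows):
    """rows: list of (gene_id, delta)."""
    recs = [
        make_record(
            gene_id=g, gene_symbol=g.lower(), exon_start=100 + 200 * i,
            exon_end=200 + 200 * i, psi_control=0.5, psi_kd=0.5 + d, delta_psi=d,
        )
        for i, (g, d) in enumerate(rows)
    ]
    return KnockdownTable.from_records(rbp, recs, cell_line="HeLa")


class TestDetectCrossRegulation:
    GENE_MAP = {"X": ["GX"], "Y": ["GY"]}

    def test_hit_above_threshold(self, make_record):
        tables = [kd_table(make_record, "X", [("GY", 0.2), ("GZ", 0.4)]),
                  kd_table(make_record, "Y", [("GZ", 0.1)])]
        cross, auto = detect_cross_regulation(tables, self.GENE_MAP)
        assert len(cross) == 1 and auto == []
        hit = cross[0]
        assert (hit.knocked_down_rbp, hit.responding_rbp) == ("X", "Y")
        assert hit.n_responding_exons == 1
        assert hit.max_abs_delta_psi == pytest.approx(0.2)

    def test_below_threshold_is_not_a_hit(self, make_record):
        tables = [kd_table(make_record, "X", [("GY", 0.12)]),
                  kd_table(make_record, "Y", [])]
        cross, auto = detect_cross_regulation(tables, self.GENE_MAP)
        assert cross == [] and auto == []

    def test_own_gene_flagged_as_autoregulation(self, make_record):
        tables = [kd_table(make_record, "X", [("GX", 0.3)]),
                  kd_table(make_record, "Y", [])]
        cross, auto = detect_cross_regulation(tables, self.GENE_MAP)
        assert cross == []
        assert len(auto) == 1 and auto[0].knocked_down_rbp == "X"

    def test_unmapped_rbp_rejected_with_names(self, make_record):
        tables = [kd_table(make_record, "Z", [])]
        with pytest.raises(ValueError, match="Z"):
            detect_cross_regulation(tables, self.GENE_MAP)

    def test_invariant_to_record_order(self, make_record):
        t = kd_table(make_record, "X", [("GY", 0.2), ("GY", 0.3), ("GZ", 0.4)])
        shuffled = KnockdownTable(
            t.rbp_name, t.rbp_family, t.cell_line,
            t.frame.iloc[::-1].reset_index(drop=True),
        )
        a = detect_cross_regulation([t], self.GENE_MAP)
        b = detect_cross_regulation([shuffled], self.GENE_MAP)
        assert a == b

    def test_planted_rbp_genes_found_in_synthetic_tables(self, small_dataset):
        truth = small_dataset.truth
        gene_map = {r: list(gs) for r, gs in truth.rbp_gene_map.items()}
        tables = list(small_dataset.tables["HeLa"].values())
        cross, auto = detect_cross_regulation(tables, gene_map)
        for hit in cross:
            assert hit.max_abs_delta_psi > 0.15
            assert hit.knocked_down_rbp != hit.responding_rbp


class TestCrossLineOverlap:
    def make_regs(self, line, sets):
        universe = frozenset(range(1000))
        return {
            name: si.Regulon(name, line, HELA_POLICY, frozenset(s),
                             {k: "increase" for k in s}, universe)
            for name, s in sets.items()
        }

    def test_identical_and_disjoint_regulons(self):
        by_line = {
            "L1": self.make_regs("L1", {"A": range(10), "B": range(20, 30)}),
            "L2": self.make_regs("L2", {"A": range(10), "B": range(50, 60)}),
        }
        out = cross_line_exon_overlap(by_line).set_index("rbp_name")
        assert out.loc["A", "jaccard"] == 1.0
        assert out.loc["B", "jaccard"] == 0.0

    def test_resampled_lines_match_expected_jaccard(self):
        # keep-probability f, sizes restored: E[J] ~ f / (2 - f)
        f = 0.25
        cfg = si.SyntheticConfig(
            seed=3, n_rbps=8, universe_size=4000,
            regulon_sizes=[120] * 8, planted_multiplicity={},
            cell_lines=[si.CellLineSpec("L1"), si.CellLineSpec("L2", resample_fraction=f)],
        )
        ds = si.generate(cfg)
        by_line = {
            line: {r.rbp_name: r for r in ds.truth.regulons(line)}
            for line in ("L1", "L2")
        }
        out = cross_line_exon_overlap(by_line)
        expected = f / (2 - f)
        assert out["jaccard"].mean() == pytest.approx(expected, abs=0.05)
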