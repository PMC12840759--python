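from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from helpers import brute_force_complete_linkage, exact_hypergeom_sf
from spliceinterdep.filtering import HELA_POLICY, Regulon
from spliceinterdep.interdependence import (
    InterdependenceMatrix,
    all_pairs,
    build_matrix,
    cluster_matrix,
    hypergeom_sf,
    pairs_frame,
)
from spliceinterdep.interdependence import test_pair as pair_test


def regulon(name, affected, universe, cell_line="HeLa"):
    return Regulon(
        rbp_name=name,
        cell_line=cell_line,
        policy=HELA_POLICY,
        affected=frozenset(affected),
        directions={k: "decrease" for k in affected},
        universe=frozenset(universe),
    )


class TestHypergeomSf:
    def test_zero_overlap_tail_is_one(self):
        assert hypergeom_sf(0, 10, 5, 5) == 1.0
        assert hypergeom_sf(0, 0, 0, 0) == 1.0

    def test_small_case_matches_exact_enumeration(self):
        # P(X >= 1) for N=10, M=n=5: 1 - C(5,5)/C(10,5) = 251/252
        assert hypergeom_sf(1, 10, 5, 5) == pytest.approx(251 / 252, abs=1e-12)

    def test_overlap_beyond_support_is_exactly_zero(self):
        assert hypergeom_sf(6, 10, 5, 5) == 0.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_sf(1, 10, 11, 5)
        with pytest.raises(ValueError):
            hypergeom_sf(1, 10, 5, 11)
        with pytest.raises(ValueError):
            hypergeom_sf(1.5, 10, 5, 5)

    def test_matches_exact_oracle_on_random_tuples(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            N = int(rng.integers(1, 26))
            M = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            m = int(rng.integers(0, min(M, n) + 2))
            assert hypergeom_sf(m, N, M, n) == pytest.approx(
                float(exact_hypergeom_sf(m, N, M, n)), abs=1e-12
            )

    def test_matches_scipy_at_scale(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            N = int(rng.integers(100, 50_000))
            M = int(rng.integers(1, min(N, 400)))
            n = int(rng.integers(1, min(N, 400)))
            m = int(rng.integers(0, min(M, n) + 1))
            ours = hypergeom_sf(m, N, M, n)
            ref = float(hypergeom.sf(m - 1, N, M, n))
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_complement_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            N = int(rng.integers(1, 40))
            M = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            m = int(rng.integers(0, min(M, n) + 1))
            cdf = float(hypergeom.cdf(m - 1, N, M, n))
            assert hypergeom_sf(m, N, M, n) + cdf == pytest.approx(1.0, abs=1e-12)

    def test_tail_non_increasing_in_m(self):
        N, M, n = 500, 60, 80
        vals = [hypergeom_sf(m, N, M, n) for m in range(0, min(M, n) + 2)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))


class TestTestPair:
    def test_counts_and_significance_for_planted_overlap(self):
        universe = range(5000)
        shared = set(range(40))
        a = regulon("A", shared | set(range(100, 160)), universe)
        b = regulon("B", shared | set(range(200, 260)), universe)
        r = pair_test(a, b)
        assert (r.m, r.N, r.M, r.n) == (40, 5000, 100, 100)
        assert r.p_value < 1e-30 and r.significant and r.status == "tested"

    def test_symmetry(self):
        universe = range(300)
        a = regulon("A", range(0, 30), universe)
        b = regulon("B", range(20, 80), range(0, 400))
        r1, r2 = pair_test(a, b), pair_test(b, a)
        assert (r1.m, r1.N) == (r2.m, r2.N)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert (r1.M, r1.n) == (r2.n, r2.M)

    def test_disjoint_regulons_flagged_no_overlap(self):
        universe = range(100)
        r = pair_test(regulon("A", range(10), universe), regulon("B", range(50, 60), universe))
        assert r.m == 0 and r.p_value == 1.0 and r.status == "no_overlap"
        assert not r.significant

    def test_degenerate_full_overlap_has_p_one(self):
        universe = range(20)
        a = regulon("A", universe, universe)
        b = regulon("B", universe, universe)
        r = pair_test(a, b, alpha=0.05)
        assert r.p_value == pytest.approx(1.0) and not r.significant
        assert pair_test(a, b, alpha=1.0).significant

    def test_mismatched_cell_lines_rejected(self):
        a = regulon("A", range(5), range(50))
        b = regulon("B", range(5), range(50), cell_line="K562")
        with pytest.raises(ValueError, match="cell line"):
            pair_test(a, b)

    def test_sum_universe_mode_is_larger(self):
        universe = range(200)
        a = regulon("A", range(20), universe)
        b = regulon("B", range(10, 40), universe)
        assert pair_test(a, b, universe_mode="sum").N == 400
        assert pair_test(a, b).N == 200


class TestAllPairs:
    def test_pair_count_is_k_choose_2(self):
        universe = range(500)
        regs = [regulon(f"R{i:02d}", range(i * 10, i * 10 + 20), universe) for i in range(5)]
        assert len(all_pairs(regs)) == 10
        assert len(all_pairs(regs[:2])) == 1

    def test_results_ordered_lexicographically(self):
        universe = range(100)
        regs = [regulon(n, range(10), universe) for n in ("C", "A", "B")]
        res = all_pairs(regs)
        assert [(r.rbp_a, r.rbp_b) for r in res] == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_duplicate_names_rejected(self):
        universe = range(100)
        regs = [regulon("A", range(10), universe), regulon("A", range(20, 30), universe)]
        with pytest.raises(ValueError, match="duplicate"):
            all_pairs(regs)

    def test_planted_pairs_detected_null_pairs_not(self, small_dataset):
        cfg = small_dataset.config
        import spliceinterdep as si

        ds = si.generate(
            si.SyntheticConfig(
                seed=2, n_rbps=5, universe_size=5000,
                regulon_sizes=[100, 100, 80, 60, 40],
                planted_multiplicity={},
                planted_pairs=[("SRSF01", "SRSF02", 40), ("SRSF03", "hnRNPX01", 20)],
            )
        )
        res = all_pairs(ds.truth.regulons())
        sig = {tuple(sorted(r.pair)) for r in res if r.significant}
        assert sig == {("SRSF01", "SRSF02"), ("SRSF03", "hnRNPX01")}

    def test_bh_correction_never_adds_discoveries(self):
        rng = np.random.default_rng(9)
        universe = range(2000)
        regs = [
            regulon(f"R{i:02d}", rng.choice(2000, 60, replace=False), universe)
            for i in range(8)
        ]
        raw = all_pairs(regs)
        bh = all_pairs(regs, correction="bh")
        assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)


class TestBuildMatrix:
    def test_worked_example_44_percent_cell(self):
        # row RBP affects 9 exons, all shared with others; 4 shared with B
        universe = range(1000)
        a = regulon("hnRNPR", range(9), universe)
        b = regulon("hnRNPC", range(4), universe)          # shares exons 0-3
        c = regulon("hnRNPH", range(4, 9), universe)       # shares exons 4-8
        mat = build_matrix([a, b, c])
        assert mat.row_totals["hnRNPR"] == 9
        assert mat.per_rbp_interdependent_fraction["hnRNPR"] == pytest.approx(100.0)
        assert round(mat.cells.loc["hnRNPR", "hnRNPC"]) == 44

    def test_worked_example_2_percent_cell(self):
        # 137 affected exons all interdependent, 3 shared with the partner
        universe = range(5000)
        a = regulon("hnRNPK", range(137), universe)
        b = regulon("hnRNPA0", range(3), universe)
        c = regulon("bulk", range(3, 137), universe)
        mat = build_matrix([a, b, c])
        assert mat.row_totals["hnRNPK"] == 137
        assert round(mat.cells.loc["hnRNPK", "hnRNPA0"]) == 2

    def test_fully_shared_regulon_is_100_percent_interdependent(self):
        universe = range(100)
        a = regulon("A", range(10), universe)
        b = regulon("B", range(10), universe)
        mat = build_matrix([a, b])
        assert mat.per_rbp_interdependent_fraction["A"] == pytest.approx(100.0)
        assert mat.cells.loc["A", "B"] == pytest.approx(100.0)

    def test_zero_interdependent_row_reports_zero_cells(self):
        universe = range(100)
        a = regulon("A", range(10), universe)
        b = regulon("B", range(50, 60), universe)
        mat = build_matrix([a, b])
        assert mat.row_totals["A"] == 0
        assert mat.cells.loc["A", "B"] == 0.0
        assert mat.per_rbp_interdependent_fraction["A"] == 0.0

    def test_inconsistent_pair_results_rejected(self):
        universe = range(100)
        a = regulon("A", range(10), universe)
        b = regulon("B", range(5, 15), universe)
        res = all_pairs([a, b])
        bad = [res[0].__class__(**{**res[0].__dict__, "m": res[0].m + 1})]
        with pytest.raises(ValueError, match="recomputed"):
            build_matrix([a, b], bad)


class TestClusterMatrix:
    def matrix_from_rows(self, names, rows):
        cells = pd.DataFrame(rows, index=names, columns=[f"c{i}" for i in range(len(rows[0]))])
        return InterdependenceMatrix(
            rbp_order=list(names), row_totals={}, cells=cells,
            per_rbp_interdependent_fraction={}, n_affected={},
        )

    def test_complete_linkage_heights_match_brute_force(self):
        # points 0, 1, 2.1: complete and single linkage disagree on heights
        pts = [(0.0,), (1.0,), (2.1,)]
        mat = self.matrix_from_rows(["a", "b", "c"], pts)
        res = cluster_matrix(mat)
        heights = sorted(res.row_linkage[:, 2])
        assert heights == pytest.approx(brute_force_complete_linkage(pts))
        assert heights[-1] == pytest.approx(2.1)  # single linkage would give 1.1

    def test_identical_rows_merge_at_height_zero(self):
        mat = self.matrix_from_rows(["a", "b"], [(1.0, 2.0), (1.0, 2.0)])
        res = cluster_matrix(mat)
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_two_rows_give_single_merge(self):
        mat = self.matrix_from_rows(["a", "b"], [(0.0,), (3.0,)])
        res = cluster_matrix(mat)
        assert res.row_linkage.shape[0] == 1
        assert set(res.row_order) == {"a", "b"}

    def test_single_row_rejected(self):
        mat = self.matrix_from_rows(["a"], [(0.0,)])
        with pytest.raises(ValueError):
            cluster_matrix(mat)
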