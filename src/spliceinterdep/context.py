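"""Cross-cell-line comparisons and indirect-effect (cross-regulation) scans.

Covers: relative importance of each RBP within a cell line (affected-exon
count normalised to the line's most influential RBP), RBP pairs whose
co-regulation is significant in every cell line, per-RBP Jaccard overlap of
regulons across lines, and detection of knockdowns that change the splicing
of *another* splicing factor's gene — evidence that part of a knockdown's
footprint is indirect.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import KnockdownTable
from .filtering import Regulon
from .interdependence import PairTestResult

__all__ = [
    "relative_importance",
    "SharedPairs",
    "shared_significant_pairs",
    "CrossRegulationHit",
    "detect_cross_regulation",
    "cross_line_exon_overlap",
]


def relative_importance(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalise per-RBP affected counts by each cell line's maximum.

    ``counts`` needs columns ``rbp_name``, ``cell_line``, ``n_affected``.
    Within each line the most influential RBP gets importance 1.0.
    """
    required = {"rbp_name", "cell_line", "n_affected"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts frame missing column(s) {sorted(missing)}")
    out = counts.copy()
    maxima = out.groupby("cell_line")["n_affected"].transform("max")
    if (maxima == 0).any():
        zero = sorted(out.loc[maxima == 0, "cell_line"].unique())
        raise ValueError(f"cell line(s) with no affected exons at all: {zero}")
    out["relative_importance"] = out["n_affected"] / maxima
    return out.sort_values(["cell_line", "rbp_name"], ignore_index=True)


@dataclass
class SharedPairs:
    """Significant pairs common to every cell line, plus per-line rates."""

    shared: set  # of frozenset({rbp_a, rbp_b})
    per_line_significant_fraction: dict
    per_line_n_tested: dict


def shared_significant_pairs(
    results_by_line: Mapping[str, Sequence[PairTestResult]]
) -> SharedPairs:
    """Intersect significant pairs across cell lines."""
    if not results_by_line:
        raise ValueError("no pair results given")
    rbp_sets = [
        {n for r in results for n in (r.rbp_a, r.rbp_b)}
        for results in results_by_line.values()
    ]
    common = set.intersection(*rbp_sets)
    if not common:
        raise ValueError("cell lines share no RBPs")
    shared = None
    fractions, tested = {}, {}
    for line, results in results_by_line.items():
        sig = {r.pair for r in results if r.significant}
        fractions[line] = len(sig) / len(results) if results else float("nan")
        tested[line] = len(results)
        shared = sig if shared is None else shared & sig
    return SharedPairs(
        shared=shared or set(),
        per_line_significant_fraction=fractions,
        per_line_n_tested=tested,
    )


@dataclass(frozen=True)
class CrossRegulationHit:
    """Knockdown of one RBP changed splicing of another RBP's gene."""

    knocked_down_rbp: str
    responding_rbp: str
    n_responding_exons: int
    max_abs_delta_psi: float


def detect_cross_regulation(
    tables: Iterable[KnockdownTable],
    rbp_gene_map: Mapping[str, Iterable[str]],
    min_abs_delta_psi: float = 0.15,
) -> tuple[list[CrossRegulationHit], list[CrossRegulationHit]]:
    """Scan knockdown tables for splicing changes in other RBPs' genes.

    ``rbp_gene_map`` maps each RBP name to the gene identifiers/symbols of
    its own gene.  Returns ``(cross_hits, autoregulation)``: a cross hit
    records >= 1 exon of another RBP's gene with |delta PSI| above the
    threshold; events in the knocked-down RBP's own gene are reported
    separately as candidate autoregulation, not counted as cross hits.
    """
    tables = list(tables)
    unmapped = sorted({t.rbp_name for t in tables} - set(rbp_gene_map))
    if unmapped:
        raise ValueError(f"RBP(s) missing from the gene map: {unmapped}")
    gene_to_rbp: dict[str, str] = {}
    for rbp, genes in rbp_gene_map.items():
        for g in genes:
            gene_to_rbp[str(g)] = rbp

    cross: dict[tuple, list] = {}
    auto: dict[tuple, list] = {}
    for t in tables:
        frame = t.frame
        passing = frame["delta_psi"].abs() > min_abs_delta_psi
        for row in frame[passing].itertuples(index=False):
            target = gene_to_rbp.get(str(row.gene_id)) or gene_to_rbp.get(
                str(row.gene_symbol)
            )
            if target is None:
                continue
            bucket = auto if target == t.rbp_name else cross
            bucket.setdefault((t.rbp_name, target), []).append(abs(row.delta_psi))

    def finish(d: dict) -> list[CrossRegulationHit]:
        return sorted(
            (
                CrossRegulationHit(kd, resp, len(vals), max(vals))
                for (kd, resp), vals in d.items()
            ),
            key=lambda h: (h.knocked_down_rbp, h.responding_rbp),
        )

    return finish(cross), finish(auto)


def cross_line_exon_overlap(
    regulons_by_line: Mapping[str, Mapping[str, Regulon]]
) -> pd.DataFrame:
    """Per-RBP Jaccard index of affected-exon sets between cell-line pairs.

    Assumes all lines share one genome build (coordinates comparable).
    """
    lines = sorted(regulons_by_line)
    rows = []
    for la, lb in combinations(lines, 2):
        shared_rbps = sorted(set(regulons_by_line[la]) & set(regulons_by_line[lb]))
        for rbp in shared_rbps:
            a = regulons_by_line[la][rbp].affected
            b = regulons_by_line[lb][rbp].affected
            union = len(a | b)
            rows.append(
                {
                    "rbp_name": rbp,
                    "line_a": la,
                    "line_b": lb,
                    "n_a": len(a),
                    "n_b": len(b),
                    "n_shared": len(a & b),
                    "jaccard": (len(a & b) / union) if union else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["rbp_name", "line_a", "line_b", "n_a", "n_b", "n_shared", "jaccard"])
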