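"""Pairwise co-regulation tests and the interdependence matrix.

Two RBPs *interdependently regulate* splicing when their regulons (affected
exon sets) overlap more than chance expects.  With a universe of N exons,
regulon sizes M and n, and observed overlap m, the p-value is the
hypergeometric survival function

    P(X >= m) = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n),

i.e. the chance that two independent draws of these sizes share at least m
exons.  The tail is summed in log-space for numerical stability and
cross-checked against :mod:`scipy.stats` in the test suite.

The interdependence matrix summarises, for each RBP (row), what share of
its interdependently regulated exons is also affected by each other RBP
(column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .filtering import Regulon

__all__ = [
    "hypergeom_sf",
    "PairTestResult",
    "test_pair",
    "all_pairs",
    "pairs_frame",
    "InterdependenceMatrix",
    "build_matrix",
    "ClusterResult",
    "cluster_matrix",
]


def hypergeom_sf(m: int, N: int, M: int, n: int) -> float:
    """Upper tail P(X >= m) of a hypergeometric(N, M, n) overlap.

    Returns 1.0 for m <= 0 and exactly 0.0 when m exceeds min(M, n), the
    largest achievable overlap.  Raises for inconsistent arguments.
    """
    for name, v in (("m", m), ("N", N), ("M", M), ("n", n)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    m, N, M, n = int(m), int(N), int(M), int(n)
    if N < 0 or M < 0 or n < 0:
        raise ValueError("N, M, n must be non-negative")
    if M > N or n > N:
        raise ValueError(f"regulon larger than universe: M={M}, n={n}, N={N}")
    if m <= 0:
        return 1.0
    hi = min(M, n)
    if m > hi:
        return 0.0
    lo = max(0, n - (N - M))  # smallest achievable overlap
    i = np.arange(max(m, lo), hi + 1)
    log_pmf = (
        gammaln(M + 1)
        - gammaln(i + 1)
        - gammaln(M - i + 1)
        + gammaln(N - M + 1)
        - gammaln(n - i + 1)
        - gammaln(N - M - (n - i) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    p = float(np.exp(logsumexp(log_pmf)))
    return min(1.0, max(0.0, p))


@dataclass(frozen=True)
class PairTestResult:
    """Overlap counts and survival-function p-value for one RBP pair."""

    rbp_a: str
    rbp_b: str
    m: int  # shared affected exons
    N: int  # combined unfiltered universe
    M: int  # affected exons of rbp_a
    n: int  # affected exons of rbp_b
    p_value: float
    significant: bool
    status: str  # 'tested' | 'no_overlap'

    @property
    def pair(self) -> frozenset:
        return frozenset((self.rbp_a, self.rbp_b))


def test_pair(
    reg_a: Regulon,
    reg_b: Regulon,
    alpha: float = 0.05,
    universe_mode: str = "union",
) -> PairTestResult:
    """Hypergeometric overlap test for one pair of regulons.

    ``universe_mode`` controls N: ``"union"`` (default) uses the union of
    the two deduplicated universes; ``"sum"`` adds the two sizes, for
    sensitivity analysis against the double-counting reading of a combined
    universe.
    """
    if reg_a.cell_line != reg_b.cell_line:
        raise ValueError("regulons come from different cell lines")
    if reg_a.policy != reg_b.policy:
        raise ValueError("regulons filtered under different policies")
    if universe_mode == "union":
        N = len(reg_a.universe | reg_b.universe)
    elif universe_mode == "sum":
        N = len(reg_a.universe) + len(reg_b.universe)
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    if N == 0:
        raise ValueError("empty combined universe")
    m = len(reg_a.affected & reg_b.affected)
    M = len(reg_a.affected)
    n = len(reg_b.affected)
    p = hypergeom_sf(m, N, M, n)
    return PairTestResult(
        rbp_a=reg_a.rbp_name,
        rbp_b=reg_b.rbp_name,
        m=m,
        N=N,
        M=M,
        n=n,
        p_value=p,
        significant=p <= alpha,
        status="no_overlap" if m == 0 else "tested",
    )


def all_pairs(
    regulons: Iterable[Regulon],
    alpha: float = 0.05,
    universe_mode: str = "union",
    correction: Optional[str] = None,
) -> list[PairTestResult]:
    """Test every unordered pair of regulons; k regulons -> k(k-1)/2 results.

    Results are ordered lexicographically by RBP name.  ``correction="bh"``
    re-declares significance with a Benjamini-Hochberg adjusted threshold
    (off by default: the primary analysis uses raw p <= alpha).
    """
    regs = sorted(regulons, key=lambda r: r.rbp_name)
    if len(regs) < 2:
        raise ValueError("need at least 2 regulons")
    names = [r.rbp_name for r in regs]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate RBP names: {dup}")
    results = [
        test_pair(a, b, alpha=alpha, universe_mode=universe_mode)
        for a, b in combinations(regs, 2)
    ]
    if correction is None:
        return results
    if correction != "bh":
        raise ValueError(f"unknown correction {correction!r}")
    q = false_discovery_control([r.p_value for r in results], method="bh")
    return [
        PairTestResult(
            r.rbp_a, r.rbp_b, r.m, r.N, r.M, r.n, r.p_value,
            significant=qi <= alpha, status=r.status,
        )
        for r, qi in zip(results, q)
    ]


def pairs_frame(results: Sequence[PairTestResult]) -> pd.DataFrame:
    cols = ["rbp_a", "rbp_b", "m", "N", "M", "n", "p_value", "significant", "status"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


@dataclass
class InterdependenceMatrix:
    """Row-normalised shared-regulation percentages between RBPs.

    ``row_totals[r]`` counts r's interdependently regulated exons (affected
    exons shared with at least one other RBP); ``cells.loc[r, c]`` is the
    percentage of those also affected by c (diagonal is NaN);
    ``per_rbp_interdependent_fraction[r]`` is the percentage of r's affected
    exons that are interdependently regulated.
    """

    rbp_order: list
    row_totals: dict
    cells: pd.DataFrame
    per_rbp_interdependent_fraction: dict
    n_affected: dict

    def rounded(self) -> pd.DataFrame:
        """Display form: percentages rounded to the nearest integer."""
        return self.cells.round(0)


def build_matrix(
    regulons: Iterable[Regulon],
    pair_results: Optional[Sequence[PairTestResult]] = None,
) -> InterdependenceMatrix:
    """Build the interdependence matrix from regulons.

    ``pair_results``, when given, must cover every pair and is checked for
    consistency with the recomputed overlaps.
    """
    regs = sorted(regulons, key=lambda r: r.rbp_name)
    order = [r.rbp_name for r in regs]
    by_name = {r.rbp_name: r for r in regs}
    if pair_results is not None:
        expected = {frozenset(p) for p in combinations(order, 2)}
        got = {r.pair for r in pair_results}
        if expected - got:
            raise ValueError(f"pair_results missing {len(expected - got)} pair(s)")
        for r in pair_results:
            m = len(by_name[r.rbp_a].affected & by_name[r.rbp_b].affected)
            if m != r.m:
                raise ValueError(
                    f"pair ({r.rbp_a}, {r.rbp_b}): stored m={r.m} != recomputed {m}"
                )

    # exons shared with at least one other RBP, per row RBP
    interdependent: dict[str, set] = {}
    for r in regs:
        others = set().union(*(o.affected for o in regs if o is not r)) if len(regs) > 1 else set()
        interdependent[r.rbp_name] = set(r.affected) & others

    row_totals = {name: len(s) for name, s in interdependent.items()}
    cells = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    for a in regs:
        tot = row_totals[a.rbp_name]
        for b in regs:
            if a is b:
                continue
            if tot == 0:
                cells.loc[a.rbp_name, b.rbp_name] = 0.0
            else:
                shared = len(a.affected & b.affected)
                cells.loc[a.rbp_name, b.rbp_name] = 100.0 * shared / tot
    frac = {
        name: (100.0 * row_totals[name] / by_name[name].n_affected
               if by_name[name].n_affected else 0.0)
        for name in order
    }
    return InterdependenceMatrix(
        rbp_order=order,
        row_totals=row_totals,
        cells=cells,
        per_rbp_interdependent_fraction=frac,
        n_affected={name: by_name[name].n_affected for name in order},
    )


@dataclass
class ClusterResult:
    """Complete-linkage dendrograms over matrix rows and columns."""

    row_linkage: np.ndarray
    row_order: list
    col_linkage: np.ndarray
    col_order: list


def cluster_matrix(matrix: InterdependenceMatrix) -> ClusterResult:
    """Hierarchically cluster the matrix (Euclidean distance, complete linkage).

    Rows enter in lexicographic RBP order, which fixes tie-breaking; the
    undefined diagonal is treated as 0.
    """
    cells = matrix.cells.fillna(0.0)
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    rows = cells.to_numpy()
    row_Z = hierarchy.linkage(rows, method="complete", metric="euclidean")
    row_order = [matrix.rbp_order[i] for i in hierarchy.leaves_list(row_Z)]
    if rows.shape[1] >= 2:
        col_Z = hierarchy.linkage(rows.T, method="complete", metric="euclidean")
        col_order = [cells.columns[i] for i in hierarchy.leaves_list(col_Z)]
    else:  # a single column cannot be clustered
        col_Z = np.empty((0, 4))
        col_order = list(cells.columns)
    return ClusterResult(row_Z, row_order, col_Z, col_order)
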