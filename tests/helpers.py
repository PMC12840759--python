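"""Independent oracles used by several test modules."""

from __future__ import annotations

from fractions import Fraction
from math import comb


def exact_hypergeom_sf(m: int, N: int, M: int, n: int) -> Fraction:
    """P(X >= m) by exact integer enumeration of the hypergeometric tail.

    Independent of the package's log-space implementation: sums
    C(M, i) * C(N - M, n - i) over the upper tail with exact rationals.
    """
    if m <= 0:
        return Fraction(1)
    hi = min(M, n)
    if m > hi:
        return Fraction(0)
    total = comb(N, n)
    tail = sum(comb(M, i) * comb(N - M, n - i) for i in range(m, hi + 1))
    return Fraction(tail, total)


def brute_force_complete_linkage(points: list[tuple]) -> list[float]:
    """Merge heights of complete-linkage clustering by direct simulation.

    Maintains clusters as index sets; at each step merges the pair whose
    *maximum* inter-point Euclidean distance is smallest.
    """
    import numpy as np

    pts = [np.asarray(p, dtype=float) for p in points]
    clusters = [{i} for i in range(len(pts))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    float(np.linalg.norm(pts[i] - pts[j]))
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return heights
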