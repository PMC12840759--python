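"""Significance filtering of knockdown tables into per-RBP regulons.

A *regulon* is the set of cassette exons whose inclusion changes
significantly when one RBP is knocked down.  Two stock policies mirror the
common analysis settings: a |delta PSI| > 0.15 rule for datasets without
per-event statistics, and |delta PSI| > 0.10 with FDR <= 0.05 where an FDR
column is available.  The delta-PSI bound is strict ("greater than"), the
FDR bound inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .io import ExonKey, KnockdownTable

__all__ = [
    "FilterPolicy",
    "Regulon",
    "ConfigurationError",
    "HELA_POLICY",
    "ENCODE_POLICY",
    "POLICIES",
    "apply_filter",
    "affected_counts",
]

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A filter policy cannot be applied to the given table."""


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds defining which events count as affected.

    ``min_abs_delta_psi`` is an exclusive lower bound on |delta PSI|
    (fraction units); ``max_fdr`` an inclusive upper bound, or ``None`` when
    the source has no event-level statistics.
    """

    name: str
    min_abs_delta_psi: float
    max_fdr: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_abs_delta_psi < 1:
            raise ValueError("min_abs_delta_psi must be in [0, 1)")
        if self.max_fdr is not None and not 0 <= self.max_fdr <= 1:
            raise ValueError("max_fdr must be in [0, 1]")


HELA_POLICY = FilterPolicy("hela", min_abs_delta_psi=0.15)
ENCODE_POLICY = FilterPolicy("encode", min_abs_delta_psi=0.10, max_fdr=0.05)
POLICIES = {p.name: p for p in (HELA_POLICY, ENCODE_POLICY)}


@dataclass(frozen=True)
class Regulon:
    """Affected-exon set of one knockdown under one filter policy.

    ``universe`` is every deduplicated exon in the unfiltered table — the
    sampling frame of the overlap test.  ``directions`` labels each affected
    exon 'increase' or 'decrease' by the sign of its delta PSI, and
    ``psi_control`` carries the wildtype inclusion level for downstream
    distribution analyses.
    """

    rbp_name: str
    cell_line: str
    policy: FilterPolicy
    affected: frozenset
    directions: Mapping[ExonKey, str]
    universe: frozenset
    psi_control: Mapping[ExonKey, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.psi_control is None:
            object.__setattr__(self, "psi_control", {})
        if not self.affected <= self.universe:
            raise ValueError("affected exons must be a subset of the universe")
        missing = self.affected - set(self.directions)
        if missing:
            raise ValueError(f"{len(missing)} affected exons lack a direction")

    @property
    def n_affected(self) -> int:
        return len(self.affected)


def apply_filter(table: KnockdownTable, policy: FilterPolicy) -> Regulon:
    """Filter a deduplicated table into a :class:`Regulon`.

    Rows with missing delta PSI contribute to neither the affected set nor
    the universe (logged).  Requesting an FDR bound on a table without FDR
    values raises :class:`ConfigurationError`.
    """
    frame = table.frame
    keys = table.keys()
    if keys.duplicated().any():
        raise ValueError(
            f"{table.rbp_name}: table contains duplicate exon keys; deduplicate first"
        )
    usable = frame["delta_psi"].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("%s: dropped %d rows with missing delta_psi", table.rbp_name, n_dropped)

    delta = frame["delta_psi"]
    passing = usable & (delta.abs() > policy.min_abs_delta_psi)
    if policy.max_fdr is not None:
        if frame["fdr"].isna().all() and len(frame):
            raise ConfigurationError(
                f"policy {policy.name!r} requires an FDR column but "
                f"{table.rbp_name} has none"
            )
        passing &= frame["fdr"].notna() & (frame["fdr"] <= policy.max_fdr)

    universe = frozenset(keys[usable])
    affected_keys = keys[passing]
    directions = {
        k: ("increase" if d > 0 else "decrease")
        for k, d in zip(affected_keys, delta[passing])
    }
    psi = {
        k: float(p)
        for k, p in zip(affected_keys, frame.loc[passing, "psi_control"])
        if not np.isnan(p)
    }
    return Regulon(
        rbp_name=table.rbp_name,
        cell_line=table.cell_line,
        policy=policy,
        affected=frozenset(affected_keys),
        directions=directions,
        universe=universe,
        psi_control=psi,
    )


def affected_counts(regulons: Iterable[Regulon]) -> pd.DataFrame:
    """Per-RBP affected-exon counts (one cell line, one policy)."""
    regulons = list(regulons)
    if not regulons:
        return pd.DataFrame(columns=["rbp_name", "n_affected"])
    policies = {r.policy for r in regulons}
    if len(policies) > 1:
        raise ValueError(f"mixed filter policies: {sorted(p.name for p in policies)}")
    lines = {r.cell_line for r in regulons}
    if len(lines) > 1:
        raise ValueError(f"mixed cell lines: {sorted(lines)}")
    rows = [(r.rbp_name, r.n_affected) for r in regulons]
    return pd.DataFrame(rows, columns=["rbp_name", "n_affected"]).sort_values(
        "rbp_name", ignore_index=True
    )
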