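"""Enhancer/silencer direction summaries per RBP and exon population.

A knockdown that *decreases* an exon's inclusion implies the RBP enhances
that exon's inclusion in the wildtype; an *increase* implies silencing.
Each RBP is summarised over three exon populations: all its affected exons
(total), those it alone affects (independent, multiplicity 1), and those
shared with other RBPs (interdependent, multiplicity >= 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .filtering import Regulon
from .multiplicity import MultiplicityProfile

__all__ = ["DirectionSummary", "summarize_direction", "direction_table", "POPULATIONS"]

POPULATIONS = ("total", "independent", "interdependent")


@dataclass(frozen=True)
class DirectionSummary:
    """Share of an RBP's exons gaining vs losing inclusion upon knockdown.

    Percentages are ``None`` when the population is empty.
    """

    rbp_name: str
    population: str
    n_exons: int
    pct_decrease: Optional[float]  # knockdown lowered inclusion -> wildtype enhancer
    pct_increase: Optional[float]  # knockdown raised inclusion -> wildtype silencer


def summarize_direction(
    regulon: Regulon, profile: MultiplicityProfile, population: str = "total"
) -> DirectionSummary:
    """Direction percentages of one RBP over one exon population.

    ``profile`` must be built from a regulon collection that includes this
    regulon, so multiplicity-1 membership identifies the independent set.
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; choose from {POPULATIONS}")
    missing = regulon.affected - set(profile.per_exon)
    if missing:
        raise ValueError(
            f"{regulon.rbp_name}: {len(missing)} affected exon(s) absent from the "
            "multiplicity profile; build it over the same regulon collection"
        )
    if population == "total":
        keys = regulon.affected
    elif population == "independent":
        keys = {k for k in regulon.affected if profile.per_exon[k].count == 1}
    else:
        keys = {k for k in regulon.affected if profile.per_exon[k].count >= 2}
    n = len(keys)
    if n == 0:
        return DirectionSummary(regulon.rbp_name, population, 0, None, None)
    n_dec = sum(1 for k in keys if regulon.directions[k] == "decrease")
    return DirectionSummary(
        rbp_name=regulon.rbp_name,
        population=population,
        n_exons=n,
        pct_decrease=100.0 * n_dec / n,
        pct_increase=100.0 * (n - n_dec) / n,
    )


def direction_table(
    regulons: Iterable[Regulon], profile: MultiplicityProfile
) -> pd.DataFrame:
    """All RBPs x all populations, as a tidy frame."""
    rows = []
    for reg in sorted(regulons, key=lambda r: r.rbp_name):
        for pop in POPULATIONS:
            s = summarize_direction(reg, profile, pop)
            rows.append(
                {
                    "rbp_name": s.rbp_name,
                    "population": s.population,
                    "n_exons": s.n_exons,
                    "pct_decrease": s.pct_decrease,
                    "pct_increase": s.pct_increase,
                }
            )
    return pd.DataFrame(rows)
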