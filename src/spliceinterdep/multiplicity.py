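"""Regulator multiplicity per exon, inclusion distributions and feature trends.

Pooling all knockdowns of one cell line, each affected exon is credited
with the number of RBPs whose knockdown changed its inclusion (its
*multiplicity*).  Exons of multiplicity 1 form the independently regulated
population; multiplicity >= 2 the interdependently regulated one.  This
module bins exons by multiplicity, summarises the direction consistency of
their responses, contrasts wildtype-inclusion distributions of the two
populations, and regresses per-bin mean exon features (splice-site
strength, conservation, lengths) on multiplicity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import FEATURE_COLUMNS, ExonKey
from .filtering import Regulon

__all__ = [
    "ExonMultiplicity",
    "MultiplicityProfile",
    "build_multiplicity",
    "direction_consistency",
    "InclusionDistributions",
    "inclusion_distributions",
    "FeatureTrend",
    "feature_trend",
    "bin_feature_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExonMultiplicity:
    """Per-exon pooled evidence: affecting RBPs, response signs, wildtype PSI."""

    rbps: tuple
    signs: tuple  # 'increase' / 'decrease', aligned with rbps
    psi_control: Optional[float]

    @property
    def count(self) -> int:
        return len(self.rbps)


@dataclass
class MultiplicityProfile:
    """Mapping of every affected exon to its :class:`ExonMultiplicity`."""

    per_exon: Mapping[ExonKey, ExonMultiplicity]
    cell_line: str = ""

    @property
    def bins(self) -> dict:
        """multiplicity -> list of exon keys (insertion-ordered)."""
        out: dict[int, list] = {}
        for key, e in self.per_exon.items():
            out.setdefault(e.count, []).append(key)
        return dict(sorted(out.items()))

    def counts_table(self) -> pd.DataFrame:
        bins = self.bins
        return pd.DataFrame(
            {"n_rbps": list(bins), "n_exons": [len(v) for v in bins.values()]}
        )

    def keys_with_count(self, predicate) -> set:
        return {k for k, e in self.per_exon.items() if predicate(e.count)}


def build_multiplicity(regulons: Iterable[Regulon]) -> MultiplicityProfile:
    """Pool regulons of one cell line into a per-exon multiplicity profile.

    Wildtype PSI is averaged across the source tables that report the exon
    (different control batches can disagree slightly; the mean is taken as
    the cell line's wildtype level).
    """
    regs = sorted(regulons, key=lambda r: r.rbp_name)
    lines = {r.cell_line for r in regs}
    if len(lines) > 1:
        raise ValueError(f"mixed cell lines: {sorted(lines)}")
    if len({r.policy for r in regs}) > 1:
        raise ValueError("mixed filter policies")
    acc: dict[ExonKey, list] = {}
    psis: dict[ExonKey, list] = {}
    for r in regs:
        for key in r.affected:
            acc.setdefault(key, []).append((r.rbp_name, r.directions[key]))
            if key in r.psi_control:
                psis.setdefault(key, []).append(r.psi_control[key])
    per_exon = {}
    for key, pairs in acc.items():
        rbps, signs = zip(*pairs)
        psi_vals = psis.get(key)
        per_exon[key] = ExonMultiplicity(
            rbps=rbps,
            signs=signs,
            psi_control=float(np.mean(psi_vals)) if psi_vals else None,
        )
    return MultiplicityProfile(per_exon=per_exon, cell_line=regs[0].cell_line if regs else "")


def direction_consistency(profile: MultiplicityProfile) -> pd.DataFrame:
    """Per-multiplicity-bin percentages of consistently vs variably responding exons.

    An exon is ``increase_only`` when every affecting RBP's knockdown raised
    its inclusion, ``decrease_only`` symmetrically, and ``both`` otherwise.
    Multiplicity-1 exons are never ``both``.
    """
    rows = []
    for count, keys in profile.bins.items():
        n = len(keys)
        classes = {"increase_only": 0, "decrease_only": 0, "both": 0}
        for key in keys:
            signs = set(profile.per_exon[key].signs)
            if signs == {"increase"}:
                classes["increase_only"] += 1
            elif signs == {"decrease"}:
                classes["decrease_only"] += 1
            else:
                classes["both"] += 1
        rows.append(
            {
                "n_rbps": count,
                "n_exons": n,
                "pct_increase_only": 100.0 * classes["increase_only"] / n,
                "pct_decrease_only": 100.0 * classes["decrease_only"] / n,
                "pct_both": 100.0 * classes["both"] / n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class InclusionDistributions:
    """Wildtype-PSI histograms of the independent vs interdependent populations."""

    bin_edges: np.ndarray
    independent_hist: np.ndarray
    interdependent_hist: np.ndarray
    independent_intermediate_fraction: float
    interdependent_intermediate_fraction: float
    intermediate_window: Tuple[float, float]
    n_independent: int
    n_interdependent: int

    def frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame(
            {
                "bin_mid": mid,
                "independent": self.independent_hist,
                "interdependent": self.interdependent_hist,
            }
        )


def inclusion_distributions(
    profile: MultiplicityProfile,
    intermediate_window: Tuple[float, float] = (0.35, 0.65),
    n_bins: int = 40,
) -> InclusionDistributions:
    """Contrast wildtype inclusion of multiplicity-1 vs multiplicity>=2 exons.

    Returns histograms on [0, 1] and, for each population, the fraction of
    exons whose wildtype PSI lies in the intermediate-inclusion window.
    Warns when fewer than 90% of exons carry a wildtype PSI; errors when
    none do.
    """
    indep, inter = [], []
    n_missing = 0
    for e in profile.per_exon.values():
        if e.psi_control is None:
            n_missing += 1
            continue
        (indep if e.count == 1 else inter).append(e.psi_control)
    total = len(profile.per_exon)
    if total and n_missing > 0.10 * total:
        warnings.warn(
            f"wildtype PSI missing for {n_missing}/{total} exons", stacklevel=2
        )
    if not indep and not inter:
        raise ValueError("no exons with wildtype PSI")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    lo, hi = intermediate_window

    def frac_mid(vals: list) -> float:
        if not vals:
            return float("nan")
        v = np.asarray(vals)
        return float(((v >= lo) & (v <= hi)).mean())

    return InclusionDistributions(
        bin_edges=edges,
        independent_hist=np.histogram(indep, bins=edges)[0],
        interdependent_hist=np.histogram(inter, bins=edges)[0],
        independent_intermediate_fraction=frac_mid(indep),
        interdependent_intermediate_fraction=frac_mid(inter),
        intermediate_window=intermediate_window,
        n_independent=len(indep),
        n_interdependent=len(inter),
    )


@dataclass
class FeatureTrend:
    """OLS fit of per-bin mean feature value on multiplicity."""

    feature: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    ci95: Tuple[float, float]
    n_bins: int
    reference: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "stderr": self.stderr,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n_bins": self.n_bins,
            "reference": self.reference,
        }


def bin_feature_summary(
    profile: MultiplicityProfile, features: pd.DataFrame
) -> pd.DataFrame:
    """Mean exon features per multiplicity bin.

    ``features`` is the frame returned by :func:`~spliceinterdep.io.read_feature_table`
    (indexed by exon key).  Exons absent from the feature table are dropped
    and logged; bins left empty after the join are omitted.
    """
    rows = []
    n_missing = 0
    for count, keys in profile.bins.items():
        present = [k for k in keys if k in features.index]
        n_missing += len(keys) - len(present)
        if not present:
            continue
        sub = features.loc[present]
        row = {"n_rbps": count, "n_exons": len(present)}
        for col in FEATURE_COLUMNS:
            row[col] = float(sub[col].mean())
        rows.append(row)
    if n_missing:
        log.info("feature table missing %d affected exon(s)", n_missing)
    return pd.DataFrame(rows)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares with t-based inference (df = n - 2)."""
    W = w / w.sum()
    xb = float((W * x).sum())
    yb = float((W * y).sum())
    sxx = float((w * (x - xb) ** 2).sum())
    sxy = float((w * (x - xb) * (y - yb)).sum())
    slope = sxy / sxx
    intercept = yb - slope * xb
    resid = y - (intercept + slope * x)
    df = len(x) - 2
    s2 = float((w * resid**2).sum()) / df if df > 0 else float("nan")
    stderr = float(np.sqrt(s2 / sxx))
    t = slope / stderr if stderr > 0 else float("inf")
    p = 2 * stats.t.sf(abs(t), df) if df > 0 else float("nan")
    syy = float((w * (y - yb) ** 2).sum())
    r2 = (sxy**2) / (sxx * syy) if syy > 0 else 0.0
    return slope, intercept, r2, p, stderr, df


def feature_trend(
    profile: MultiplicityProfile,
    features: pd.DataFrame,
    weighted: bool = False,
    reference_values: Optional[Mapping[str, float]] = None,
    min_bins: int = 3,
) -> dict:
    """Regress per-bin mean features on multiplicity; one fit per feature.

    The default fit is unweighted over bin means; ``weighted=True`` weights
    each bin by its exon count.  ``reference_values`` (e.g. genome-wide
    median splice-site scores) are echoed into the corresponding results.
    Raises when fewer than ``min_bins`` usable bins remain.
    """
    summary = bin_feature_summary(profile, features)
    if len(summary) < min_bins:
        raise ValueError(
            f"need >= {min_bins} multiplicity bins with feature coverage, "
            f"got {len(summary)}"
        )
    x = summary["n_rbps"].to_numpy(dtype=float)
    w = summary["n_exons"].to_numpy(dtype=float) if weighted else np.ones(len(summary))
    refs = dict(reference_values or {})
    out = {}
    for col in FEATURE_COLUMNS:
        y = summary[col].to_numpy(dtype=float)
        slope, intercept, r2, p, stderr, df = _wls(x, y, w)
        if np.allclose(y, y[0]):
            slope, r2, p = 0.0, 0.0, 1.0
        tcrit = stats.t.ppf(0.975, df) if df > 0 else float("nan")
        out[col] = FeatureTrend(
            feature=col,
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            p_value=p,
            stderr=stderr,
            ci95=(slope - tcrit * stderr, slope + tcrit * stderr),
            n_bins=len(summary),
            reference=refs.get(col),
        )
    return out
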