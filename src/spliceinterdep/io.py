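"""Reading, validating and writing skipped-exon differential-splicing tables.

A *skipped exon* (cassette exon) event is one row of an rMATS-style table:
the exon, its two flanking constitutive exons, and the inclusion level (PSI,
percent spliced in) in two conditions.  Internally all PSI values are
fractions in [0, 1] and the inclusion-level difference (delta PSI) follows
the convention *knockdown minus control*: a positive delta means the exon is
included more after the knockdown.

Tables arrive in several dialects (the package's canonical TSV, rMATS
``SE.MATS.JC``-style files with replicate PSI lists, percent-scaled
variants); a :class:`TableDialect` describes the column mapping and unit /
sign conventions and the reader normalises everything on the way in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExonKey",
    "SkippedExonRecord",
    "KnockdownTable",
    "TableDialect",
    "FormatError",
    "CANONICAL_DIALECT",
    "RMATS_SE_DIALECT",
    "DIALECTS",
    "register_dialect",
    "read_knockdown_table",
    "write_knockdown_table",
    "deduplicate",
    "read_feature_table",
    "write_feature_table",
    "FEATURE_COLUMNS",
]


class FormatError(ValueError):
    """A table violates its declared dialect or an internal invariant."""


class ExonKey(NamedTuple):
    """Identity of a cassette exon: chromosome, strand and exon coordinates.

    Flanking-exon coordinates are deliberately excluded so that the same
    exon reported with different flanking pairs collapses to one event.
    Coordinates are 0-based half-open.
    """

    chrom: str
    strand: str
    exon_start: int
    exon_end: int


@dataclass(frozen=True)
class SkippedExonRecord:
    """One cassette-exon event from a differential-splicing table."""

    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_es: int
    upstream_ee: int
    downstream_es: int
    downstream_ee: int
    psi_control: float
    psi_kd: float
    delta_psi: float
    fdr: Optional[float] = None

    @property
    def key(self) -> ExonKey:
        return ExonKey(self.chrom, self.strand, self.exon_start, self.exon_end)


#: canonical column order of the in-memory frame and the canonical TSV
CANONICAL_FIELDS = [
    "gene_id",
    "gene_symbol",
    "chrom",
    "strand",
    "exon_start",
    "exon_end",
    "upstream_es",
    "upstream_ee",
    "downstream_es",
    "downstream_ee",
    "psi_control",
    "psi_kd",
    "delta_psi",
    "fdr",
]

_KEY_FIELDS = ["chrom", "strand", "exon_start", "exon_end"]
_INT_FIELDS = [
    "exon_start",
    "exon_end",
    "upstream_es",
    "upstream_ee",
    "downstream_es",
    "downstream_ee",
]

#: header of the canonical on-disk TSV, one entry per canonical field
CANONICAL_HEADER = {
    "gene_id": "GeneID",
    "gene_symbol": "geneSymbol",
    "chrom": "chr",
    "strand": "strand",
    "exon_start": "exonStart_0base",
    "exon_end": "exonEnd",
    "upstream_es": "upstreamES",
    "upstream_ee": "upstreamEE",
    "downstream_es": "downstreamES",
    "downstream_ee": "downstreamEE",
    "psi_control": "PSI_control",
    "psi_kd": "PSI_kd",
    "delta_psi": "IncLevelDifference",
    "fdr": "FDR",
}


@dataclass(frozen=True)
class TableDialect:
    """How to interpret one differential-splicing table format.

    Parameters
    ----------
    columns:
        canonical field -> source column name.  For rMATS-style dialects the
        per-condition PSI columns hold comma-separated replicate lists; set
        ``replicate_lists=True`` and map ``psi_group1`` / ``psi_group2``
        instead of ``psi_control`` / ``psi_kd``.
    knockdown_minus_control:
        sign convention of the source delta-PSI column.  ``False`` means the
        source stores control minus knockdown and the reader flips the sign.
    knockdown_group:
        for replicate-list dialects, which PSI group (1 or 2) is the
        knockdown condition.
    psi_unit:
        ``"fraction"``, ``"percent"`` or ``"auto"`` (percent detected when
        any |value| exceeds 1).
    coord_base:
        0 or 1; 1-based starts are shifted down on read.
    """

    name: str
    columns: Mapping[str, str]
    knockdown_minus_control: bool = True
    knockdown_group: int = 1
    psi_unit: str = "auto"
    coord_base: int = 0
    replicate_lists: bool = False


CANONICAL_DIALECT = TableDialect(
    name="canonical",
    columns=dict(CANONICAL_HEADER),
    knockdown_minus_control=True,
    psi_unit="auto",
    coord_base=0,
)

RMATS_SE_DIALECT = TableDialect(
    name="rmats-se",
    columns={
        "gene_id": "GeneID",
        "gene_symbol": "geneSymbol",
        "chrom": "chr",
        "strand": "strand",
        "exon_start": "exonStart_0base",
        "exon_end": "exonEnd",
        "upstream_es": "upstreamES",
        "upstream_ee": "upstreamEE",
        "downstream_es": "downstreamES",
        "downstream_ee": "downstreamEE",
        "psi_group1": "IncLevel1",
        "psi_group2": "IncLevel2",
        "delta_psi": "IncLevelDifference",
        "fdr": "FDR",
    },
    knockdown_minus_control=True,  # IncLevelDifference = group1 - group2
    knockdown_group=1,
    psi_unit="fraction",
    coord_base=0,
    replicate_lists=True,
)

DIALECTS: dict[str, TableDialect] = {
    CANONICAL_DIALECT.name: CANONICAL_DIALECT,
    RMATS_SE_DIALECT.name: RMATS_SE_DIALECT,
}


def register_dialect(dialect: TableDialect) -> None:
    DIALECTS[dialect.name] = dialect


def dialect_from_mapping(spec: Mapping) -> TableDialect:
    """Build a dialect from a plain mapping (e.g. parsed YAML/JSON)."""
    known = {
        "name",
        "columns",
        "knockdown_minus_control",
        "knockdown_group",
        "psi_unit",
        "coord_base",
        "replicate_lists",
    }
    unknown = set(spec) - known
    if unknown:
        raise FormatError(f"unknown dialect keys: {sorted(unknown)}")
    return TableDialect(**spec)


@dataclass
class KnockdownTable:
    """All skipped-exon events of one RBP knockdown in one cell line.

    ``frame`` holds the canonical columns (:data:`CANONICAL_FIELDS`); the
    ``records`` property materialises :class:`SkippedExonRecord` objects for
    small-table use.
    """

    rbp_name: str
    rbp_family: str
    cell_line: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.rbp_name:
            raise ValueError("rbp_name must be non-empty")
        missing = [c for c in CANONICAL_FIELDS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"table frame missing canonical columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[SkippedExonRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            fdr = d.get("fdr")
            if fdr is not None and isinstance(fdr, float) and math.isnan(fdr):
                fdr = None
            out.append(
                SkippedExonRecord(
                    **{k: d[k] for k in CANONICAL_FIELDS if k != "fdr"}, fdr=fdr
                )
            )
        return out

    def keys(self) -> pd.Series:
        """One ExonKey per row, in row order."""
        f = self.frame
        return pd.Series(
            [
                ExonKey(c, s, int(a), int(b))
                for c, s, a, b in zip(
                    f["chrom"], f["strand"], f["exon_start"], f["exon_end"]
                )
            ],
            index=f.index,
        )

    @classmethod
    def from_records(
        cls,
        rbp_name: str,
        records: Sequence[SkippedExonRecord],
        rbp_family: str = "other",
        cell_line: str = "",
    ) -> "KnockdownTable":
        frame = pd.DataFrame(
            [
                {f: getattr(r, f) for f in CANONICAL_FIELDS}
                for r in records
            ],
            columns=CANONICAL_FIELDS,
        )
        if frame.empty:
            frame = _empty_frame()
        return cls(rbp_name, rbp_family, cell_line, frame)


def _empty_frame() -> pd.DataFrame:
    frame = pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_FIELDS})
    for c in _INT_FIELDS:
        frame[c] = frame[c].astype(np.int64)
    for c in ["psi_control", "psi_kd", "delta_psi", "fdr"]:
        frame[c] = frame[c].astype(float)
    return frame


_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}  # accept unicode minus


def _parse_replicate_mean(values: pd.Series, column: str) -> pd.Series:
    def one(v) -> float:
        parts = [p for p in str(v).split(",") if p not in ("", "NA", "nan")]
        if not parts:
            return float("nan")
        try:
            nums = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"unparseable PSI list in column {column!r}: {v!r}") from exc
        return float(np.mean(nums))

    return values.map(one)


def read_knockdown_table(
    path,
    dialect: TableDialect | str = CANONICAL_DIALECT,
    rbp_name: Optional[str] = None,
    rbp_family: str = "other",
    cell_line: str = "",
    psi_tolerance: float = 5e-3,
) -> KnockdownTable:
    """Parse one differential-splicing table into canonical form.

    PSI values are rescaled to fractions, coordinates to 0-based, and the
    delta-PSI sign normalised to knockdown-minus-control.  ``psi_tolerance``
    bounds the allowed discrepancy between the stated delta and the PSI
    difference (source files round PSIs).
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise FormatError(
                f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
            ) from None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    needed = set(dialect.columns.values())
    missing = needed - set(raw.columns)
    if missing:
        raise FormatError(
            f"{path.name}: missing mandatory column(s) {sorted(missing)} "
            f"for dialect {dialect.name!r}"
        )
    inv = {src: canon for canon, src in dialect.columns.items()}
    frame = raw[list(needed)].rename(columns=inv)

    # strand
    strands = frame["strand"].map(lambda s: _STRAND_ALIASES.get(str(s).strip()))
    if strands.isna().any():
        bad = frame["strand"][strands.isna()].unique()
        raise FormatError(f"{path.name}: unrecognised strand symbol(s) {list(bad)}")
    frame["strand"] = strands

    # coordinates
    for col in _INT_FIELDS:
        try:
            frame[col] = frame[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2  # header + 1-based
            raise FormatError(
                f"{path.name}: unparseable coordinate in column {col!r} at line {line}"
            ) from None
    if dialect.coord_base == 1:
        for col in ["exon_start", "upstream_es", "downstream_es"]:
            frame[col] = frame[col] - 1
    bad = frame["exon_start"] >= frame["exon_end"]
    if bad.any():
        line = int(frame.index[bad][0]) + 2
        raise FormatError(f"{path.name}: exon_start >= exon_end at line {line}")

    # PSI columns
    if dialect.replicate_lists:
        g1 = _parse_replicate_mean(frame.pop("psi_group1"), dialect.columns["psi_group1"])
        g2 = _parse_replicate_mean(frame.pop("psi_group2"), dialect.columns["psi_group2"])
        if dialect.knockdown_group == 1:
            frame["psi_kd"], frame["psi_control"] = g1, g2
        else:
            frame["psi_kd"], frame["psi_control"] = g2, g1
    else:
        frame["psi_control"] = pd.to_numeric(frame["psi_control"], errors="coerce")
        frame["psi_kd"] = pd.to_numeric(frame["psi_kd"], errors="coerce")
    frame["delta_psi"] = pd.to_numeric(frame["delta_psi"], errors="coerce")
    if "fdr" in frame.columns:
        frame["fdr"] = pd.to_numeric(frame["fdr"], errors="coerce")
    else:
        frame["fdr"] = np.nan

    # unit normalisation (percent -> fraction)
    unit = dialect.psi_unit
    if unit == "auto":
        vals = pd.concat(
            [frame["psi_control"].abs(), frame["psi_kd"].abs(), frame["delta_psi"].abs()]
        )
        unit = "percent" if (vals > 1.000001).any() else "fraction"
    if unit == "percent":
        for col in ["psi_control", "psi_kd", "delta_psi"]:
            frame[col] = frame[col] / 100.0

    # sign normalisation: internal convention is knockdown minus control
    if not dialect.knockdown_minus_control:
        frame["delta_psi"] = -frame["delta_psi"]
    if dialect.replicate_lists and dialect.knockdown_group == 2 and dialect.knockdown_minus_control:
        # source delta was group1 - group2 = control - kd; flip
        frame["delta_psi"] = -frame["delta_psi"]

    # consistency: delta = kd - control where both PSIs are present
    both = frame["psi_control"].notna() & frame["psi_kd"].notna() & frame["delta_psi"].notna()
    if both.any():
        diff = (frame.loc[both, "psi_kd"] - frame.loc[both, "psi_control"]) - frame.loc[
            both, "delta_psi"
        ]
        worst = diff.abs().max()
        if worst > psi_tolerance:
            line = int(diff.abs().idxmax()) + 2
            raise FormatError(
                f"{path.name}: delta_psi inconsistent with PSI difference "
                f"(|err|={worst:.4g} at line {line})"
            )

    out_of_range = frame["delta_psi"].abs() > 1 + 1e-9
    if out_of_range.any():
        line = int(frame.index[out_of_range][0]) + 2
        raise FormatError(f"{path.name}: |delta_psi| > 1 at line {line}")

    frame = frame.reindex(columns=CANONICAL_FIELDS)
    frame["gene_id"] = frame["gene_id"].astype(str)
    frame["gene_symbol"] = frame["gene_symbol"].astype(str)
    name = rbp_name or path.stem.split(".")[0]
    return KnockdownTable(name, rbp_family, cell_line, frame.reset_index(drop=True))


def write_knockdown_table(table: KnockdownTable, path) -> None:
    """Write a table in the canonical TSV dialect (fractions, 0-based)."""
    out = table.frame.reindex(columns=CANONICAL_FIELDS).rename(columns=CANONICAL_HEADER)
    out.to_csv(path, sep="\t", index=False, float_format="%.9g", na_rep="NA")


def deduplicate(table: KnockdownTable) -> KnockdownTable:
    """Collapse rows sharing an :class:`ExonKey` to the strongest record.

    Ties on |delta PSI| are broken by smallest FDR, then first occurrence.
    Idempotent; surviving rows keep their original order.
    """
    frame = table.frame
    if frame.empty:
        return table
    keys = table.keys()
    order = pd.DataFrame(
        {
            "_key": keys,
            "_abs": -frame["delta_psi"].abs().fillna(-np.inf),
            "_fdr": frame["fdr"].fillna(np.inf),
            "_pos": np.arange(len(frame)),
        }
    )
    best = (
        order.sort_values(["_abs", "_fdr", "_pos"], kind="mergesort")
        .groupby("_key", sort=False)["_pos"]
        .first()
    )
    keep = np.sort(best.to_numpy())
    return replace(table, frame=frame.iloc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# exon feature tables

FEATURE_COLUMNS = [
    "exon_length",
    "upstream_intron_length",
    "downstream_intron_length",
    "ss5_score",
    "ss3_score",
    "phylop",
]

FEATURE_HEADER = {
    "chrom": "chr",
    "strand": "strand",
    "exon_start": "exonStart_0base",
    "exon_end": "exonEnd",
    "exon_length": "exon_len",
    "upstream_intron_length": "up_intron_len",
    "downstream_intron_length": "down_intron_len",
    "ss5_score": "ss5_maxent",
    "ss3_score": "ss3_maxent",
    "phylop": "phylop",
}

_LENGTH_COLUMNS = ["exon_length", "upstream_intron_length", "downstream_intron_length"]


def read_feature_table(path) -> pd.DataFrame:
    """Read a per-exon feature TSV; returns a frame indexed by ExonKey.

    Columns: exon length, flanking intron lengths, MaxEnt-style 5'/3'
    splice-site scores, PhyloP conservation.  Duplicate exon keys and
    non-positive lengths are format errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t")
    inv = {src: canon for canon, src in FEATURE_HEADER.items()}
    missing = set(FEATURE_HEADER.values()) - set(raw.columns)
    if missing:
        raise FormatError(f"{path.name}: feature table missing column(s) {sorted(missing)}")
    frame = raw.rename(columns=inv)
    keys = [
        ExonKey(str(c), str(s), int(a), int(b))
        for c, s, a, b in zip(frame["chrom"], frame["strand"], frame["exon_start"], frame["exon_end"])
    ]
    dup = pd.Series(keys).duplicated()
    if dup.any():
        first = keys[int(np.flatnonzero(dup)[0])]
        raise FormatError(f"{path.name}: duplicated exon key {first}")
    for col in _LENGTH_COLUMNS:
        if (frame[col] <= 0).any():
            raise FormatError(f"{path.name}: non-positive {col}")
    index = pd.MultiIndex.from_tuples(keys, names=_KEY_FIELDS)
    out = frame.set_index(index)[FEATURE_COLUMNS]
    return out.astype(float)


def feature_index(keys) -> pd.MultiIndex:
    """MultiIndex over ExonKeys, as used by feature frames."""
    return pd.MultiIndex.from_tuples(keys, names=_KEY_FIELDS)


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_feature_table`."""
    out = features.reset_index().rename(columns=FEATURE_HEADER)
    out.to_csv(path, sep="\t", index=False, float_format="%.9g")
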