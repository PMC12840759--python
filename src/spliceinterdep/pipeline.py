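"""End-to-end orchestration: read -> dedup -> filter -> pairs -> summaries.

Every number written by the pipeline comes from the stage functions in the
other modules; this layer only sequences them, writes artifacts and records
a manifest (row counts and SHA-256 checksums) for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .config import RunConfig
from .context import detect_cross_regulation
from .direction import direction_table
from .filtering import apply_filter
from .interdependence import all_pairs, build_matrix, cluster_matrix, pairs_frame
from .io import KnockdownTable, deduplicate, read_feature_table, read_knockdown_table
from .multiplicity import (
    build_multiplicity,
    direction_consistency,
    feature_trend,
    inclusion_distributions,
)

__all__ = ["run_pipeline", "PipelineError", "load_tables"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


def load_tables(input_dir, dialect: str = "canonical", cell_line: str = "") -> list:
    """Read every ``*.tsv`` in a directory as one knockdown table per file."""
    paths = sorted(Path(input_dir).glob("*.tsv"))
    tables = []
    for p in paths:
        if p.name == "exon_features.tsv":
            continue
        tables.append(
            read_knockdown_table(p, dialect=dialect, cell_line=cell_line)
        )
    return tables


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_gene_map(path: Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    return {str(k): ([v] if isinstance(v, str) else list(v)) for k, v in raw.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the output manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}

    def emit(name: str, path: Path, n_rows: Optional[int]) -> None:
        artifacts[name] = {
            "path": str(path),
            "n_rows": n_rows,
            "sha256": _checksum(path),
        }

    def stage(name: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(name, str(exc)) from exc
        return wrap

    tables = stage("read")(load_tables, config.input_dir, config.dialect, config.cell_line)
    if len(tables) < 2:
        raise PipelineError("read", f"need >= 2 knockdown tables, found {len(tables)}")
    tables = [stage("deduplicate")(deduplicate, t) for t in tables]
    log.info("read %d tables", len(tables))

    regulons = [stage("filter")(apply_filter, t, config.filter_policy) for t in tables]
    counts = pd.DataFrame(
        {"rbp_name": [r.rbp_name for r in regulons], "n_affected": [r.n_affected for r in regulons]}
    ).sort_values("rbp_name", ignore_index=True)
    p = out / "affected_counts.tsv"
    counts.to_csv(p, sep="\t", index=False)
    emit("affected_counts", p, len(counts))

    results = stage("pairs")(
        all_pairs, regulons, alpha=config.alpha,
        universe_mode=config.universe_mode, correction=config.correction,
    )
    pf = pairs_frame(results)
    p = out / "pair_results.tsv"
    pf.to_csv(p, sep="\t", index=False, float_format="%.6g")
    emit("pair_results", p, len(pf))

    matrix = stage("matrix")(build_matrix, regulons, results)
    p = out / "interdependence_matrix.tsv"
    matrix.cells.to_csv(p, sep="\t", float_format="%.6g")
    emit("interdependence_matrix", p, len(matrix.cells))
    if len(matrix.rbp_order) >= 2:
        clust = stage("cluster")(cluster_matrix, matrix)
        p = out / "cluster_order.json"
        p.write_text(json.dumps({"rows": clust.row_order, "columns": clust.col_order}, indent=2))
        emit("cluster_order", p, None)

    profile = stage("multiplicity")(build_multiplicity, regulons)
    p = out / "multiplicity_histogram.tsv"
    profile.counts_table().to_csv(p, sep="\t", index=False)
    emit("multiplicity_histogram", p, len(profile.bins))
    p = out / "direction_consistency.tsv"
    direction_consistency(profile).to_csv(p, sep="\t", index=False, float_format="%.6g")
    emit("direction_consistency", p, len(profile.bins))

    dirs = stage("direction")(direction_table, regulons, profile)
    p = out / "direction_summary.tsv"
    dirs.to_csv(p, sep="\t", index=False, float_format="%.6g")
    emit("direction_summary", p, len(dirs))

    dist = stage("inclusion")(
        inclusion_distributions, profile, intermediate_window=config.intermediate_window
    )
    p = out / "inclusion_distributions.tsv"
    dist.frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
    emit("inclusion_distributions", p, len(dist.frame()))
    summary = {
        "n_pairs": len(results),
        "n_significant": sum(r.significant for r in results),
        "fraction_significant": (sum(r.significant for r in results) / len(results)),
        "intermediate_fraction_independent": dist.independent_intermediate_fraction,
        "intermediate_fraction_interdependent": dist.interdependent_intermediate_fraction,
    }

    if config.feature_table is not None:
        features = stage("features")(read_feature_table, config.feature_table)
        trends = stage("features")(
            feature_trend, profile, features, reference_values=config.reference_values
        )
        p = out / "feature_trends.json"
        p.write_text(json.dumps({k: v.to_dict() for k, v in trends.items()}, indent=2))
        emit("feature_trends", p, None)
    else:
        log.info("no feature table configured; feature stage skipped")

    if config.rbp_gene_map is not None:
        gene_map = stage("context")(_load_gene_map, config.rbp_gene_map)
        cross, auto = stage("context")(detect_cross_regulation, tables, gene_map)
        frame = pd.DataFrame(
            [
                {
                    "knocked_down_rbp": h.knocked_down_rbp,
                    "responding_rbp": h.responding_rbp,
                    "n_responding_exons": h.n_responding_exons,
                    "max_abs_delta_psi": h.max_abs_delta_psi,
                    "autoregulation": is_auto,
                }
                for hits, is_auto in ((cross, False), (auto, True))
                for h in hits
            ]
        )
        p = out / "cross_regulation.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        emit("cross_regulation", p, len(frame))

    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2))
    emit("summary", p, None)

    manifest = {
        "cell_line": config.cell_line,
        "policy": config.filter_policy.name,
        "alpha": config.alpha,
        "n_tables": len(tables),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
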