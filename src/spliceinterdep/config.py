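"""Run configuration: YAML loading with collected (non-fail-fast) validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .filtering import FilterPolicy, POLICIES
from .io import DIALECTS

__all__ = ["RunConfig", "validate_config", "ConfigValidationError"]


class ConfigValidationError(ValueError):
    def __init__(self, errors: list):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Everything one end-to-end analysis run needs."""

    input_dir: Path
    output_dir: Path
    dialect: str = "canonical"
    filter_policy: FilterPolicy = field(default_factory=lambda: POLICIES["hela"])
    alpha: float = 0.05
    universe_mode: str = "union"
    correction: Optional[str] = None
    intermediate_window: Tuple[float, float] = (0.35, 0.65)
    feature_table: Optional[Path] = None
    rbp_gene_map: Optional[Path] = None
    cell_line: str = "HeLa"
    seed: int = 0
    reference_values: dict = field(default_factory=dict)


def _parse_policy(raw, errors: list) -> FilterPolicy:
    default = POLICIES["hela"]
    if raw is None:
        return default
    if isinstance(raw, str):
        if raw not in POLICIES:
            errors.append(f"filter: unknown policy {raw!r}; registered: {sorted(POLICIES)}")
            return default
        return POLICIES[raw]
    if isinstance(raw, dict):
        try:
            return FilterPolicy(
                name=raw.get("name", "custom"),
                min_abs_delta_psi=float(raw["min_abs_delta_psi"]),
                max_fdr=(None if raw.get("max_fdr") is None else float(raw["max_fdr"])),
            )
        except KeyError as exc:
            errors.append(f"filter: missing key {exc}")
        except (TypeError, ValueError) as exc:
            errors.append(f"filter: {exc}")
        return default
    errors.append("filter: expected a policy name or mapping")
    return default


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; raises with *all* errors collected."""
    path = Path(path)
    errors: list[str] = []
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigValidationError([f"cannot read config: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigValidationError(["config root must be a mapping"])

    input_dir = raw.get("input_dir")
    if not input_dir:
        errors.append("input_dir: required")
    elif not Path(input_dir).is_dir():
        errors.append(f"input_dir: not a directory: {input_dir}")
    output_dir = raw.get("output_dir")
    if not output_dir:
        errors.append("output_dir: required")

    dialect = raw.get("dialect", "canonical")
    if dialect not in DIALECTS:
        errors.append(f"dialect: unknown {dialect!r}; registered: {sorted(DIALECTS)}")

    alpha = raw.get("alpha", 0.05)
    try:
        alpha = float(alpha)
        if not 0 < alpha < 1:
            errors.append("alpha: out of range (0, 1)")
    except (TypeError, ValueError):
        errors.append(f"alpha: not a number: {alpha!r}")
        alpha = 0.05

    universe_mode = raw.get("universe_mode", "union")
    if universe_mode not in ("union", "sum"):
        errors.append(f"universe_mode: must be 'union' or 'sum', got {universe_mode!r}")

    correction = raw.get("correction")
    if correction not in (None, "bh"):
        errors.append(f"correction: must be null or 'bh', got {correction!r}")

    window = raw.get("intermediate_window", [0.35, 0.65])
    try:
        lo, hi = float(window[0]), float(window[1])
        if not 0 <= lo < hi <= 1:
            errors.append("intermediate_window: need 0 <= low < high <= 1")
    except (TypeError, ValueError, IndexError):
        errors.append(f"intermediate_window: expected [low, high], got {window!r}")
        lo, hi = 0.35, 0.65

    feature_table = raw.get("feature_table")
    if feature_table is not None and not Path(feature_table).is_file():
        errors.append(f"feature_table: not a file: {feature_table}")
    gene_map = raw.get("rbp_gene_map")
    if gene_map is not None and not Path(gene_map).is_file():
        errors.append(f"rbp_gene_map: not a file: {gene_map}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer, got {seed!r}")
        seed = 0

    policy = _parse_policy(raw.get("filter"), errors)

    if errors:
        raise ConfigValidationError(errors)
    return RunConfig(
        input_dir=Path(input_dir),
        output_dir=Path(output_dir),
        dialect=dialect,
        filter_policy=policy,
        alpha=alpha,
        universe_mode=universe_mode,
        correction=correction,
        intermediate_window=(lo, hi),
        feature_table=None if feature_table is None else Path(feature_table),
        rbp_gene_map=None if gene_map is None else Path(gene_map),
        cell_line=str(raw.get("cell_line", "HeLa")),
        seed=seed,
        reference_values=dict(raw.get("reference_values", {})),
    )
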