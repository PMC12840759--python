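"""Shared study configuration for the numbered analysis drivers.

One synthetic compendium stands in for the real inputs: a HeLa-like base
line plus two ENCODE-like lines (fewer detected events, mostly different
regulated exons).  Regenerated deterministically from STUDY_SEED by every
driver, so each script runs standalone.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

from spliceinterdep.filtering import ENCODE_POLICY, HELA_POLICY, apply_filter
from spliceinterdep.io import deduplicate
from spliceinterdep.simulate import CellLineSpec, SyntheticConfig, generate

STUDY_SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"

LINE_POLICIES = {"HeLa": HELA_POLICY, "HepG2": ENCODE_POLICY, "K562": ENCODE_POLICY}


def study_config(seed: int = STUDY_SEED) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        cell_lines=[
            CellLineSpec("HeLa"),
            CellLineSpec("HepG2", resample_fraction=0.2, size_scale=0.5),
            CellLineSpec("K562", resample_fraction=0.2, size_scale=0.5),
        ],
    )


@lru_cache(maxsize=1)
def study_dataset(seed: int = STUDY_SEED):
    return generate(study_config(seed))


@lru_cache(maxsize=4)
def study_regulons(line: str = "HeLa", seed: int = STUDY_SEED):
    ds = study_dataset(seed)
    policy = LINE_POLICIES[line]
    return tuple(
        apply_filter(deduplicate(t), policy) for t in ds.tables[line].values()
    )


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
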