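from __future__ import annotations

import pytest

from spliceinterdep import SyntheticConfig, generate
from spliceinterdep.io import SkippedExonRecord


@pytest.fixture(scope="session")
def small_dataset():
    """14 RBPs over a 2000-exon universe: every multiplicity bin populated."""
    return generate(SyntheticConfig(seed=11, n_rbps=14, universe_size=2000))


@pytest.fixture(scope="session")
def small_regulons(small_dataset):
    return small_dataset.truth.regulons()


@pytest.fixture(scope="session")
def study_dataset():
    """Default study-scale scenario: 30 RBPs, 20k-exon universe."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture
def make_record():
    """Factory for records; override any field by keyword."""

    def _make(**kw) -> SkippedExonRecord:
        base = dict(
            gene_id="GENE00001",
            gene_symbol="G1",
            chrom="chr1",
            strand="+",
            exon_start=1000,
            exon_end=1200,
            upstream_es=500,
            upstream_ee=650,
            downstream_es=1500,
            downstream_ee=1650,
            psi_control=0.50,
            psi_kd=0.72,
            delta_psi=0.22,
            fdr=0.01,
        )
        base.update(kw)
        return SkippedExonRecord(**base)

    return _make
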