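from __future__ import annotations

import dataclasses

import pytest

from readxlate.config import (
    FixedSpan,
    PipelineConfig,
    QualityPolicy,
    ReadStructure,
    SegmentSpec,
    VariableSpec,
)
from readxlate.simulate import simulate_scrna


def scrna_structure_config(cell_len: int, umi_len: int, gene_len: int = 20) -> PipelineConfig:
    """Droplet-style source structure: cell+UMI on read 1, cDNA on read 2."""
    return PipelineConfig(
        (
            ReadStructure(
                "src",
                (
                    SegmentSpec("cell", 0, FixedSpan(0, cell_len)),
                    SegmentSpec("umi", 0, FixedSpan(cell_len, cell_len + umi_len)),
                    SegmentSpec("cdna", 1, FixedSpan(0, gene_len)),
                ),
            ),
        ),
        (
            VariableSpec("cellID", ("cell",), role="parental"),
            VariableSpec("umiID", ("umi",), role="local", parent="cellID"),
            VariableSpec("payload", ("cdna",)),
        ),
        QualityPolicy(),
    )


@pytest.fixture
def tiny_scrna(tmp_path):
    """Small error-free droplet library written to disk with its config."""
    sim = simulate_scrna(n_cells=8, n_genes=4, max_umis=4, seed=11)
    paths = sim.write(tmp_path / "fastq")
    return sim, paths


@pytest.fixture
def with_destinations():
    def _attach(cfg, destinations):
        return dataclasses.replace(cfg, destinations=tuple(destinations))

    return _attach
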