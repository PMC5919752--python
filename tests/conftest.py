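import dataclasses

import pytest

from peakscreen import PipelineConfig, SimulationConfig


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A scaled-down study for fast end-to-end tests."""
    return SimulationConfig(
        seed=11,
        chromosomes=(("chrI", 60_000),),
        n_genes=12,
        conditions=("S96,YPD", "S96,4NQO"),
        n_rna_replicates=2,
        n_chip_replicates=2,
        n_true_peaks=3,
        n_hyperchip=3,
        n_negative_peaks=2,
        rna_depth=200_000,
    )


@pytest.fixture
def small_pipeline_config(small_sim_config, tmp_path) -> PipelineConfig:
    return PipelineConfig(out_dir=str(tmp_path / "out"), seed=11,
                          simulation=small_sim_config)
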