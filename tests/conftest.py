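"""Shared fixtures: a small planted simulation reused across test modules."""

import dataclasses

import pytest

from chapvar import PipelineConfig, SimConfig
from chapvar.pipeline import run_expression_stage, run_motif_stage
from chapvar.synthetic import simulate_counts


def small_sim_config(**overrides) -> SimConfig:
    base = dict(n_strains=3, n_genes=150, n_replicates=3, n_tfs=4,
                targets_per_tf=10, promoter_len=150, motif_len=12, seed=42)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(sim=small_sim_config())


@pytest.fixture(scope="session")
def small_motif_stage(small_config):
    return run_motif_stage(small_config)


@pytest.fixture(scope="session")
def small_expression_stage(small_config, small_motif_stage):
    expt = simulate_counts(small_config.sim, small_motif_stage.truth)
    return run_expression_stage(small_config, expt)


@pytest.fixture()
def clean_sim_config():
    """Zero mutation rates: promoters identical across strains."""
    return small_sim_config(snp_rate=0.0, motif_variant_rate=0.0,
                            motif_loss_rate=0.0, expression_bm_sd=0.0)
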