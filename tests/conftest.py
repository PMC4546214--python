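"""Shared fixtures: one seeded default-scale pipeline run per session."""

import pytest

from xcidyn import pipeline as pl
from xcidyn import simulate as sim


@pytest.fixture(scope="session")
def default_config():
    cfg, analysis = pl.load_config(None, seed=1)
    return cfg, analysis


@pytest.fixture(scope="session")
def pipeline_run(default_config, tmp_path_factory):
    """Full simulate -> report run at the default study conditions."""
    cfg, analysis = default_config
    outdir = tmp_path_factory.mktemp("run_seed1")
    return pl.run_all(cfg, outdir, analysis), outdir


@pytest.fixture(scope="session")
def dataset(pipeline_run):
    return pipeline_run[0]["dataset"]


@pytest.fixture(scope="session")
def small_config():
    """Reduced gene count for fast CLI / IO round-trip checks."""
    return sim.SimulationConfig(seed=7, n_genes_x=120, n_genes_autosome=80)
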