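from types import SimpleNamespace

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coipnet import SimulationConfig, generate_interactome
from coipnet.pipeline import PipelineConfig, run_pipeline

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study (seed 1)."""
    outdir = tmp_path_factory.mktemp("default_run")
    sim = SimulationConfig(seed=1)
    config = PipelineConfig(outdir=str(outdir), seed=1, simulation=sim)
    report = run_pipeline(config)
    data = generate_interactome(sim)
    decisions = pd.read_csv(outdir / "filter_funnel.tsv", sep="\t")
    table = pd.read_csv(outdir / "differential.tsv", sep="\t")
    return SimpleNamespace(
        report=report, data=data, decisions=decisions, table=table, outdir=outdir
    )


@pytest.fixture()
def small_config():
    """Small, fast synthetic study for unit-level checks."""
    return SimulationConfig(n_proteins=120, seed=7)
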