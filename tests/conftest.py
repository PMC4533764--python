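import pytest
from hypothesis import HealthCheck, settings

from stressomics import pipeline, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> simulate.GeneratorConfig:
    """A single-stressor study small enough for per-module tests."""
    return simulate.GeneratorConfig(n_genes=120, seed=7, stressors=("BuOH",))


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config, small_genome):
    _genome, _ann, truth = small_genome
    return simulate.generate_expression(truth, small_config)


@pytest.fixture(scope="session")
def sim_run(small_config, tmp_path_factory):
    """Full pipeline run on written synthetic files (exercises all readers)."""
    outdir = tmp_path_factory.mktemp("simrun")
    cfg = pipeline.write_simulated_inputs(small_config, outdir / "inputs")
    result = pipeline.run_pipeline(cfg, outdir / "run")
    truth = simulate.read_truth(outdir / "inputs" / "truth.tsv")
    return {"config": cfg, "result": result, "truth": truth, "outdir": outdir}
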