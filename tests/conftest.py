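import pytest

from degnet.pipeline import bundle_config, run_pipeline
from degnet.synthetic_data import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default synthetic bundle (500 genes, 5 blocks) with its truth labels."""
    outdir = tmp_path_factory.mktemp("bundle")
    labels = generate_bundle(SimulationConfig(seed=11), outdir)
    return outdir, labels


@pytest.fixture(scope="session")
def pipeline_run(sim_bundle, tmp_path_factory):
    """A full pipeline run on the default bundle."""
    bundle, labels = sim_bundle
    outdir = tmp_path_factory.mktemp("run")
    run_pipeline(bundle_config(bundle, seed=11), outdir)
    return outdir, labels
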