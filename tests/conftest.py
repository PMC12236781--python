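import warnings

import pytest

from supersil.pipeline import PipelineConfig, run_pipeline
from supersil.simulate import TruthManifest, simulate_all

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def synthetic(tmp_path_factory):
    """Default synthetic epigenome (2 x 20 Mb, fixed seed) plus its truth."""
    outdir = tmp_path_factory.mktemp("synthetic")
    manifest = TruthManifest(seed=DEFAULT_SEED)
    truth = simulate_all(manifest, outdir)
    return manifest, truth, outdir


@pytest.fixture(scope="session")
def pipeline_run(synthetic, tmp_path_factory):
    """Full pipeline run over the default synthetic epigenome."""
    manifest, truth, indir = synthetic
    outdir = tmp_path_factory.mktemp("reports")
    config = PipelineConfig(input_dir=str(indir), output_dir=str(outdir),
                            seed=DEFAULT_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # expected unfillable-bin warnings
        reports = run_pipeline(config)
    return manifest, truth, reports, outdir
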