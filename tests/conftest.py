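import pytest

from kleptoscreen.pipeline import RunConfig, run_all
from kleptoscreen.simulate import FixtureConfig, simulate_study


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic study, shared across the session."""
    outdir = tmp_path_factory.mktemp("study")
    return simulate_study(FixtureConfig(seed=7), outdir)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """The full pipeline executed once on the shared synthetic study."""
    outdir = tmp_path_factory.mktemp("pipeline")
    indir = bundle.paths["genome.fasta"].parent
    manifest = run_all(RunConfig(input_dir=indir, output_dir=outdir))
    return outdir, manifest
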