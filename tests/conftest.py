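import pytest

from pbscore import pipeline


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """One full synthetic pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("synth_run")
    cfg = pipeline.RunConfig(mode="synthetic", seed=1, outdir=outdir)
    summary = pipeline.run_core_analysis(cfg)
    return cfg, summary
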