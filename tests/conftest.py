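import pytest

from rarescreen.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-patient synthetic corpus shared by read-only tests."""
    return generate_corpus(SynthConfig(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def pipeline_out(tmp_path_factory):
    """One full pipeline run on a 250-patient corpus, shared read-only."""
    from rarescreen.pipeline import PipelineConfig, run_all

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        out_dir=str(out), seed=11,
        synth={"n_patients": 250, "case_fraction": 0.02},
        k_partitions=5, k_review=25,
    )
    metrics = run_all(cfg)
    return cfg, metrics
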