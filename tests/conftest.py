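import pytest

from clonetrace import pipeline, simulate


@pytest.fixture(scope="session")
def small_run():
    """One deterministic desk-scale noise-free experiment, shared across
    tests that only read from it."""
    cfg = pipeline.PipelineConfig(
        seed=11,
        n_barcodes=50_000,
        n_cells_exposed=4_000,
        transduction_rate=0.018,
        stage_rates=(1.0,),
        read_config=simulate.ReadSimConfig(mean_umis=5.0, reads_per_umi_mean=5.0),
    )
    return pipeline.run_pipeline(cfg)
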