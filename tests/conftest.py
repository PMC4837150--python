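import pytest

from aatkit import pipeline, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.GeneratorConfig(
        n_chromosomes=2, chromosome_length=80_000, n_background_genes=20,
        subfamily_plan={"AAP": 6, "CAT": 5},
        tandem_arrays=(("chr1", 3, 0),),
        collinear_blocks=(("chr1", "chr2", 3, 0.2),),
        decoy_truncated=2, seed=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return synthetic.generate_genome(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default bundle: 189 planted family genes, 17 decoys."""
    return synthetic.generate_genome(synthetic.GeneratorConfig())


@pytest.fixture(scope="session")
def default_pipeline_result(default_bundle):
    return pipeline.run_pipeline(default_bundle)
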