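import pytest

from ricehnt.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small 12-sample experiment with all four planted classes."""
    config = SimConfig(
        n_transcripts=400,
        class_proportions={
            "null": 0.7,
            "concordant_equal": 0.1,
            "concordant_divergent": 0.1,
            "discordant": 0.1,
        },
        dispersion=0.01,
        seed=42,
    )
    counts, truth = simulate_experiment(config)
    return config, counts, truth
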