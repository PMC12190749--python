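import pytest

from markdyn.simulate import SimulationConfig, simulate_study


def small_config(**overrides) -> SimulationConfig:
    """A reduced study that keeps every structural feature of the default."""
    base = dict(
        seed=0,
        n_chroms=2,
        chrom_length=80_000,
        n_genes=60,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(seed=5))


@pytest.fixture(scope="session")
def noiseless_study():
    return simulate_study(
        small_config(
            seed=6,
            peak_dropout_prob=0.0,
            peak_jitter_sd=0.0,
            noise_peak_rate=0.0,
        )
    )
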