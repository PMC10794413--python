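import pytest

from fretflux import (
    RateMatrix,
    SimulationConfig,
    TriggerConfig,
    generate_trigger_dataset,
    hsp90_like_rates,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def db_ring() -> RateMatrix:
    """Detailed-balance Hsp90-like ring (long-lived 0/3, short-lived 1/2)."""
    return hsp90_like_rates(0.0)


@pytest.fixture(scope="session")
def driven_ring() -> RateMatrix:
    """Uniform ring driven to -2 k_BT."""
    from fretflux import uniform_ring_rates
    return uniform_ring_rates(-2.0)


@pytest.fixture(scope="session")
def small_dataset(db_ring):
    """Small detailed-balance dataset (20 traces x 150 frames)."""
    cfg = SimulationConfig(rates=db_ring, n_traces=20, n_frames=150, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def trigger_dataset():
    """Noisy trigger dataset at the default pattern (40 traces)."""
    cfg = TriggerConfig(n_traces=40, seed=7)
    return cfg, *generate_trigger_dataset(cfg)


@pytest.fixture(scope="session")
def clean_trigger_dataset():
    """Noise-free trigger dataset (10 traces)."""
    cfg = TriggerConfig(n_traces=10, noise_sd=0.0, seed=3)
    return cfg, *generate_trigger_dataset(cfg)
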