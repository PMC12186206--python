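import numpy as np
import pytest

from sanburden.synthetic_world import (
    MortalityEffectsConfig,
    SanitationTrendConfig,
    WorldConfig,
    generate_world,
)


@pytest.fixture(scope="session")
def small_world():
    """5 countries, 2000-2020, default stochastic regime."""
    return generate_world(WorldConfig(n_countries=5, year_start=2000,
                                      year_end=2020, seed=42))


@pytest.fixture(scope="session")
def noise_free_world():
    """Deterministic regime: no mortality noise, no cohort walk, no share noise."""
    cfg = WorldConfig(
        n_countries=3, year_start=2000, year_end=2020, seed=7,
        sanitation_trend=SanitationTrendConfig(logit_noise=0.0),
        mortality_effects=MortalityEffectsConfig(noise_scale=0.0, cohort_scale=0.0),
    )
    return generate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
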