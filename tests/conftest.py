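import numpy as np
import pandas as pd
import pytest

from lifegaps.synthetic import (
    CovariateEffects,
    SkewedNoise,
    SyntheticConfig,
    generate_population,
)
from lifegaps.indicators import attach_indicators
from lifegaps.covariates import attach_covariates


@pytest.fixture(scope="session")
def small_population():
    """A 3000-record synthetic population under default study conditions."""
    config = SyntheticConfig(n_individuals=3000, seed=101, missing_cell_frac=0.02)
    records, truth, life_table, panel = generate_population(config)
    return config, records, truth, life_table, panel


@pytest.fixture(scope="session")
def prepared_records(small_population):
    """Small population with indicators and covariates attached."""
    _, records, _, life_table, panel = small_population
    enriched = attach_indicators(records, life_table)
    return attach_covariates(enriched, panel)


@pytest.fixture(scope="session")
def csr_points():
    """Factory for complete-spatial-randomness point sets."""

    def make(n: int, seed: int, extent: float = 20_000.0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.uniform(0.0, extent, (n, 2))

    return make


def quiet_config(**overrides) -> SyntheticConfig:
    """Config with all planted effects, covariate effects and noise off."""
    base = dict(
        n_individuals=400,
        seed=7,
        cluster_effect_years=0.0,
        covariate_effects=CovariateEffects(0.0, 0.0, 0.0),
        skew_params=SkewedNoise(mean=0.0, sd=0.0),
        n_subsectors=25,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def make_quiet_config():
    return quiet_config
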