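import numpy as np
import pytest

from featureshy import (
    Extent,
    FeatureSpec,
    LandscapeConfig,
    SuppressionFunction,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def square_extent():
    return Extent(0.0, 0.0, 5000.0, 5000.0)


def recovery_landscape(seed: int, n_animals: int = 250, n_random: int = 2000) -> LandscapeConfig:
    """Dense fence-grid study area with a known hard 500 m avoidance threshold.

    Grid spacing 1100 m puts every point within 550 m of a fence, the regime
    in which the cumulative-curve convergence identifies the threshold.
    """
    return LandscapeConfig(
        extent=Extent(0.0, 0.0, 5000.0, 5000.0),
        feature_specs=(FeatureSpec(name="fence", kind="grid", spacing_m=1100.0),),
        n_animals=n_animals,
        n_random=n_random,
        avoidance_profile={"fence": SuppressionFunction(threshold_m=500.0, form="hard")},
        seed=seed,
    )
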