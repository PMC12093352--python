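import numpy as np
import pytest

from ldcm.forward import FrequencyGrid, predict_csd_batch
from ldcm.model import ModelVariant, default_priors, get_layout


@pytest.fixture(scope="session")
def variant2():
    """Small two-region variant used for fast inversion tests."""
    return ModelVariant(n_regions=2)


@pytest.fixture(scope="session")
def variant4():
    return ModelVariant(n_regions=4)


@pytest.fixture(scope="session")
def variant_full():
    return ModelVariant(dual_glutamate=True, regional_stl=True, n_regions=4)


@pytest.fixture(scope="session")
def coarse_grid():
    return FrequencyGrid(np.arange(2.0, 46.0, 2.0))


def draw_stable_theta(variant, seed, leadfield_sd=0.25, grid=None):
    """Prior-distributed parameters whose linearisation is stable."""
    layout = get_layout(variant)
    prior = default_priors(variant)
    sd = np.sqrt(prior.variances.copy())
    sd[layout.blocks["L"][0]] = leadfield_sd
    grid = grid or FrequencyGrid(np.arange(2.0, 46.0, 2.0))
    rng = np.random.default_rng(seed)
    for _ in range(50):
        theta = prior.mean + sd * rng.standard_normal(layout.n_params)
        _, stable = predict_csd_batch(theta[None], variant, grid)
        if stable.all():
            return theta
    raise RuntimeError("no stable draw found")


@pytest.fixture(scope="session")
def stable_theta2(variant2):
    return draw_stable_theta(variant2, seed=3)
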