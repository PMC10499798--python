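"""Shared fixtures: a small virtual-species world and a fitted mini-ensemble."""

import numpy as np
import pytest

from suitmap import brt, sampling, synthetic


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 tropical test world with ~250 presence cells."""
    return synthetic.default_world(seed=2, n_rows=60, n_cols=60, n_points=300)


@pytest.fixture(scope="session")
def fast_config():
    """Cheap boosting settings for unit tests (higher shrinkage, few trees)."""
    return brt.BRTConfig(learning_rate=0.05, tree_complexity=4,
                         bag_fraction=0.75, n_folds=5, step_size=50,
                         max_trees=150, base_seed=11)


@pytest.fixture(scope="session")
def small_presences(small_world):
    return sampling.grid_presences(small_world["points"], small_world["stack"])


@pytest.fixture(scope="session")
def small_draws(small_world, small_presences, fast_config):
    ref = sampling.bootstrap_reference(small_world["stack"], small_presences,
                                       fast_config, seed=5)
    cand = sampling.screen_background_candidates(ref, small_presences,
                                                 small_world["stack"])
    return sampling.draw_background(cand, len(small_presences), 3, base_seed=11)


@pytest.fixture(scope="session")
def small_ensemble(small_world, small_presences, small_draws, fast_config):
    return brt.fit_ensemble(small_presences, small_draws,
                            small_world["stack"], fast_config)


@pytest.fixture(scope="session")
def small_map(small_ensemble, small_world):
    return brt.ensemble_predict(small_ensemble, small_world["stack"])


@pytest.fixture(scope="session")
def toy_submodel():
    """A deterministic 5-tree model on a 200-row, 3-feature table."""
    rng = np.random.default_rng(42)
    import pandas as pd
    X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200),
                      "c": rng.normal(size=200)})
    logit = 2.5 * X["a"] + 1.0 * X["b"]
    y = (rng.random(200) < 1 / (1 + np.exp(-logit))).astype(int)
    cfg = brt.BRTConfig(learning_rate=0.3, tree_complexity=3,
                        bag_fraction=1.0, n_folds=2, step_size=5, max_trees=5,
                        min_obs_in_leaf=5)
    return brt.fit_brt(X, y, cfg, n_trees=5, seed=3, categorical=[])
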