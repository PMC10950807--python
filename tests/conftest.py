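import numpy as np
import pandas as pd
import pytest

from circuitrx import (
    MorfHyperparams,
    fit_morf,
    generate_fixture_resources,
    generate_synthetic_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-truth dataset small enough for per-test fits."""
    X, Y, truth = generate_synthetic_dataset(
        n_samples=150, n_kdt=12, n_circuits=3, drivers_per_circuit=3, seed=0
    )
    return X, Y, truth


@pytest.fixture(scope="session")
def small_model(small_dataset):
    X, Y, _ = small_dataset
    hp = MorfHyperparams(n_trees=40, max_depth=6, random_seed=0)
    return fit_morf(X.iloc[:100], Y.iloc[:100], hp)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Self-consistent miniature resource set on disk."""
    out = tmp_path_factory.mktemp("resources")
    env = generate_fixture_resources(
        out, n_kdt=12, n_circuits=3, n_drugs=6, n_samples=120, seed=0
    )
    return env.parent


@pytest.fixture(scope="session")
def fixture_env(fixture_dir):
    return fixture_dir / "disease.env"


def random_forest_instance(rng, n_features=None, n_bg=None, n_samples=25,
                           n_outputs=2, n_trees=3, depth=3):
    """A small random fitted forest plus background/explained points."""
    if n_features is None:
        n_features = int(rng.integers(2, 9))
    if n_bg is None:
        n_bg = int(rng.integers(2, 16))
    X = pd.DataFrame(
        rng.normal(size=(n_samples, n_features)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"g{j}" for j in range(n_features)],
    )
    beta = rng.normal(size=(n_features, n_outputs))
    Y = pd.DataFrame(
        X.to_numpy() @ beta + 0.2 * rng.normal(size=(n_samples, n_outputs)),
        index=X.index,
        columns=[f"c{k}" for k in range(n_outputs)],
    )
    hp = MorfHyperparams(
        n_trees=n_trees,
        max_depth=depth,
        max_features_per_split=max(1, n_features // 2),
        random_seed=int(rng.integers(0, 2**31 - 1)),
    )
    model = fit_morf(X, Y, hp)
    bg = rng.normal(size=(n_bg, n_features))
    x = rng.normal(size=n_features)
    return model, bg, x
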