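"""Shared fixtures: flow conditions and the session-scoped surrogate database."""

import warnings

import numpy as np
import pytest

from tribochar.flow_field import AIR, PipeGeometry, build_profile
from tribochar.surrogate_ann import (
    MinMaxNormalizer,
    SurrogateDataset,
    assign_splits,
    build_database,
    latin_hypercube_plan,
    train_ensemble,
)


def synthetic_dataset(n=120, seed=0, noise=0.02, constant=None):
    """Cheap analytic stand-in for a simulator-backed database.

    A smooth response over the six inputs plus Gaussian label noise; used
    where surrogate mechanics (splits, training, persistence) are under
    test rather than simulator fidelity.
    """
    plan = latin_hypercube_plan(n, seed=seed)
    x = plan.to_numpy(float)
    rng = np.random.default_rng(seed)
    if constant is None:
        xn = (x - x.min(0)) / (x.max(0) - x.min(0))
        y = 3.0 + 10.0 * xn[:, 0] * (1 - xn[:, 0]) + 4.0 * xn[:, 3] - 2.0 * xn[:, 4]
        y = y + noise * rng.standard_normal(n)
    else:
        y = np.full(n, float(constant))
    split = assign_splits(n, seed=seed)
    norm = MinMaxNormalizer.fit(x[split == "train"], y[split == "train"])
    return SurrogateDataset(
        features=plan, targets=y, split=split,
        target_sem=np.full(n, noise), normalizer=norm,
    )


@pytest.fixture(scope="session")
def headline_geometry():
    """1 m x 4.76 mm pipe used throughout the parameter studies."""
    return PipeGeometry(length=1.0, inner_diameter=4.76e-3)


@pytest.fixture(scope="session")
def headline_flow(headline_geometry):
    """Turbulent flow at 8.4 m/s mean air velocity in the headline pipe."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_profile(headline_geometry, AIR, 8.4, regime="turbulent")


@pytest.fixture(scope="session")
def database():
    """Full 197-point simulator-backed surrogate database (built once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_database(seed=123)


@pytest.fixture(scope="session")
def ensemble(database):
    """Default 30-member surrogate ensemble trained on the session database."""
    return train_ensemble(database, seed=123)
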