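"""Shared fixtures: a compact bivariate generator (one knot per response)
whose fits run in seconds, plus session-scoped fitted models reused across
test modules."""

import warnings

import numpy as np
import pytest

import splinemlm as sm
from splinemlm.synthetic_data import nearest_pd

# compact bivariate truth: weight/MAP-like scales, one knot each at week 20
SMALL_WEIGHT = sm.SplineSpec("weight", 8.0, (20.0,), 44.0)
SMALL_MAP = sm.SplineSpec("map", 8.0, (20.0,), 44.0)
_SMALL_G_RAW = np.array(
    [
        [119.6, -0.58, 0.04, 25.6, 0.39, -0.53],
        [-0.58, 0.050, 0.008, -0.11, 0.004, 0.010],
        [0.04, 0.008, 0.040, -0.02, 0.005, 0.008],
        [25.6, -0.11, -0.02, 36.6, -1.07, -0.28],
        [0.39, 0.004, 0.005, -1.07, 0.180, -0.035],
        [-0.53, 0.010, 0.008, -0.28, -0.035, 0.113],
    ]
)
SMALL_G = nearest_pd(_SMALL_G_RAW)[0]
SMALL_FIXED = {
    "weight": np.array([65.0, 0.35, 0.48]),
    "map": np.array([85.0, -0.2, 0.4]),
}


def small_generator(n_individuals: int, seed: int, **kwargs) -> sm.GeneratorSpec:
    return sm.GeneratorSpec(
        n_individuals=n_individuals,
        specs=(SMALL_WEIGHT, SMALL_MAP),
        fixed_effects=SMALL_FIXED,
        G_true=SMALL_G,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def example_specs():
    """The worked-example spline structure: weight knots 18/29, MAP knots
    18/29/36, baseline week 8, horizon week 44."""
    return (sm.WEIGHT_SPEC, sm.MAP_SPEC)


@pytest.fixture(scope="session")
def small_dataset():
    gspec = small_generator(300, seed=11)
    data, truth = sm.generate(gspec)
    return gspec, data, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    gspec, data, _ = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.fit(gspec.model_spec(), data)


@pytest.fixture(scope="session")
def small_restricted_fit(small_dataset):
    """Same data fitted under a precedence restriction (MAP change may not
    correlate with subsequent weight change)."""
    gspec, data, _ = small_dataset
    cset = sm.precedence((SMALL_WEIGHT, SMALL_MAP), "map", "weight")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.fit(gspec.model_spec(constraints=cset), data)


@pytest.fixture(scope="session")
def large_fit():
    """A larger sample (n=2500) of the compact design: the large-sample
    regime in which delta-method and simulation intervals should agree."""
    gspec = small_generator(2500, seed=11)
    data, _ = sm.generate(gspec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.fit(gspec.model_spec(), data)
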