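import numpy as np
import pytest

from empdisp import Behavior, ColonyMap, GrowthForcing, Theta
from empdisp.synthetic import generate_benchmark
from empdisp.types import circular_distance_matrix


def make_circular_map(
    n=5,
    circumference=1500.0,
    regions=None,
    K=None,
    n0=None,
):
    """Small evenly spaced circular colony network for unit tests."""
    arc = np.arange(n) * (circumference / n)
    dist = circular_distance_matrix(arc, circumference)
    if regions is None:
        regions = ["A"] * n
    if K is None:
        K = np.full(n, 1000.0)
    if n0 is None:
        n0 = np.full(n, 500.0)
    return ColonyMap(
        ids=[f"c{i}" for i in range(n)],
        region=np.asarray(regions, dtype=object),
        K=np.asarray(K, float),
        n0=np.asarray(n0, float),
        dist=dist,
        metric="circular",
        coords={"arc_km": arc, "circumference_km": circumference},
    )


def make_forcing(r, t0=2000, rc_star=None):
    r = np.atleast_2d(np.asarray(r, float))
    years = np.arange(t0, t0 + r.shape[1])
    return GrowthForcing(years=years, r=r, rc_star=rc_star)


def make_theta(d=400.0, pm=0.3, n_regions=1, behavior=Behavior.SEMI_INFORMED, mu_unknown=None):
    return Theta(
        d=d,
        pm=np.full(n_regions, pm),
        behavior=behavior,
        mu_unknown=mu_unknown or {},
    )


@pytest.fixture(scope="session")
def benchmark():
    """The default scaled-down benchmark dataset (seed 1), shared across tests."""
    return generate_benchmark(seed=1)
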