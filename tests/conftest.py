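import numpy as np
import pytest

from clmfca import (
    DemandPoint,
    Hospital,
    LandscapeConfig,
    TravelTimeMatrix,
    catchment_sets,
    choice_probabilities,
    generate_landscape,
)


@pytest.fixture
def symmetric_2x2():
    """Two demand points and two identical, equidistant hospitals.

    D = (100, 300), S = (10, 20); every pair 10 minutes apart, so all
    choice probabilities are 0.5 and every quantity is hand-computable.
    """
    demand = [
        DemandPoint("d1", 0.0, 0.0, 100.0),
        DemandPoint("d2", 10.0, 0.0, 300.0),
    ]
    hospitals = [
        Hospital("h1", 5.0, 5.0, 10.0, level="Low", urbanization="Metro", n_specialists=0),
        Hospital("h2", 5.0, -5.0, 20.0, level="Low", urbanization="Metro", n_specialists=0),
    ]
    tau = np.full((2, 2), 10.0)
    tt = TravelTimeMatrix(tau, ("d1", "d2"), ("h1", "h2"))
    return demand, hospitals, tt


@pytest.fixture
def single_pair():
    """One demand point (D=10) and one hospital (S=5), co-located."""
    demand = [DemandPoint("d1", 0.0, 0.0, 10.0)]
    hospitals = [Hospital("h1", 0.0, 0.0, 5.0)]
    tt = TravelTimeMatrix(np.zeros((1, 1)), ("d1",), ("h1",))
    return demand, hospitals, tt


@pytest.fixture(scope="session")
def small_landscape():
    """A seeded synthetic landscape with its catchments and probabilities."""
    config = LandscapeConfig(
        n_demand=60, n_hospitals=10, region_km=120.0, n_clusters=3, seed=11
    )
    demand, hospitals, tt = generate_landscape(config)
    catchments = catchment_sets(tt, 60.0)
    probs = choice_probabilities(demand, hospitals, tt, catchments)
    return demand, hospitals, tt, catchments, probs


def random_instance(rng, n_demand=10, n_hospitals=5, region=100.0):
    """A random small landscape built directly (no generator), for oracles."""
    demand = [
        DemandPoint(
            f"d{i}", rng.uniform(0, region), rng.uniform(0, region),
            float(rng.integers(50, 5000)),
        )
        for i in range(n_demand)
    ]
    hospitals = [
        Hospital(
            f"h{j}", rng.uniform(0, region), rng.uniform(0, region),
            float(rng.integers(5, 300)),
            level=rng.choice(["High", "Low"]),
            urbanization=rng.choice(["Metro", "City", "Rural"]),
            n_specialists=int(rng.integers(0, 10)),
        )
        for j in range(n_hospitals)
    ]
    times = rng.uniform(0.0, 90.0, size=(n_demand, n_hospitals))
    tt = TravelTimeMatrix(times, tuple(d.id for d in demand), tuple(h.id for h in hospitals))
    return demand, hospitals, tt
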