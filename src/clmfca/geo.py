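"""Spatial primitives: demand/supply points, travel-time matrices, catchments.

Demand locations are population-weighted centroids of areal units (the
toolkit never requires individual addresses); hospitals are point suppliers
with a capacity and the attributes the hospital-choice model uses. All
downstream travel costs are expressed in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088

HOSPITAL_LEVELS = ("High", "Low")
URBANIZATION_CLASSES = ("Metro", "City", "Rural")


@dataclass(frozen=True)
class DemandPoint:
    """A population centroid *i* carrying potential demand ``population``.

    Coordinates are planar kilometres by default; when travel times are
    synthesised with ``mode="haversine"``, ``x`` is longitude and ``y``
    latitude in degrees. ``zone_id`` is the areal unit used when scores are
    aggregated for comparison against revealed accessibility; it defaults to
    the point's own id (one zone per centroid).
    """

    id: str
    x: float
    y: float
    population: float
    zone_id: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"demand point {self.id!r}: non-finite coordinates")
        if not math.isfinite(self.population) or self.population < 0:
            raise ValueError(f"demand point {self.id!r}: population must be >= 0")

    @property
    def zone(self) -> str:
        return self.zone_id if self.zone_id is not None else self.id


@dataclass(frozen=True)
class Hospital:
    """A supply point *j* with capacity ``capacity`` (beds or providers).

    ``level`` is the care tier ({"High", "Low"}), ``urbanization`` the
    location class ({"Metro", "City", "Rural"}) and ``n_specialists`` the
    specialist head count — the three non-spatial covariates of the
    hospital-choice utility.
    """

    id: str
    x: float
    y: float
    capacity: float
    level: str = "Low"
    urbanization: str = "Metro"
    n_specialists: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"hospital {self.id!r}: non-finite coordinates")
        if not math.isfinite(self.capacity) or self.capacity <= 0:
            raise ValueError(f"hospital {self.id!r}: capacity must be > 0")
        if self.level not in HOSPITAL_LEVELS:
            raise ValueError(
                f"hospital {self.id!r}: level {self.level!r} not in {HOSPITAL_LEVELS}"
            )
        if self.urbanization not in URBANIZATION_CLASSES:
            raise ValueError(
                f"hospital {self.id!r}: urbanization {self.urbanization!r} "
                f"not in {URBANIZATION_CLASSES}"
            )
        if self.n_specialists < 0:
            raise ValueError(f"hospital {self.id!r}: n_specialists must be >= 0")


def _check_unique_ids(items: Iterable, kind: str) -> None:
    seen: set = set()
    for item in items:
        if item.id in seen:
            raise ValueError(f"duplicate {kind} id {item.id!r}")
        seen.add(item.id)


@dataclass(frozen=True)
class TravelTimeMatrix:
    """Dense |I| x |J| matrix of travel times tau_ij in minutes."""

    times: np.ndarray
    demand_ids: tuple[str, ...]
    hospital_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "demand_ids", tuple(self.demand_ids))
        object.__setattr__(self, "hospital_ids", tuple(self.hospital_ids))
        if times.ndim != 2 or times.shape != (len(self.demand_ids), len(self.hospital_ids)):
            raise ValueError(
                f"travel-time matrix shape {times.shape} does not match "
                f"{len(self.demand_ids)} demand ids x {len(self.hospital_ids)} hospital ids"
            )
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("travel times must be finite and >= 0")

    @property
    def n_demand(self) -> int:
        return len(self.demand_ids)

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_ids)

    def demand_index(self, demand_id: str) -> int:
        return self.demand_ids.index(demand_id)

    def hospital_index(self, hospital_id: str) -> int:
        return self.hospital_ids.index(hospital_id)


@dataclass(frozen=True)
class CatchmentStructure:
    """Reachability at a travel-time threshold.

    ``within[i, j]`` is True iff tau_ij <= threshold (closed boundary): the
    hospital is in the catchment J_i of demand point i, and equivalently i is
    in the hospital's catchment I_j.
    """

    threshold: float
    within: np.ndarray
    demand_ids: tuple[str, ...]
    hospital_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        within = np.asarray(self.within, dtype=bool)
        object.__setattr__(self, "within", within)
        object.__setattr__(self, "demand_ids", tuple(self.demand_ids))
        object.__setattr__(self, "hospital_ids", tuple(self.hospital_ids))
        if within.shape != (len(self.demand_ids), len(self.hospital_ids)):
            raise ValueError("catchment mask shape does not match id lists")

    @property
    def J(self) -> Mapping[str, frozenset[str]]:
        """Hospitals reachable from each demand point (J_i)."""
        h = np.asarray(self.hospital_ids, dtype=object)
        return {
            did: frozenset(h[self.within[i]])
            for i, did in enumerate(self.demand_ids)
        }

    @property
    def I(self) -> Mapping[str, frozenset[str]]:  # noqa: E743 - field notation
        """Demand points reaching each hospital (I_j)."""
        d = np.asarray(self.demand_ids, dtype=object)
        return {
            hid: frozenset(d[self.within[:, j]])
            for j, hid in enumerate(self.hospital_ids)
        }

    def empty_demand_catchments(self) -> tuple[str, ...]:
        """Demand points that cannot reach any hospital."""
        reach = self.within.any(axis=1)
        return tuple(d for d, r in zip(self.demand_ids, reach) if not r)

    def unreached_hospitals(self) -> tuple[str, ...]:
        """Hospitals outside every demand point's catchment."""
        reach = self.within.any(axis=0)
        return tuple(h for h, r in zip(self.hospital_ids, reach) if not r)


def _haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon, lat) degree arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def build_travel_time_matrix(
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    mode: str = "planar",
    speed_kmh: float = 60.0,
) -> TravelTimeMatrix:
    """Synthesise tau_ij = distance(i, j) / speed, in minutes.

    Straight-line travel at a constant speed stands in for road-network
    routing; a matrix of observed network times can be supplied instead via
    :func:`clmfca.io.read_travel_matrix_csv`.

    Parameters
    ----------
    mode
        ``"planar"`` — Euclidean distance on km coordinates (default for
        synthetic landscapes); ``"haversine"`` — great-circle distance on
        (lon, lat) degrees.
    speed_kmh
        Constant ground speed, must be positive.
    """
    if speed_kmh <= 0 or not math.isfinite(speed_kmh):
        raise ValueError("speed_kmh must be positive and finite")
    if mode not in ("planar", "haversine"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_unique_ids(demand, "demand")
    _check_unique_ids(hospitals, "hospital")

    dx = np.array([p.x for p in demand], dtype=float)
    dy = np.array([p.y for p in demand], dtype=float)
    hx = np.array([h.x for h in hospitals], dtype=float)
    hy = np.array([h.y for h in hospitals], dtype=float)

    if mode == "planar":
        dist_km = np.hypot(dx[:, None] - hx[None, :], dy[:, None] - hy[None, :])
    else:
        dist_km = _haversine_km(dx[:, None], dy[:, None], hx[None, :], hy[None, :])

    minutes = dist_km / speed_kmh * 60.0
    return TravelTimeMatrix(
        times=minutes,
        demand_ids=tuple(p.id for p in demand),
        hospital_ids=tuple(h.id for h in hospitals),
    )


def catchment_sets(tt: TravelTimeMatrix, threshold_min: float = 60.0) -> CatchmentStructure:
    """Threshold the travel-time matrix into the bipartite catchment sets.

    A pair is in-catchment when tau_ij <= threshold (closed boundary); empty
    catchments are allowed and surfaced by the structure's helpers.
    """
    if threshold_min <= 0 or not math.isfinite(threshold_min):
        raise ValueError("threshold_min must be positive and finite")
    return CatchmentStructure(
        threshold=float(threshold_min),
        within=tt.times <= threshold_min,
        demand_ids=tt.demand_ids,
        hospital_ids=tt.hospital_ids,
    )
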