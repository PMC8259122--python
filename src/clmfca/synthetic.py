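"""Synthetic demand/supply landscapes and choice-driven utilization.

The generator emulates the structure of a national obstetric-care system on
a square planar region at country scale: a few hundred areal-unit centroids
whose populations are log-normally skewed and concentrated in urban
clusters, a few dozen hospitals placed where the people are, urbanization
labels assigned from local population-density terciles, tier and specialist
counts drawn with urban areas more likely to host high-tier,
specialist-rich hospitals, and straight-line travel times.

Two structural features mirror real hospital markets and matter for any
comparison against revealed accessibility:

* supply concentrates super-linearly with population (placement weight is
  population**placement_pop_power): low-demand areas lose providers, so
  remote zones face genuine travel-time scarcity;
* capacity follows demand: each hospital's bed count is proportional to its
  expected patient volume under the hospital-choice model, times a
  lognormal occupancy disturbance — hospitals are sized to their markets
  rather than drawn independently of them.

Utilization is simulated from the conditional-logit probabilities, so
revealed behaviour (including bypassing a near hospital for a distant
attractive one) is emergent rather than scripted. All draws descend from a
single seed via spawned generator streams, so a config reproduces its
landscape exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .choice import DEFAULT_SPEC, ChoiceModelSpec, ChoiceProbabilityMatrix, hospital_features
from .geo import DemandPoint, Hospital, TravelTimeMatrix, build_travel_time_matrix
from .validation import UtilizationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Defaults are a desk-scale analogue of a national system: a 300 km
    square region with 5 urban clusters holding ~70% of 400 demand
    centroids, log-normal zone populations (rural median ~2.4k, urban
    ~5.4k, heavy right tail), and 60 hospitals — a ~7:1 demand-point to
    hospital ratio. ``beds_per_1000`` sets system-wide supply per expected
    patient; ``occupancy_log_sigma`` is the spread of hospital sizes around
    their market (log scale). ``zone_cell_km`` assigns each demand point a
    municipal-like square-grid zone for revealed-accessibility comparison;
    ``None`` keeps one zone per centroid.
    """

    n_demand: int = 400
    n_hospitals: int = 60
    region_km: float = 300.0
    n_clusters: int = 5
    cluster_sd_km: float = 10.0
    urban_fraction: float = 0.7
    pop_log_mean: float = 7.8
    pop_log_sigma: float = 1.1
    pop_urban_log_shift: float = 0.8
    placement_pop_power: float = 1.5
    hospital_jitter_km: float = 3.0
    density_radius_km: float = 15.0
    beds_per_1000: float = 8.0
    occupancy_log_sigma: float = 0.3
    specialist_mean_by_urbanization: Mapping[str, float] = field(
        default_factory=lambda: {"Metro": 6.0, "City": 3.0, "Rural": 1.0}
    )
    p_high_by_urbanization: Mapping[str, float] = field(
        default_factory=lambda: {"Metro": 0.30, "City": 0.15, "Rural": 0.05}
    )
    speed_kmh: float = 60.0
    zone_cell_km: float | None = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_demand < 1 or self.n_hospitals < 1:
            raise ValueError("n_demand and n_hospitals must be >= 1")
        for name in ("region_km", "cluster_sd_km", "pop_log_sigma", "beds_per_1000",
                     "density_radius_km", "speed_kmh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.occupancy_log_sigma < 0:
            raise ValueError("occupancy_log_sigma must be >= 0")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError("urban_fraction must lie in [0, 1]")
        if self.urban_fraction > 0 and self.n_clusters < 1:
            raise ValueError("urban_fraction > 0 requires at least one cluster")
        if self.zone_cell_km is not None and self.zone_cell_km <= 0:
            raise ValueError("zone_cell_km must be positive or None")

    def with_seed(self, seed: int) -> "LandscapeConfig":
        return replace(self, seed=seed)


def generate_landscape(
    config: LandscapeConfig,
    spec: ChoiceModelSpec = DEFAULT_SPEC,
) -> tuple[list[DemandPoint], list[Hospital], TravelTimeMatrix]:
    """Draw a full landscape (demand points, hospitals, travel times).

    Deterministic given ``config``. ``spec`` is the choice model used to
    size hospital capacities to their expected markets; it is normally the
    same coefficient set used later for scoring.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_pop, rng_site, rng_attr = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    r = config.region_km

    centers = rng_layout.uniform(0.15 * r, 0.85 * r, size=(max(config.n_clusters, 1), 2))
    n_urban = int(round(config.urban_fraction * config.n_demand))
    coords = np.empty((config.n_demand, 2))
    is_urban = np.zeros(config.n_demand, dtype=bool)
    if n_urban:
        which = rng_layout.integers(0, config.n_clusters, size=n_urban)
        coords[:n_urban] = centers[which] + rng_layout.normal(
            0.0, config.cluster_sd_km, size=(n_urban, 2)
        )
        is_urban[:n_urban] = True
    coords[n_urban:] = rng_layout.uniform(0.0, r, size=(config.n_demand - n_urban, 2))
    coords = np.clip(coords, 0.0, r)

    log_mu = np.where(is_urban, config.pop_log_mean + config.pop_urban_log_shift,
                      config.pop_log_mean)
    populations = np.round(rng_pop.lognormal(log_mu, config.pop_log_sigma))

    width = len(str(config.n_demand))
    demand = []
    for i in range(config.n_demand):
        zone = None
        if config.zone_cell_km is not None:
            cell = config.zone_cell_km
            zone = f"z{int(coords[i, 0] // cell):03d}_{int(coords[i, 1] // cell):03d}"
        demand.append(
            DemandPoint(
                id=f"d{i:0{width}d}",
                x=float(coords[i, 0]),
                y=float(coords[i, 1]),
                population=float(populations[i]),
                zone_id=zone,
            )
        )

    weight = populations.astype(float) ** config.placement_pop_power
    weight /= weight.sum()
    anchors = rng_site.choice(config.n_demand, size=config.n_hospitals, p=weight)
    sites = coords[anchors] + rng_site.normal(
        0.0, config.hospital_jitter_km, size=(config.n_hospitals, 2)
    )
    sites = np.clip(sites, 0.0, r)

    # local population mass -> urbanization terciles (Rural | City | Metro)
    dist = np.hypot(
        sites[:, 0:1] - coords[None, :, 0], sites[:, 1:2] - coords[None, :, 1]
    )
    density = (dist <= config.density_radius_km) @ populations
    cuts = np.quantile(density, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.array(["Rural", "City", "Metro"], dtype=object)
    urb = labels[np.searchsorted(cuts, density, side="right")]

    levels = []
    n_specs = []
    for j in range(config.n_hospitals):
        u = str(urb[j])
        levels.append("High" if rng_attr.random() < config.p_high_by_urbanization[u] else "Low")
        n_specs.append(int(rng_attr.poisson(config.specialist_mean_by_urbanization[u])))

    # size capacity to the hospital's expected market under the choice model
    # (utilities do not involve capacity, so this is a single pass)
    x = np.array(
        [
            [1.0 if lv == "High" else 0.0,
             1.0 if str(u) == "City" else 0.0,
             1.0 if str(u) == "Rural" else 0.0,
             float(ns)]
            for lv, u, ns in zip(levels, urb, n_specs)
        ]
    )
    beta = spec.as_array()
    tau = dist.T / config.speed_kmh * 60.0  # (n_demand, n_hospitals) minutes
    v = x @ beta[:4] + beta[4] * tau
    p = np.exp(v - v.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    expected_market = populations @ p
    caps = (
        expected_market * config.beds_per_1000 / 1000.0
        * np.exp(rng_attr.normal(0.0, config.occupancy_log_sigma, config.n_hospitals))
    )

    hwidth = len(str(config.n_hospitals))
    hospitals = [
        Hospital(
            id=f"h{j:0{hwidth}d}",
            x=float(sites[j, 0]),
            y=float(sites[j, 1]),
            capacity=float(max(1.0, round(caps[j]))),
            level=levels[j],
            urbanization=str(urb[j]),
            n_specialists=n_specs[j],
        )
        for j in range(config.n_hospitals)
    ]

    tt = build_travel_time_matrix(demand, hospitals, mode="planar",
                                  speed_kmh=config.speed_kmh)
    return demand, hospitals, tt


def simulate_utilization(
    probs: ChoiceProbabilityMatrix,
    demand: Sequence[DemandPoint],
    tt: TravelTimeMatrix,
    visits_per_capita: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> list[UtilizationRecord]:
    """Draw visit records from the choice probabilities.

    Each demand point generates Poisson(population x ``visits_per_capita``)
    visits, allocated across hospitals by a multinomial draw from its
    probability row; records carry the pair's travel time and the demand
    point's zone. The default rate treats a visit as any instance of usage
    (antenatal care included), not only deliveries. Demand points with an
    all-zero probability row (empty option set) yield no records and are
    logged. Pass the ``"global"`` choice-set probabilities when the records
    will feed TRI, so that revealed travel can exceed the catchment
    threshold as it does in observed data.
    """
    if visits_per_capita < 0:
        raise ValueError("visits_per_capita must be >= 0")
    if probs.demand_ids != tuple(p.id for p in demand) or probs.demand_ids != tt.demand_ids:
        raise ValueError("inputs disagree on demand ordering")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    records: list[UtilizationRecord] = []
    hospital_ids = probs.hospital_ids
    for i, point in enumerate(demand):
        row = probs.probs[i]
        total = row.sum()
        n_visits = int(rng.poisson(point.population * visits_per_capita))
        if n_visits == 0:
            continue
        if total <= 0:
            logger.info("demand point %s has an empty option set; no visits simulated",
                        point.id)
            continue
        counts = rng.multinomial(n_visits, row / total)
        for j in np.nonzero(counts)[0]:
            records.append(
                UtilizationRecord(
                    zone_id=point.zone,
                    hospital_id=hospital_ids[j],
                    visits=int(counts[j]),
                    tau_min=float(tt.times[i, j]),
                )
            )
    return records
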