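"""Floating catchment area metrics: clmFCA and the three classical benchmarks.

All four metrics share the two-stage FCA skeleton — form a supply-to-demand
ratio per hospital, then sum reachable hospitals' ratios per demand point —
and differ in how demand is apportioned to hospitals:

* clmFCA apportions demand by conditional-logit choice probabilities P_ij:
  R_j = S_j / sum_i D_i P_ij and A_i = sum_{j in J_i} R_j P_ij.
* 2SFCA counts the full population D_i at every reachable hospital.
* 3SFCA splits demand with a travel-time selection weight
  G_ij = W_ij / sum_k W_ik (Wan-style competition adjustment).
* M2SFCA applies the decay weight on both the demand and the supply side:
  A_i = sum_j S_j W_ij^2 / sum_k D_k W_kj, so measured access can fall
  below total supply when travel is costly.

Hospitals whose apportioned demand is exactly zero have an undefined ratio;
their capacity is reported as stranded supply and excluded from every score
rather than treated as infinite access.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .choice import ChoiceProbabilityMatrix
from .geo import CatchmentStructure, DemandPoint, Hospital, TravelTimeMatrix, catchment_sets

DECAY_FAMILIES = ("gaussian", "binary")


@dataclass(frozen=True)
class DecaySpec:
    """Travel-impedance weight W(tau) used by the 3SFCA/M2SFCA benchmarks.

    ``gaussian`` — W(tau) = exp(-tau^2 / b) with b chosen so that
    W(threshold) = ``floor_weight``, and W = 0 beyond the threshold;
    ``binary`` — 1 inside the catchment, 0 outside. W(0) = 1 and W is
    nonincreasing in either family.
    """

    family: str = "gaussian"
    threshold: float = 60.0
    floor_weight: float = 0.01

    def __post_init__(self) -> None:
        if self.family not in DECAY_FAMILIES:
            raise ValueError(f"decay family must be one of {DECAY_FAMILIES}")
        if self.threshold <= 0 or not math.isfinite(self.threshold):
            raise ValueError("decay threshold must be positive and finite")
        if self.family == "gaussian" and not (0.0 < self.floor_weight < 1.0):
            raise ValueError("floor_weight must lie in (0, 1)")


def decay_weight(tau_min, decay: DecaySpec):
    """Evaluate the decay weight at travel time(s) ``tau_min`` (minutes)."""
    tau = np.asarray(tau_min, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau_min must be >= 0")
    inside = tau <= decay.threshold
    if decay.family == "binary":
        w = inside.astype(float)
    else:
        b = decay.threshold**2 / math.log(1.0 / decay.floor_weight)
        w = np.where(inside, np.exp(-(tau**2) / b), 0.0)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class AccessibilityResult:
    """Per-demand-point accessibility A_i for one metric.

    ``scores`` are in raw supply-per-person units (beds per person here);
    ``ratios`` hold each hospital's supply-to-apportioned-demand ratio R_j,
    NaN where the hospital's demand is zero (stranded supply, listed in
    ``stranded_hospitals``). ``parameters`` echoes the settings that
    produced the result.
    """

    metric_name: str
    demand_ids: tuple[str, ...]
    scores: np.ndarray
    hospital_ids: tuple[str, ...]
    ratios: np.ndarray
    stranded_hospitals: tuple[str, ...] = ()
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        object.__setattr__(self, "demand_ids", tuple(self.demand_ids))
        object.__setattr__(self, "hospital_ids", tuple(self.hospital_ids))
        if self.scores.shape != (len(self.demand_ids),):
            raise ValueError("one score per demand point required")
        if np.any(self.scores < 0):
            raise ValueError("accessibility scores must be >= 0")

    def score_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.demand_ids), name=self.metric_name)

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        """Long-format scores; ``scale`` is display-only (e.g. 1e4)."""
        return pd.DataFrame(
            {
                "demand_id": list(self.demand_ids),
                "metric": self.metric_name,
                "score": self.scores * scale,
            }
        )


def _populations(demand: Sequence[DemandPoint]) -> np.ndarray:
    d = np.array([p.population for p in demand], dtype=float)
    if np.any(d < 0):
        raise ValueError("populations must be >= 0")
    return d


def _capacities(hospitals: Sequence[Hospital]) -> np.ndarray:
    s = np.array([h.capacity for h in hospitals], dtype=float)
    if np.any(s <= 0):
        raise ValueError("capacities must be > 0")
    return s


def _ratio_result(
    name: str,
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    scores: np.ndarray,
    capacity: np.ndarray,
    apportioned: np.ndarray,
    parameters: dict,
) -> AccessibilityResult:
    allocated = apportioned > 0
    ratios = np.full(len(hospitals), np.nan)
    ratios[allocated] = capacity[allocated] / apportioned[allocated]
    stranded = tuple(h.id for h, a in zip(hospitals, allocated) if not a)
    return AccessibilityResult(
        metric_name=name,
        demand_ids=tuple(p.id for p in demand),
        scores=scores,
        hospital_ids=tuple(h.id for h in hospitals),
        ratios=ratios,
        stranded_hospitals=stranded,
        parameters=parameters,
    )


def clmfca(
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    probs: ChoiceProbabilityMatrix,
    catchments: CatchmentStructure,
) -> AccessibilityResult:
    """Choice-model-based FCA.

    Step 1 (done upstream) yields P_ij; step 2 forms each hospital's ratio of
    capacity to expected demand, R_j = S_j / sum_i D_i P_ij; step 3 mixes the
    ratios back with the same probabilities, A_i = sum_{j in J_i} R_j P_ij.
    Under the catchment choice-set convention this is a proper mixture and
    total weighted access equals total allocated supply.
    """
    if probs.demand_ids != tuple(p.id for p in demand):
        raise ValueError("probability matrix inconsistent with demand ordering")
    if probs.hospital_ids != tuple(h.id for h in hospitals):
        raise ValueError("probability matrix inconsistent with hospital ordering")
    if catchments.demand_ids != probs.demand_ids or catchments.hospital_ids != probs.hospital_ids:
        raise ValueError("catchment structure inconsistent with probability matrix")

    d = _populations(demand)
    s = _capacities(hospitals)
    p = probs.probs
    expected_demand = d @ p  # sum_i D_i P_ij, per hospital
    allocated = expected_demand > 0
    r = np.zeros(len(hospitals))
    r[allocated] = s[allocated] / expected_demand[allocated]
    scores = (p * catchments.within) @ r  # step 3 sums over J_i only
    return _ratio_result(
        "clmFCA", demand, hospitals, scores, s, expected_demand,
        {"threshold_min": catchments.threshold, "choice_set": probs.choice_set},
    )


def two_sfca(
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    catchments: CatchmentStructure,
) -> AccessibilityResult:
    """Two-step FCA: full demand counted at every reachable hospital."""
    d = _populations(demand)
    s = _capacities(hospitals)
    within = catchments.within
    reachable_pop = within.T @ d
    allocated = reachable_pop > 0
    r = np.zeros(len(hospitals))
    r[allocated] = s[allocated] / reachable_pop[allocated]
    scores = within @ r
    return _ratio_result(
        "2SFCA", demand, hospitals, scores, s, reachable_pop,
        {"threshold_min": catchments.threshold},
    )


def three_sfca(
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    tt: TravelTimeMatrix,
    decay: DecaySpec = DecaySpec(),
) -> AccessibilityResult:
    """Three-step FCA with a travel-time selection (competition) weight.

    G_ij = W_ij / sum_k W_ik splits each demand point across its reachable
    hospitals; R_j = S_j / sum_i G_ij W_ij D_i; A_i = sum_j G_ij W_ij R_j.
    """
    d = _populations(demand)
    s = _capacities(hospitals)
    w = decay_weight(tt.times, decay)
    row_sum = w.sum(axis=1, keepdims=True)
    g = np.divide(w, row_sum, out=np.zeros_like(w), where=row_sum > 0)
    gw = g * w
    apportioned = gw.T @ d
    allocated = apportioned > 0
    r = np.zeros(len(hospitals))
    r[allocated] = s[allocated] / apportioned[allocated]
    scores = gw @ r
    return _ratio_result(
        "3SFCA", demand, hospitals, scores, s, apportioned,
        {"threshold_min": decay.threshold, "decay": decay},
    )


def m2sfca(
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    tt: TravelTimeMatrix,
    decay: DecaySpec = DecaySpec(),
) -> AccessibilityResult:
    """Modified 2SFCA: decay applied to both demand and supply sides.

    A_i = sum_j S_j W_ij^2 / sum_k D_k W_kj. Because W^2 <= W term-wise,
    total weighted access never exceeds total supply (sub-conservation),
    reflecting that suboptimally placed supply is partly lost to distance.
    """
    d = _populations(demand)
    s = _capacities(hospitals)
    w = decay_weight(tt.times, decay)
    weighted_pop = w.T @ d  # sum_k D_k W_kj
    allocated = weighted_pop > 0
    r = np.zeros(len(hospitals))
    r[allocated] = s[allocated] / weighted_pop[allocated]
    scores = (w**2) @ r
    return _ratio_result(
        "M2SFCA", demand, hospitals, scores, s, weighted_pop,
        {"threshold_min": decay.threshold, "decay": decay},
    )


def weighted_total_access(demand: Sequence[DemandPoint], result: AccessibilityResult) -> float:
    """sum_i D_i A_i — compare against total supply to audit conservation."""
    return float(_populations(demand) @ result.scores)


def compute_all(
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    tt: TravelTimeMatrix,
    probs: ChoiceProbabilityMatrix,
    threshold_min: float = 60.0,
    decay: DecaySpec | None = None,
) -> dict[str, AccessibilityResult]:
    """Convenience: all four metrics on one landscape, keyed by metric name."""
    decay = decay if decay is not None else DecaySpec(threshold=threshold_min)
    catchments = catchment_sets(tt, threshold_min)
    return {
        "clmFCA": clmfca(demand, hospitals, probs, catchments),
        "2SFCA": two_sfca(demand, hospitals, catchments),
        "3SFCA": three_sfca(demand, hospitals, tt, decay),
        "M2SFCA": m2sfca(demand, hospitals, tt, decay),
    }
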