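"""Revealed-accessibility validation: TRI and rank-correlation comparison.

The timely relevance index (TRI) of a zone is the share of its observed
hospital visits made to hospitals reachable within a travel-time threshold —
a revealed-accessibility measure. Potential accessibility scores are
aggregated to the same zones (population-weighted) and compared with TRI by
Spearman and Kendall tau-b rank correlations, since the two quantities live
on different scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo import DemandPoint
from .metrics import AccessibilityResult


class InsufficientDataError(ValueError):
    """Raised when fewer than 3 zones carry both a score and a TRI value."""


@dataclass(frozen=True)
class UtilizationRecord:
    """Observed visits from one zone to one hospital, with the pair's travel time."""

    zone_id: str
    hospital_id: str
    visits: int
    tau_min: float

    def __post_init__(self) -> None:
        if self.visits < 1:
            raise ValueError("visits must be >= 1")
        if self.tau_min < 0 or not math.isfinite(self.tau_min):
            raise ValueError("tau_min must be finite and >= 0")


def tri(records: Sequence[UtilizationRecord], threshold_min: float = 60.0) -> pd.Series:
    """Per-zone timely relevance index in [0, 1].

    TRI_z = (visits from z with tau <= threshold) / (all visits from z).
    Zones with no recorded visits are absent from the result (missing, not
    zero): with no observed utilization the index is undefined.
    """
    if threshold_min <= 0 or not math.isfinite(threshold_min):
        raise ValueError("threshold_min must be positive and finite")
    if not records:
        return pd.Series(dtype=float, name="TRI")
    frame = pd.DataFrame(
        {
            "zone": [r.zone_id for r in records],
            "visits": [r.visits for r in records],
            "timely": [r.visits if r.tau_min <= threshold_min else 0 for r in records],
        }
    )
    grouped = frame.groupby("zone", sort=True).sum()
    out = grouped["timely"] / grouped["visits"]
    out.name = "TRI"
    out.index.name = "zone"
    return out


def aggregate_scores_to_zones(
    result: AccessibilityResult, demand: Sequence[DemandPoint]
) -> pd.Series:
    """Population-weighted mean score per zone (plain mean if a zone's
    population is zero)."""
    ids = {p.id for p in demand}
    if set(result.demand_ids) != ids:
        raise ValueError("accessibility result does not cover the demand points")
    scores = result.score_series()
    frame = pd.DataFrame(
        {
            "zone": [p.zone for p in demand],
            "pop": [p.population for p in demand],
            "score": [scores[p.id] for p in demand],
        }
    )

    def _wmean(g: pd.DataFrame) -> float:
        w = g["pop"].to_numpy()
        return float(np.average(g["score"], weights=w)) if w.sum() > 0 else float(g["score"].mean())

    out = frame.groupby("zone", sort=True).apply(_wmean, include_groups=False)
    out.name = result.metric_name
    return out


@dataclass(frozen=True)
class ComparisonReport:
    """Rank agreement between potential accessibility metrics and TRI.

    ``correlations`` is indexed by metric with columns ``spearman`` and
    ``kendall``; ``zone_table`` holds the aligned per-zone values the
    coefficients were computed from. When a clmFCA result is among the
    inputs, ``differences`` holds each benchmark's zone-level excess over
    clmFCA and ``exceedance_counts`` the number of zones where the benchmark
    scores higher.
    """

    correlations: pd.DataFrame
    n_zones: int
    zone_table: pd.DataFrame
    differences: pd.DataFrame | None = None
    exceedance_counts: Mapping[str, int] | None = None


def rank_correlations(
    results: Sequence[AccessibilityResult],
    tri_by_zone: pd.Series | Mapping[str, float],
    demand: Sequence[DemandPoint],
) -> ComparisonReport:
    """Spearman and Kendall tau-b of each metric's zone scores against TRI.

    Scores are aggregated demand point -> zone by population-weighted mean;
    zones lacking a TRI value are dropped pairwise. Spearman uses average
    ranks for ties; Kendall is the tie-corrected tau-b. Fewer than 3
    overlapping zones raise :class:`InsufficientDataError`.
    """
    tri_series = pd.Series(tri_by_zone, dtype=float).dropna()
    zone_scores = {r.metric_name: aggregate_scores_to_zones(r, demand) for r in results}
    table = pd.DataFrame(zone_scores)
    table["TRI"] = tri_series
    table = table.dropna()
    if len(table) < 3:
        raise InsufficientDataError(
            f"only {len(table)} zones have both a score and a TRI value (need >= 3)"
        )

    rows = {}
    for name in zone_scores:
        rows[name] = {
            "spearman": float(stats.spearmanr(table[name], table["TRI"]).statistic),
            "kendall": float(stats.kendalltau(table[name], table["TRI"], variant="b").statistic),
        }
    correlations = pd.DataFrame(rows).T[["spearman", "kendall"]]

    differences = None
    exceedance = None
    if "clmFCA" in table.columns:
        bench = [c for c in zone_scores if c != "clmFCA"]
        if bench:
            differences = table[bench].sub(table["clmFCA"], axis=0)
            exceedance = {b: int((differences[b] > 0).sum()) for b in bench}
    return ComparisonReport(
        correlations=correlations,
        n_zones=len(table),
        zone_table=table,
        differences=differences,
        exceedance_counts=exceedance,
    )


@dataclass(frozen=True)
class ScoreDifferences:
    """Per-demand-point benchmark minus clmFCA differences."""

    differences: pd.Series
    exceedance_count: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def score_differences(
    benchmark: AccessibilityResult, clm: AccessibilityResult, n_bins: int = 20
) -> ScoreDifferences:
    """Benchmark - clmFCA score per demand point, with the count of points
    where the benchmark is strictly higher and histogram-ready bins."""
    if benchmark.demand_ids != clm.demand_ids:
        raise ValueError("results cover different demand points")
    diff = pd.Series(
        benchmark.scores - clm.scores,
        index=list(benchmark.demand_ids),
        name=f"{benchmark.metric_name}-{clm.metric_name}",
    )
    counts, edges = np.histogram(diff.to_numpy(), bins=n_bins)
    return ScoreDifferences(
        differences=diff,
        exceedance_count=int((diff > 0).sum()),
        bin_edges=edges,
        bin_counts=counts,
    )
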