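"""Readers and writers for the toolkit's plain-text interchange formats.

Tables are headed delimited text (CSV); the choice-model coefficients travel
as YAML or JSON keyed by coefficient name; point layers can additionally be
written as GeoJSON FeatureCollections. Floating-point output uses 10
significant digits so round-trips are lossless at test tolerance.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .choice import ChoiceModelSpec, ChoiceRecord
from .geo import DemandPoint, Hospital, TravelTimeMatrix
from .metrics import AccessibilityResult
from .validation import UtilizationRecord

FLOAT_FORMAT = "%.10g"

_COEF_KEYS = {
    "beta_lvh_high",
    "beta_urb_city",
    "beta_urb_rural",
    "beta_num",
    "beta_tau",
}


# ---------------------------------------------------------------- demand / hospitals

def write_demand_csv(demand: Sequence[DemandPoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in demand],
            "x": [p.x for p in demand],
            "y": [p.y for p in demand],
            "population": [p.population for p in demand],
            "zone_id": [p.zone for p in demand],
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_demand_csv(path: str | Path) -> list[DemandPoint]:
    frame = pd.read_csv(path, dtype={"id": str, "zone_id": str})
    points = []
    for row in frame.itertuples(index=False):
        zone = getattr(row, "zone_id", None)
        points.append(
            DemandPoint(
                id=str(row.id), x=float(row.x), y=float(row.y),
                population=float(row.population),
                zone_id=None if zone is None or pd.isna(zone) else str(zone),
            )
        )
    return points


def write_hospitals_csv(hospitals: Sequence[Hospital], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [h.id for h in hospitals],
            "x": [h.x for h in hospitals],
            "y": [h.y for h in hospitals],
            "capacity": [h.capacity for h in hospitals],
            "level": [h.level for h in hospitals],
            "urbanization": [h.urbanization for h in hospitals],
            "n_specialists": [h.n_specialists for h in hospitals],
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_hospitals_csv(path: str | Path) -> list[Hospital]:
    frame = pd.read_csv(path, dtype={"id": str})
    return [
        Hospital(
            id=str(row.id), x=float(row.x), y=float(row.y),
            capacity=float(row.capacity), level=str(row.level),
            urbanization=str(row.urbanization), n_specialists=int(row.n_specialists),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------- travel times

def write_travel_matrix_csv(tt: TravelTimeMatrix, path: str | Path) -> None:
    """First column the demand id, one further column per hospital id."""
    frame = pd.DataFrame(tt.times, columns=list(tt.hospital_ids))
    frame.insert(0, "demand_id", list(tt.demand_ids))
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_travel_matrix_csv(path: str | Path) -> TravelTimeMatrix:
    frame = pd.read_csv(path, dtype={"demand_id": str})
    demand_ids = tuple(frame.pop("demand_id"))
    return TravelTimeMatrix(
        times=frame.to_numpy(dtype=float),
        demand_ids=demand_ids,
        hospital_ids=tuple(str(c) for c in frame.columns),
    )


# ---------------------------------------------------------------- choice model

def write_choice_spec(spec: ChoiceModelSpec, path: str | Path) -> None:
    """Serialize the five named coefficients as YAML (or JSON by extension)."""
    path = Path(path)
    payload = {
        "beta_lvh_high": spec.beta_lvh_high,
        "beta_urb_city": spec.beta_urb_city,
        "beta_urb_rural": spec.beta_urb_rural,
        "beta_num": spec.beta_num,
        "beta_tau": spec.beta_tau,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def read_choice_spec(path: str | Path) -> ChoiceModelSpec:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    unknown = set(payload) - _COEF_KEYS
    if unknown:
        raise ValueError(f"unknown coefficient keys in {path}: {sorted(unknown)}")
    return ChoiceModelSpec(**payload)


def default_choice_spec() -> ChoiceModelSpec:
    """The packaged default coefficient set."""
    with resources.as_file(
        resources.files("clmfca.data").joinpath("coefficients_default.yaml")
    ) as p:
        return read_choice_spec(p)


def write_choice_records_csv(records: Sequence[ChoiceRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "demand_id": [r.demand_id for r in records],
            "chosen_hospital_id": [r.chosen_hospital_id for r in records],
            "option_ids": [";".join(r.option_ids) for r in records],
        }
    ).to_csv(path, index=False)


def read_choice_records_csv(path: str | Path) -> list[ChoiceRecord]:
    frame = pd.read_csv(path, dtype=str)
    return [
        ChoiceRecord(
            demand_id=row.demand_id,
            chosen_hospital_id=row.chosen_hospital_id,
            option_ids=tuple(row.option_ids.split(";")),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------- utilization / scores

def write_utilization_csv(records: Sequence[UtilizationRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "zone_id": [r.zone_id for r in records],
            "hospital_id": [r.hospital_id for r in records],
            "visits": [r.visits for r in records],
            "tau_min": [r.tau_min for r in records],
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_utilization_csv(path: str | Path) -> list[UtilizationRecord]:
    frame = pd.read_csv(path, dtype={"zone_id": str, "hospital_id": str})
    return [
        UtilizationRecord(
            zone_id=str(row.zone_id), hospital_id=str(row.hospital_id),
            visits=int(row.visits), tau_min=float(row.tau_min),
        )
        for row in frame.itertuples(index=False)
    ]


def write_scores_csv(result: AccessibilityResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"demand_id": str, "metric": str})


# ---------------------------------------------------------------- GeoJSON

def _feature(x: float, y: float, properties: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [x, y]},
        "properties": properties,
    }


def write_geojson_points(
    items: Sequence[DemandPoint] | Sequence[Hospital],
    path: str | Path,
    scores: dict[str, float] | None = None,
) -> None:
    """Write demand points or hospitals as a GeoJSON FeatureCollection.

    ``scores`` (id -> value) attaches an accessibility score property to
    each feature, for mapping in any GIS viewer.
    """
    features = []
    for item in items:
        if isinstance(item, DemandPoint):
            props = {"id": item.id, "population": item.population, "zone_id": item.zone}
        else:
            props = {
                "id": item.id, "capacity": item.capacity, "level": item.level,
                "urbanization": item.urbanization, "n_specialists": item.n_specialists,
            }
        if scores is not None:
            props["score"] = scores.get(item.id)
        features.append(_feature(item.x, item.y, props))
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2) + "\n"
    )


def read_geojson_points(path: str | Path) -> list[DemandPoint] | list[Hospital]:
    """Read a point FeatureCollection back into demand points or hospitals,
    deciding by the properties present."""
    payload = json.loads(Path(path).read_text())
    out: list = []
    for feat in payload["features"]:
        x, y = feat["geometry"]["coordinates"]
        props = feat["properties"]
        if "capacity" in props:
            out.append(
                Hospital(
                    id=str(props["id"]), x=float(x), y=float(y),
                    capacity=float(props["capacity"]), level=str(props["level"]),
                    urbanization=str(props["urbanization"]),
                    n_specialists=int(props["n_specialists"]),
                )
            )
        else:
            out.append(
                DemandPoint(
                    id=str(props["id"]), x=float(x), y=float(y),
                    population=float(props["population"]),
                    zone_id=props.get("zone_id"),
                )
            )
    return out
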