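"""Georeferenced sample points and GeoJSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

LABELS = ("soybean", "non_soybean", "cropland_unknown")
PROVENANCES = ("ground_survey", "generated")


@dataclass
class SamplePoint:
    """A survey or generated point with label and provenance."""

    id: str
    lon: float
    lat: float
    year: int
    label: str = "cropland_unknown"
    provenance: str = "generated"
    region: str = ""
    crop: str = ""  # generator truth, empty for real data

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"invalid coordinates ({self.lon}, {self.lat})")


def points_to_geojson(points: list[SamplePoint]) -> dict:
    """Build a GeoJSON FeatureCollection from sample points."""
    features = []
    for p in points:
        props = asdict(p)
        lon = props.pop("lon")
        lat = props.pop("lat")
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(points: list[SamplePoint], path: str | Path) -> None:
    Path(path).write_text(json.dumps(points_to_geojson(points), indent=1))


def read_geojson(path: str | Path) -> list[SamplePoint]:
    obj = json.loads(Path(path).read_text())
    points = []
    for feat in obj["features"]:
        lon, lat = feat["geometry"]["coordinates"]
        props = dict(feat["properties"])
        points.append(SamplePoint(lon=lon, lat=lat, **props))
    return points
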