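"""Study-region and biogeographic-slope polygons with GeoJSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

DOMAIN = "domain"
PACIFIC = "pacific"
CARIBBEAN = "caribbean"


@dataclass
class RegionSet:
    """The full study domain plus the two biogeographic slope polygons.

    The slopes partition the domain along the barrier ridge line: pacific is
    the western (low-x) side, caribbean the eastern side.
    """

    domain: BaseGeometry
    pacific: BaseGeometry
    caribbean: BaseGeometry

    def __getitem__(self, name: str) -> BaseGeometry:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(name) from None

    def slope_of_points(self, x, y) -> list[str]:
        """Slope names ('pacific'/'caribbean') containing at least one point."""
        from shapely.geometry import Point

        found = []
        for name in (PACIFIC, CARIBBEAN):
            poly = self[name]
            if any(poly.covers(Point(px, py)) for px, py in zip(x, y)):
                found.append(name)
        return found


def write_regions(path: str | Path, regions: RegionSet) -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(regions[name]),
        }
        for name in (DOMAIN, PACIFIC, CARIBBEAN)
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_regions(path: str | Path) -> RegionSet:
    fc = json.loads(Path(path).read_text())
    geoms = {}
    for feat in fc["features"]:
        geoms[feat["properties"]["name"]] = shape(feat["geometry"])
    missing = {DOMAIN, PACIFIC, CARIBBEAN} - set(geoms)
    if missing:
        raise ValueError(f"regions file missing polygons: {sorted(missing)}")
    return RegionSet(geoms[DOMAIN], geoms[PACIFIC], geoms[CARIBBEAN])
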