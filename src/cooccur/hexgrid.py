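"""Hexagonal sampling array, tiered presence aggregation and diversity maps.

Binary SDM cells (fine resolution) are aggregated into a coarse hexagonal
presence-absence matrix (PAM).  A hexagon counts as "present" for a species
when the fraction of its assigned SDM cells that are present clears a
tiered threshold: 70% when the hexagon holds at most 10 cells, 50% for 11-40
cells and 30% above 40 — small samples must be near-unanimous, large samples
may be patchy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec, Raster


@dataclass(frozen=True)
class TierRule:
    """Tiered cell-coverage rule for hexagon presence."""

    b1: int = 10
    b2: int = 40
    t1: float = 0.70
    t2: float = 0.50
    t3: float = 0.30

    def __post_init__(self) -> None:
        if not (self.t1 > self.t2 > self.t3):
            raise ValueError("thresholds must satisfy t1 > t2 > t3")
        if not (0 < self.b1 < self.b2):
            raise ValueError("breakpoints must satisfy 0 < b1 < b2")

    def threshold(self, n_cells: int) -> float:
        if n_cells <= self.b1:
            return self.t1
        if n_cells <= self.b2:
            return self.t2
        return self.t3

    def present(self, k: int, n: int) -> bool:
        """Presence of a hexagon with ``k`` of ``n`` assigned cells present.

        The comparison is inclusive (``k/n >= t``); ``n = 0`` means absence.
        """
        if n == 0:
            return False
        return k / n >= self.threshold(n)


@dataclass
class HexGrid:
    """Flat-top hexagon lattice clipped to a study region.

    ``polygons`` are the full lattice hexagons (a partition of the plane,
    used for cell assignment); ``clipped`` are their intersections with the
    region (used for areas and map export).  Ids are stable for a fixed
    region and target area.
    """

    ids: list[str]
    polygons: list[Polygon]
    clipped: list[BaseGeometry]
    target_area_km2: float
    region: BaseGeometry = None

    @property
    def centroid_spacing(self) -> float:
        """Nearest-centroid distance: sqrt(2 A / sqrt(3)) for area A."""
        return float(np.sqrt(2.0 * self.target_area_km2 / np.sqrt(3.0)))

    def __len__(self) -> int:
        return len(self.ids)


def build_hex_grid(region: BaseGeometry, target_area_km2: float = 164.8) -> HexGrid:
    """Tile ``region`` with flat-top hexagons of the given full-cell area.

    The lattice is anchored at the region bounding box's lower-left corner;
    hexagons that intersect the region (with positive overlap area) are
    retained, ordered by (column, row) which makes ids deterministic.
    """
    if region.is_empty or region.area <= 0:
        raise ValueError("degenerate study region")
    if region.area < target_area_km2:
        raise ValueError("region smaller than one hexagon")
    # flat-top hexagon with side s: area = (3 sqrt(3) / 2) s^2
    s = float(np.sqrt(2.0 * target_area_km2 / (3.0 * np.sqrt(3.0))))
    dx = 1.5 * s
    dy = np.sqrt(3.0) * s
    xmin, ymin, xmax, ymax = region.bounds

    ids, polys, clips = [], [], []
    ncol = int(np.ceil((xmax - xmin) / dx)) + 2
    nrow = int(np.ceil((ymax - ymin) / dy)) + 2
    for col in range(-1, ncol):
        cx = xmin + col * dx
        y_off = 0.5 * dy if col % 2 else 0.0
        for row in range(-1, nrow):
            cy = ymin + row * dy + y_off
            hexagon = Polygon(
                [
                    (cx + s, cy),
                    (cx + 0.5 * s, cy + 0.5 * dy),
                    (cx - 0.5 * s, cy + 0.5 * dy),
                    (cx - s, cy),
                    (cx - 0.5 * s, cy - 0.5 * dy),
                    (cx + 0.5 * s, cy - 0.5 * dy),
                ]
            )
            inter = hexagon.intersection(region)
            if inter.area > 1e-9:
                ids.append(f"h{len(ids):04d}")
                polys.append(hexagon)
                clips.append(inter)
    return HexGrid(ids, polys, clips, target_area_km2, region)


def map_cells_to_hexagons(grid_spec: GridSpec, grid: HexGrid) -> np.ndarray:
    """Assign each raster cell (by centroid) to a hexagon.

    Returns an (ny, nx) int array of hexagon indices, -1 for cells outside
    every hexagon.  A centroid exactly on a shared edge (measure-zero; does
    not occur for half-integer centroids against irrational hexagon edges)
    goes to the lowest-id covering hexagon, a deterministic convention.
    """
    X, Y = grid_spec.centroids()
    pts = shapely.points(X.ravel(), Y.ravel())
    tree = shapely.STRtree(pts)
    assignment = np.full(X.size, -1, dtype=int)
    # iterate hexagons (few) over points (many); lowest id wins ties
    for h in range(len(grid) - 1, -1, -1):
        idx = tree.query(grid.polygons[h], predicate="covers")
        assignment[idx] = h
    return assignment.reshape(grid_spec.shape)


def aggregate_presence(
    sdm: Raster, assignment: np.ndarray, rule: TierRule = TierRule(),
    n_hex: int | None = None, valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-hexagon binary presence from a binary SDM under the tier rule.

    ``valid_mask`` marks the modeled (domain) cells forming the denominator;
    it defaults to the SDM's own non-NODATA cells.  Passing the domain mask
    makes species whose rasters were clipped to an accessible area count the
    clipped-away cells as absences, which keeps constrained-mode presence a
    subset of neutral-mode presence.  A hexagon with no denominator cells
    (including hexagons holding no raster cells at all) is absent.
    """
    if assignment.shape != sdm.values.shape:
        raise ValueError("assignment does not match SDM geometry")
    if n_hex is None:
        n_hex = int(assignment.max()) + 1
    if valid_mask is None:
        valid_mask = sdm.valid_mask
    valid = (assignment >= 0) & valid_mask
    a = assignment[valid]
    n = np.bincount(a, minlength=n_hex)
    k = np.bincount(a, weights=(sdm.values[valid] == 1), minlength=n_hex).astype(int)
    thresholds = np.array([rule.threshold(int(m)) if m else np.inf for m in n])
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    return ((n > 0) & (frac >= thresholds)).astype(np.uint8)


@dataclass
class PAM:
    """Binary species x hexagon presence-absence matrix."""

    matrix: np.ndarray  # (n_species, n_hex) uint8
    species: list[str]
    hex_ids: list[str]
    season: str = ""
    mode: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.shape != (len(self.species), len(self.hex_ids)):
            raise ValueError("PAM shape does not match species/hexagon ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.hex_ids)

    def sites_matrix(self) -> np.ndarray:
        """Transposed (sites x species) view used by the motif decomposition."""
        return self.matrix.T.astype(float)


def build_pam(
    sdms: dict[str, Raster],
    grid: HexGrid,
    assignment: np.ndarray,
    rule: TierRule = TierRule(),
    season: str = "",
    mode: str = "",
    valid_mask: np.ndarray | None = None,
) -> PAM:
    """Stack per-species presence vectors into a PAM (species sorted).

    ``valid_mask`` (the domain's modeled cells) is forwarded to
    :func:`aggregate_presence` so all species share one denominator.
    """
    species = sorted(sdms)
    shape = None
    rows = []
    for sp in species:
        sdm = sdms[sp]
        if shape is None:
            shape = sdm.values.shape
        elif sdm.values.shape != shape:
            raise ValueError(f"SDM geometry mismatch for species {sp}")
        rows.append(
            aggregate_presence(
                sdm, assignment, rule, n_hex=len(grid), valid_mask=valid_mask
            )
        )
    return PAM(np.array(rows), species, list(grid.ids), season=season, mode=mode)


def diversity_maps(pam: PAM) -> pd.DataFrame:
    """Per-hexagon richness and mean range size of the species present.

    Range size is a species' total occupied-hexagon count; the mean over the
    species present is NaN (undefined) where richness is 0.
    """
    if pam.matrix.size == 0:
        raise ValueError("empty PAM")
    richness = pam.matrix.sum(axis=0)
    range_sizes = pam.matrix.sum(axis=1).astype(float)  # per species
    weighted = pam.matrix.T @ range_sizes
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_range = np.where(richness > 0, weighted / np.maximum(richness, 1), np.nan)
    return pd.DataFrame(
        {"hex_id": pam.hex_ids, "richness": richness, "mean_range_size": mean_range}
    )


def write_hex_geojson(
    path: str | Path, grid: HexGrid, properties: pd.DataFrame | None = None
) -> Path:
    """Export clipped hexagons as GeoJSON, optionally joining per-hex columns."""
    props = {}
    if properties is not None:
        props = properties.set_index("hex_id").to_dict("index")
    features = []
    for hid, geom in zip(grid.ids, grid.clipped):
        p = {"hex_id": hid}
        extra = props.get(hid, {})
        p.update({k: (None if pd.isna(v) else v) for k, v in extra.items()})
        features.append(
            {"type": "Feature", "properties": p, "geometry": mapping(geom)}
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path
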