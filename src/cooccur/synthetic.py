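"""Synthetic study system with known ground truth.

Generates a self-contained analogue of a tropical country-scale study system:
smooth correlated environmental layers on a ~1 km grid, a ridge-like elevation
layer splitting the domain into two biogeographic slopes, species whose
occurrences are drawn from known ellipsoidal niches in environment space, a
June/December season structure with a controllable niche-shift magnitude, and
resident vs (winter) migrant status.  Everything is deterministic given the
seed, so downstream parameter-recovery tests can compare fitted models against
the generative truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import box

from .grid import EnvStack, GridSpec, write_stack
from .regions import RegionSet, write_regions

logger = logging.getLogger(__name__)

JUNE = 6
DECEMBER = 12

#: Mahalanobis inclusion quantile defining a species' true suitable set.
TRUE_NICHE_QUANTILE = 0.95


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study system.

    Defaults describe a 100x100 km domain at 1 km resolution with 9
    environmental layers (matching the predictor count used for the real
    system), 60 species organised around 3 latent geographic motifs, a
    moderate seasonal niche shift of 0.5 environment-space SDs, 20% winter
    migrants and a 60% per-cell detection rate.
    """

    grid_nx: int = 100
    grid_ny: int = 100
    cell_size: float = 1.0
    n_layers: int = 9
    n_species: int = 60
    n_motifs_true: int = 3
    seasonal_shift: float = 0.5
    migrant_fraction: float = 0.2
    #: fraction of resident species flagged as close relatives of migrants
    migrant_related_fraction: float = 0.3
    detection_rate: float = 0.6
    barrier_x: int | None = None
    niche_breadth: tuple[float, float] = (0.7, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 20 or self.grid_ny < 20:
            raise ValueError("grid must be at least 20x20 cells")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers")
        if not (0 <= self.migrant_fraction <= 1):
            raise ValueError("migrant_fraction must be in [0, 1]")
        if not (0 < self.detection_rate <= 1):
            raise ValueError("detection_rate must be in (0, 1]")
        if self.seasonal_shift < 0:
            raise ValueError("seasonal_shift must be >= 0")

    @property
    def barrier_column(self) -> int:
        return self.grid_nx // 2 if self.barrier_x is None else self.barrier_x

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_nx, self.grid_ny, self.cell_size)


@dataclass
class TrueNiche:
    """Ground-truth ellipsoidal niche of one species in one season."""

    species_id: str
    season: str  # "june" | "december"
    center: np.ndarray
    covariance: np.ndarray
    resident: bool
    slope: str  # "pacific" | "caribbean" | "both"
    migrant_related: bool = False

    @property
    def month(self) -> int:
        return JUNE if self.season == "june" else DECEMBER


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _smooth_field(rng, shape, sigma: float = 10.0) -> np.ndarray:
    """Spatially autocorrelated field: smoothed white noise, standardized."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_env_stack(config: SimConfig) -> EnvStack:
    """Generate correlated smooth environmental layers plus a ridge layer.

    Layer 0 ("elevation") is a ridge peaking at the barrier column; the
    remaining layers mix a small set of shared latent fields (which makes them
    pairwise correlated) with a layer-specific field whose weight bounds all
    pairwise |r| well below 0.95.
    """
    rng = _rng(config, 0)
    grid = config.grid
    shape = grid.shape
    X, _ = grid.centroids()

    ridge_center = (config.barrier_column + 0.5) * config.cell_size
    width = 0.15 * config.grid_nx * config.cell_size
    ridge = np.exp(-(((X - ridge_center) / width) ** 2))
    ridge = (ridge - ridge.mean()) / ridge.std()

    n_latent = 3
    latents = [_smooth_field(rng, shape) for _ in range(n_latent)]
    latents.append(ridge)

    layers = []
    names = []
    elev = ridge + 0.35 * _smooth_field(rng, shape)
    layers.append((elev - elev.mean()) / elev.std())
    names.append("elevation")
    w_shared, w_unique = 0.65, 0.76  # w_shared^2 + w_unique^2 ~ 1
    for k in range(1, config.n_layers):
        coef = rng.normal(size=len(latents))
        shared = sum(c * f for c, f in zip(coef, latents))
        shared = (shared - shared.mean()) / shared.std()
        f = w_shared * shared + w_unique * _smooth_field(rng, shape)
        layers.append((f - f.mean()) / f.std())
        names.append(f"env{k}")

    return EnvStack(names, np.stack(layers).astype(np.float32), grid)


def generate_true_niches(config: SimConfig, stack: EnvStack) -> list[TrueNiche]:
    """Draw ground-truth niches anchored at latent geographic motifs.

    Niche centers are environment vectors of actual grid cells (so every
    center lies inside the realized environmental cloud), drawn near one of
    ``n_motifs_true`` archetype cells; covariances are scaled copies of the
    global environmental covariance (species occupy a compact sub-volume of
    the available, correlated environment space).  December centers displace
    the June centers by ``seasonal_shift`` environment-space SDs along a
    random unit direction.  Migrants are winter (December-only) species.
    """
    rng = _rng(config, 1)
    E, ji = stack.env_matrix()
    sds = E.std(axis=0)
    lo, hi = E.min(axis=0), E.max(axis=0)
    sigma_env = np.cov(E.T) + 1e-9 * np.eye(E.shape[1])

    anchors = E[rng.choice(len(E), size=config.n_motifs_true, replace=False)]
    # candidate center cells: the neighbourhood of each archetype in env space
    n_cand = min(300, len(E))
    cand = [
        np.argsort(np.linalg.norm((E - a) / sds, axis=1))[:n_cand] for a in anchors
    ]
    niches: list[TrueNiche] = []
    width = int(np.ceil(np.log10(max(config.n_species, 2))))
    for s in range(config.n_species):
        sid = f"sp{s:0{width}d}"
        motif = s % config.n_motifs_true
        center_cell = rng.choice(cand[motif])
        center_june = E[center_cell].copy()
        breadth = rng.uniform(*config.niche_breadth)
        cov = breadth**2 * sigma_env

        u = rng.standard_normal(len(sds))
        u /= np.linalg.norm(u)
        center_dec = np.clip(center_june + config.seasonal_shift * u * sds, lo, hi)

        resident = rng.random() >= config.migrant_fraction
        related = bool(resident and rng.random() < config.migrant_related_fraction)
        # a restricted species is confined to the slope its range centre sits on
        home = "pacific" if ji[center_cell, 1] < config.barrier_column else "caribbean"
        slope = rng.choice(["both", home], p=[0.5, 0.5])

        if resident:
            niches.append(TrueNiche(sid, "june", center_june, cov, True, slope, related))
            niches.append(TrueNiche(sid, "december", center_dec, cov, True, slope, related))
        else:
            # winter visitor: present in December only
            niches.append(TrueNiche(sid, "december", center_dec, cov, False, slope, False))
    return niches


def true_suitable_mask(niche: TrueNiche, stack: EnvStack, config: SimConfig) -> np.ndarray:
    """Boolean (ny, nx) mask of the niche's suitable cells (slope-restricted)."""
    cutoff = stats.chi2.ppf(TRUE_NICHE_QUANTILE, stack.n_layers)
    E, ji = stack.env_matrix()
    d = E - niche.center
    m2 = np.einsum("ij,ij->i", d @ np.linalg.inv(niche.covariance), d)
    mask = np.zeros(stack.grid.shape, dtype=bool)
    ok = m2 <= cutoff
    mask[ji[ok, 0], ji[ok, 1]] = True
    if niche.slope == "pacific":
        mask[:, config.barrier_column:] = False
    elif niche.slope == "caribbean":
        mask[:, : config.barrier_column] = False
    return mask


def sample_occurrences(
    niches: list[TrueNiche], stack: EnvStack, config: SimConfig
) -> pd.DataFrame:
    """Sample occurrence points from each niche's suitable cells.

    Each suitable cell is retained with probability ``detection_rate``; points
    are placed at cell centroids.  Returns columns species, x, y, month.
    """
    rng = _rng(config, 2)
    grid = config.grid
    rows = []
    for niche in niches:
        mask = true_suitable_mask(niche, stack, config)
        jj, ii = np.nonzero(mask)
        if len(jj) == 0:
            logger.warning(
                "species %s (%s) has an empty suitable area", niche.species_id, niche.season
            )
            continue
        if config.detection_rate < 1:
            keep = rng.random(len(jj)) < config.detection_rate
            jj, ii = jj[keep], ii[keep]
        x = grid.x0 + (ii + 0.5) * grid.cell_size
        y = grid.y0 + (jj + 0.5) * grid.cell_size
        rows.append(
            pd.DataFrame(
                {
                    "species": niche.species_id,
                    "x": x,
                    "y": y,
                    "month": niche.month,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["species", "x", "y", "month"])
    return pd.concat(rows, ignore_index=True)


def generate_region_polygons(config: SimConfig) -> RegionSet:
    """Domain plus the two slope polygons split at the barrier ridge line."""
    xmin, ymin, xmax, ymax = config.grid.extent
    xb = config.grid.x0 + config.barrier_column * config.cell_size
    return RegionSet(
        domain=box(xmin, ymin, xmax, ymax),
        pacific=box(xmin, ymin, xb, ymax),
        caribbean=box(xb, ymin, xmax, ymax),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    stack: EnvStack,
    niches: list[TrueNiche],
    occurrences: pd.DataFrame,
    regions: RegionSet,
    out_dir: str | Path,
    config: SimConfig | None = None,
) -> dict:
    """Write layers, occurrences, regions and ground truth; return a manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write fixture bundle to {out_dir}: {exc}") from exc

    written = list(write_stack(out_dir / "layers", stack))
    written += sorted((out_dir / "layers").glob("*.grid.json"))

    occ_path = out_dir / "occurrences.csv"
    occurrences.to_csv(occ_path, index=False)
    written.append(occ_path)

    reg_path = write_regions(out_dir / "regions.geojson", regions)
    written.append(reg_path)

    truth = [
        {
            "species": n.species_id,
            "season": n.season,
            "center": n.center.tolist(),
            "covariance": n.covariance.tolist(),
            "resident": n.resident,
            "slope": n.slope,
            "migrant_related": n.migrant_related,
        }
        for n in niches
    ]
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    written.append(truth_path)

    manifest = {
        "config": None if config is None else {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "files": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(written)
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def simulate(config: SimConfig):
    """Generate the full synthetic system: (stack, niches, occurrences, regions)."""
    stack = generate_env_stack(config)
    niches = generate_true_niches(config, stack)
    occ = sample_occurrences(niches, stack, config)
    regions = generate_region_polygons(config)
    return stack, niches, occ, regions
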