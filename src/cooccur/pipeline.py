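"""Stage-wise orchestration of the full co-occurrence analysis.

Stages (each reads its predecessors' files from the run directory and writes
its own): simulate -> clean -> enm -> pam -> cluster -> overlap -> gom ->
report.  A single YAML config validated up front drives everything; all
randomness derives from one seed, so a rerun with the same config reproduces
the run byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import clustering, enm, gom, hexgrid, overlap, preprocess
from .grid import read_raster, read_stack, write_raster
from .hexgrid import PAM, TierRule
from .regions import read_regions
from .synthetic import DECEMBER, JUNE, SimConfig, simulate, write_fixture_bundle

logger = logging.getLogger(__name__)

SEASONS = {"june": JUNE, "december": DECEMBER}
MODES = ("neutral", "constrained")


class TierConfig(BaseModel):
    b1: int = 10
    b2: int = 40
    t1: float = 0.70
    t2: float = 0.50
    t3: float = 0.30

    def rule(self) -> TierRule:
        return TierRule(self.b1, self.b2, self.t1, self.t2, self.t3)


class SimulateConfig(BaseModel):
    grid_nx: int = 100
    grid_ny: int = 100
    cell_size: float = 1.0
    n_layers: int = 9
    n_species: int = 60
    n_motifs_true: int = 3
    seasonal_shift: float = 0.5
    migrant_fraction: float = 0.2
    migrant_related_fraction: float = 0.3
    detection_rate: float = 0.6
    barrier_x: int | None = None

    def sim_config(self, seed: int) -> SimConfig:
        return SimConfig(seed=seed, **self.model_dump())


class PipelineConfig(BaseModel):
    """Validated configuration for the full pipeline."""

    simulate: SimulateConfig | None = Field(default_factory=SimulateConfig)
    occurrences: str | None = None
    layers: list[str] | None = None
    regions: str | None = None

    months: list[int] = [6, 12]
    thin_km: float = 1.0
    n_min: int = 10
    tau: float = 0.75
    tier: TierConfig = Field(default_factory=TierConfig)
    hex_area_km2: float = 164.8
    k_max: int = 10
    gap_B: int = 50
    gom_k_min: int = 2
    gom_k_max: int = 14
    gom_tol: float = 0.1
    gom_starts: int = 10
    n_null_draws: int = 1000
    n_subsamples: int = 500
    modes: list[Literal["neutral", "constrained"]] = ["neutral", "constrained"]
    seed: int = 0

    @field_validator("months")
    @classmethod
    def _check_months(cls, v):
        if sorted(v) != [6, 12]:
            raise ValueError("months must be [6, 12]")
        return v

    @field_validator("tau")
    @classmethod
    def _check_tau(cls, v):
        if not (0.5 < v <= 1.0):
            raise ValueError("tau must be in (0.5, 1]")
        return v

    def data_is_simulated(self) -> bool:
        return self.simulate is not None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run {producer} first"
        )
    return path


def _season_of(month: int) -> str:
    return {JUNE: "june", DECEMBER: "december"}[month]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> None:
    if not cfg.data_is_simulated():
        raise ValueError("config has no simulate block; provide input paths instead")
    sim_cfg = cfg.simulate.sim_config(cfg.seed)
    stack, niches, occ, regions = simulate(sim_cfg)
    write_fixture_bundle(stack, niches, occ, regions, run_dir / "sim", sim_cfg)


def _load_inputs(cfg: PipelineConfig, run_dir: Path):
    if cfg.data_is_simulated():
        sim = _require(run_dir / "sim", "simulate")
        layer_paths = sorted((sim / "layers").glob("*.tif"))
        stack = read_stack(layer_paths)
        regions = read_regions(sim / "regions.geojson")
        occ = pd.read_csv(sim / "occurrences.csv")
    else:
        stack = read_stack(cfg.layers)
        regions = read_regions(cfg.regions)
        occ = pd.read_csv(cfg.occurrences)
    return stack, regions, occ


def stage_clean(cfg: PipelineConfig, run_dir: Path) -> None:
    _, _, occ = _load_inputs(cfg, run_dir)
    out = run_dir / "clean"
    out.mkdir(parents=True, exist_ok=True)
    by_month = preprocess.split_by_month(occ, set(cfg.months))
    counts: dict[str, dict[str, int]] = {}
    for month, table in by_month.items():
        season = _season_of(month)
        kept, excluded = preprocess.clean_season(table, cfg.thin_km, cfg.n_min)
        kept.to_csv(out / f"{season}.csv", index=False)
        excluded.to_csv(out / f"excluded_{season}.csv", index=False)
        for sp, n in kept.groupby("species").size().items():
            counts.setdefault(sp, {})[season] = int(n)
    (out / "counts.json").write_text(json.dumps(counts, indent=1))


def stage_enm(cfg: PipelineConfig, run_dir: Path) -> None:
    stack, regions, _ = _load_inputs(cfg, run_dir)
    clean = _require(run_dir / "clean", "clean")
    out = run_dir / "enm"
    out.mkdir(parents=True, exist_ok=True)
    models_meta = {}
    for season in SEASONS:
        occ = pd.read_csv(_require(clean / f"{season}.csv", "clean"))
        for sp, pts in occ.groupby("species"):
            values = enm.extract_env_values(pts, stack, species=sp)
            model = enm.fit_mve(values, tau=cfg.tau)
            slopes = regions.slope_of_points(pts["x"].to_numpy(), pts["y"].to_numpy())
            meta = {"species": sp, "season": season}
            cont = enm.suitability_surface(model, stack, meta)
            binr = enm.binarize_sdm(model, stack, meta)
            for mode in cfg.modes:
                region = (
                    regions.domain
                    if mode == "neutral"
                    else enm.constrained_region(regions, pts)
                )
                for kind, r in (("cont", cont), ("bin", binr)):
                    clipped = enm.clip_to_region(r, region, mode)
                    clipped.meta.update(meta, mode=mode, kind=kind)
                    write_raster(out / f"{sp}_{season}_{mode}_{kind}.tif", clipped)
            models_meta[f"{sp}_{season}"] = {
                "species": sp,
                "season": season,
                "center": model.center_.tolist(),
                "shape": model.shape_.tolist(),
                "cutoff": model.cutoff_,
                "tau": cfg.tau,
                "n_train": model.n_train_,
                "method": model.method_,
                "layers": stack.names,
                "slopes": slopes,
            }
    (out / "models.json").write_text(json.dumps(models_meta, indent=1))


def _load_sdms(run_dir: Path, season: str, mode: str, kind: str):
    enm_dir = _require(run_dir / "enm", "enm")
    out = {}
    for p in sorted(enm_dir.glob(f"*_{season}_{mode}_{kind}.tif")):
        sp = p.name.rsplit(f"_{season}_{mode}_{kind}.tif", 1)[0]
        out[sp] = read_raster(p)
    if not out:
        raise FileNotFoundError(f"no {season}/{mode}/{kind} rasters: run enm first")
    return out


def stage_pam(cfg: PipelineConfig, run_dir: Path) -> None:
    stack, regions, _ = _load_inputs(cfg, run_dir)
    out = run_dir / "pam"
    out.mkdir(parents=True, exist_ok=True)
    grid = hexgrid.build_hex_grid(regions.domain, cfg.hex_area_km2)
    assignment = hexgrid.map_cells_to_hexagons(stack.grid, grid)
    np.save(out / "assignment.npy", assignment)
    hexgrid.write_hex_geojson(out / "hexes.geojson", grid)
    rule = cfg.tier.rule()
    for season in SEASONS:
        for mode in cfg.modes:
            sdms = _load_sdms(run_dir, season, mode, "bin")
            pam = hexgrid.build_pam(
                sdms, grid, assignment, rule, season, mode,
                valid_mask=stack.valid_mask,
            )
            pam.to_frame().to_csv(out / f"pam_{season}_{mode}.csv")
            div = hexgrid.diversity_maps(pam)
            div.to_csv(out / f"diversity_{season}_{mode}.csv", index=False)
            hexgrid.write_hex_geojson(
                out / f"diversity_{season}_{mode}.geojson", grid, div
            )


def _load_pam(run_dir: Path, season: str, mode: str) -> PAM:
    path = _require(run_dir / "pam" / f"pam_{season}_{mode}.csv", "pam")
    df = pd.read_csv(path, index_col=0)
    return PAM(df.to_numpy(), list(df.index), list(df.columns), season, mode)


def stage_cluster(cfg: PipelineConfig, run_dir: Path) -> None:
    out = run_dir / "cluster"
    out.mkdir(parents=True, exist_ok=True)
    labels_frames = []
    for mode in cfg.modes:
        solutions = {}
        for season in SEASONS:
            pam = _load_pam(run_dir, season, mode)
            n_distinct = len(np.unique(pam.matrix, axis=0))
            k_max = min(cfg.k_max, max(n_distinct - 1, 2))
            sol = clustering.cluster_species(
                pam, k_max=k_max, B=cfg.gap_B, seed=cfg.seed
            )
            solutions[season] = sol
            labels_frames.append(sol.to_frame())
            sol.gap_curve.to_csv(out / f"gap_{season}_{mode}.csv", index=False)
            _, newick = clustering.upgma_tree(pam)
            (out / f"upgma_{season}_{mode}.nwk").write_text(newick + "\n")
        shared = sorted(
            set(solutions["june"].labels) & set(solutions["december"].labels)
        )
        for src, dst in (("june", "december"), ("december", "june")):
            ov = clustering.cross_season_overlap(
                solutions[src], solutions[dst], shared
            )
            report = clustering.classify_stability(ov)
            report.to_csv(out / f"stability_{mode}_{src}_to_{dst}.csv", index=False)
    pd.concat(labels_frames, ignore_index=True).to_csv(
        out / "labels.csv", index=False
    )


def stage_overlap(cfg: PipelineConfig, run_dir: Path) -> None:
    clean = _require(run_dir / "clean", "clean")
    cluster_dir = _require(run_dir / "cluster", "cluster")
    out = run_dir / "overlap"
    out.mkdir(parents=True, exist_ok=True)
    counts = json.loads((clean / "counts.json").read_text())
    point_counts = {
        sp: (c.get("june", 0), c.get("december", 0)) for sp, c in counts.items()
    }
    labels = pd.read_csv(cluster_dir / "labels.csv")

    migrant_related: list[str] = []
    truth_path = run_dir / "sim" / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        migrant_related = sorted(
            {t["species"] for t in truth if t.get("migrant_related")}
        )

    for mode in cfg.modes:
        june = _load_sdms(run_dir, "june", mode, "cont")
        december = _load_sdms(run_dir, "december", mode, "cont")
        report = pd.read_csv(
            _require(
                cluster_dir / f"stability_{mode}_june_to_december.csv", "cluster"
            )
        )
        mode_labels = labels[(labels["mode"] == mode) & (labels["season"] == "june")]
        cat_by_cluster = dict(zip(report["cluster"], report["category"]))
        categories = {
            r.species: cat_by_cluster.get(r.cluster, "none")
            for r in mode_labels.itertuples()
        }
        records = overlap.overlap_table(
            june, december, categories, point_counts, mode
        )
        records.to_csv(out / f"records_{mode}.csv", index=False)
        null = overlap.randomized_null(
            june, december, n_draws=cfg.n_null_draws, seed=cfg.seed
        )
        pd.DataFrame({"D": null.draws}).to_csv(out / f"null_{mode}.csv", index=False)

        tests: dict = {"mode": mode, "seed": cfg.seed}
        tests["observed_vs_null"] = overlap.observed_vs_null_test(
            records["D"].to_numpy(), null
        )
        try:
            tests["category_comparisons"] = overlap.category_comparisons(
                records
            ).to_dict("records")
        except ValueError as exc:
            tests["category_comparisons"] = {"skipped": str(exc)}
        try:
            tests["effort_bias"] = overlap.effort_bias_check(records)
        except ValueError as exc:
            tests["effort_bias"] = {"skipped": str(exc)}
        if len(migrant_related) >= 5:
            tests["migrant_subsample"] = overlap.migrant_subsample_test(
                records, migrant_related, cfg.n_subsamples, seed=cfg.seed
            )
        else:
            tests["migrant_subsample"] = {"skipped": "no migrant-related set"}
        (out / f"tests_{mode}.json").write_text(json.dumps(tests, indent=1))


def stage_gom(cfg: PipelineConfig, run_dir: Path) -> None:
    out = run_dir / "gom"
    out.mkdir(parents=True, exist_ok=True)
    for season in SEASONS:
        for mode in cfg.modes:
            pam = _load_pam(run_dir, season, mode)
            sites = pam.sites_matrix()
            k_hi = min(cfg.gom_k_max, len(pam.species))
            fits = gom.motif_series(
                sites,
                range(cfg.gom_k_min, k_hi + 1),
                tol=cfg.gom_tol,
                n_starts=cfg.gom_starts,
                seed=cfg.seed,
            )
            for K, fit in fits.items():
                base = f"{season}_{mode}_K{K}"
                gom.motif_map(fit, pam.hex_ids).to_csv(
                    out / f"omega_{base}.csv", index=False
                )
                pd.DataFrame(fit.theta_, columns=pam.species).to_csv(
                    out / f"theta_{base}.csv", index=False
                )


def stage_report(cfg: PipelineConfig, run_dir: Path) -> dict:
    summary: dict = {"seed": cfg.seed, "config": cfg.model_dump()}
    clean = _require(run_dir / "clean", "clean")
    counts = json.loads((clean / "counts.json").read_text())
    residents = sorted(
        sp for sp, c in counts.items() if "june" in c and "december" in c
    )
    summary["n_species"] = {
        "june": sum("june" in c for c in counts.values()),
        "december": sum("december" in c for c in counts.values()),
        "resident": len(residents),
    }
    cluster_dir = _require(run_dir / "cluster", "cluster")
    labels = pd.read_csv(cluster_dir / "labels.csv")
    for mode in cfg.modes:
        m: dict = {}
        for season in SEASONS:
            sub = labels[(labels["mode"] == mode) & (labels["season"] == season)]
            m[f"K_{season}"] = int(sub["cluster"].max())
        report = pd.read_csv(cluster_dir / f"stability_{mode}_june_to_december.csv")
        tallies = report["category"].value_counts().to_dict()
        m["stability"] = {
            k: int(tallies.get(k, 0)) for k in ("stable", "split", "diffuse", "unknown")
        }
        tests = json.loads(
            (_require(run_dir / "overlap", "overlap") / f"tests_{mode}.json").read_text()
        )
        m["tests"] = tests
        records = pd.read_csv(run_dir / "overlap" / f"records_{mode}.csv")
        m["mean_D"] = float(records["D"].mean())
        m["n_records"] = len(records)
        summary[mode] = m
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


STAGES = {
    "simulate": stage_simulate,
    "clean": stage_clean,
    "enm": stage_enm,
    "pam": stage_pam,
    "cluster": stage_cluster,
    "overlap": stage_overlap,
    "gom": stage_gom,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute every stage in order; returns the summary dict."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    order = list(STAGES)
    if not cfg.data_is_simulated():
        order.remove("simulate")
    summary = None
    for name in order:
        logger.info("pipeline stage: %s", name)
        try:
            result = STAGES[name](cfg, run_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        if name == "report":
            summary = result
    return summary
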