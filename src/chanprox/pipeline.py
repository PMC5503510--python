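"""End-to-end orchestration: simulate/load -> filter -> rasterize -> segment
-> proximity statistics -> randomization null -> machine-readable report.

A run is fully described by a :class:`RunConfig`; rerunning the same
config reproduces the report bit-for-bit (no timestamps, all randomness
seeded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .locmap import (LocalizationTable, convex_footprint, filter_by_photons,
                     rasterize, read_localizations)
from .segmentation import cluster_size_stats, segment
from . import proximity
from .randomization import null_envelope
from .synthetic import SceneSpec, generate_cluster_scene

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    scene: SceneSpec | None = None          # simulate when set ...
    red_path: str | None = None             # ... otherwise load tables
    green_path: str | None = None
    pixel_size_nm: float = 20.0
    photon_threshold: float = 50.0
    close_iterations: int = 1
    close_count: int = 5
    min_area_px: int = 1
    ring_width_nm: float = 20.0
    max_radius_nm: float = 300.0
    enrichment_rings: tuple[int, ...] = (1, 2, 3)
    isolated_radius_nm: float = 200.0
    near_radius_nm: float = 200.0
    within_radius_nm: float = 50.0
    n_reps: int = 100
    seed: int = 0
    significance_level: float = 0.01
    footprint_mode: str = "auto"            # auto | field | hull
    out_dir: str | None = None
    make_plots: bool = False

    def validate(self) -> None:
        if self.scene is None and (self.red_path is None or self.green_path is None):
            raise ValueError("config needs either a scene spec or two input paths")
        if self.scene is None:
            for p in (self.red_path, self.green_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.footprint_mode not in ("auto", "field", "hull"):
            raise ValueError("footprint_mode must be auto, field or hull")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scene = raw.pop("scene", None)
        if scene is not None:
            scene = SceneSpec(**scene)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "enrichment_rings" in raw:
            raw["enrichment_rings"] = tuple(raw["enrichment_rings"])
        return cls(scene=scene, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scene is not None:
            d["scene"] = self.scene.to_dict()
        d["enrichment_rings"] = list(self.enrichment_rings)
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns (and optionally writes) a report containing the full
    provenance, the cluster catalogs' summary statistics, the distance
    distribution with its bell fit, the annulus profile with its
    Monte-Carlo null envelope, and per-statistic p-values with an
    enrichment flag at ``significance_level``.
    """
    config.validate()
    stage = "input"
    try:
        if config.scene is not None:
            table_red, table_green, truth = generate_cluster_scene(config.scene)
        else:
            table_red = read_localizations(config.red_path)
            table_green = read_localizations(config.green_path)
            truth = None

        stage = "filter"
        table_red = filter_by_photons(table_red, config.photon_threshold)
        table_green = filter_by_photons(table_green, config.photon_threshold)

        stage = "rasterize"
        red_map = rasterize(table_red, config.pixel_size_nm, binary=True)
        green_map = rasterize(table_green, config.pixel_size_nm, binary=True,
                              shape=red_map.shape)

        stage = "footprint"
        mode = config.footprint_mode
        if mode == "auto":
            mode = "field" if config.scene is not None else "hull"
        if mode == "field":
            footprint = np.ones(red_map.shape, dtype=bool)
        else:
            both = red_map.binary | green_map.binary
            footprint = convex_footprint(both, config.pixel_size_nm)

        stage = "segment"
        red_cat = segment(red_map, config.close_iterations, config.close_count,
                          config.min_area_px)
        green_cat = segment(green_map, config.close_iterations, config.close_count,
                            config.min_area_px)
        if len(red_cat) == 0 or len(green_cat) == 0:
            raise ValueError("segmentation produced an empty catalog")

        stage = "proximity"
        dist = proximity.nearest_edge_distances(green_cat, red_cat.mask())
        try:
            bell = proximity.fit_distance_bell(dist, config.ring_width_nm)
        except (ValueError, RuntimeError) as exc:
            log.warning("distance bell fit skipped: %s", exc)
            bell = None

        stage = "null"
        ens = null_envelope(
            red_cat, green_cat, footprint=footprint,
            n_reps=config.n_reps, seed=config.seed,
            ring_width_nm=config.ring_width_nm,
            max_radius_nm=config.max_radius_nm,
            enrichment_rings=config.enrichment_rings,
            isolated_radius_nm=config.isolated_radius_nm,
            near_radius_nm=config.near_radius_nm,
            within_radius_nm=config.within_radius_nm,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    p_enrich = ens.p_values.get("near_ring_occupancy", 1.0)
    report = {
        "provenance": {
            "package": "chanprox",
            "version": __version__,
            "config": config.to_dict(),
        },
        "clusters": {
            "red": _summary(cluster_size_stats(red_cat)),
            "green": _summary(cluster_size_stats(green_cat)),
        },
        "distances": {
            "n": len(dist),
            "median_nm": float(np.median(dist.distances_nm)),
            "bell_fit": bell,
        },
        "annulus": {
            "inner_nm": ens.ring_inner_nm,
            "outer_nm": ens.ring_outer_nm,
            "observed_percent": ens.observed_profile,
            "null_mean_percent": ens.null_mean,
            "null_lo_percent": ens.null_lo,
            "null_hi_percent": ens.null_hi,
        },
        "statistics": {
            "observed": ens.observed,
            "p_values": ens.p_values,
            "null_provenance": ens.provenance,
        },
        "flags": {
            "significant_enrichment": bool(p_enrich <= config.significance_level),
            "significance_level": config.significance_level,
        },
    }
    if truth is not None:
        report["ground_truth"] = {
            "true_isolated_fraction": truth.true_isolated_fraction,
            "true_mean_green_within_50nm": truth.true_mean_green_within_50nm,
            "n_true_red": len(truth.true_red_catalog),
            "n_true_green": len(truth.true_green_catalog),
        }
    report = _jsonable(report)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        red_cat.to_dataframe().to_csv(out / "red_clusters.csv", index=False)
        green_cat.to_dataframe().to_csv(out / "green_clusters.csv", index=False)
        prof = proximity.annulus_occupancy(
            red_cat.mask(), green_cat.mask(), config.ring_width_nm,
            config.max_radius_nm, footprint)
        prof.to_dataframe().to_csv(out / "annulus_profile.csv", index=False)
        if config.make_plots:
            from .plots import plot_annulus_profile, plot_distance_hist
            plot_annulus_profile(ens, out / "annulus_profile.png")
            plot_distance_hist(dist, bell, out / "distance_histogram.png")
    return report


def _summary(stats: dict) -> dict:
    return {"median_area_nm2": stats["median_area_nm2"],
            "n_clusters": stats["n_clusters"]}
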