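"""End-to-end pipeline: simulate → SDM → connectivity → MSPA → corridors → prioritize.

``run_pipeline`` drives the full analysis on a synthetic landscape (or
user-supplied occurrence/covariate files), writing every stage artifact
plus a machine-readable run manifest into the output directory. Re-running
with the same config and seed reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import connectivity as conn
from . import corridors as cor
from . import mspa as mspa_mod
from . import prioritize as prio
from . import sdm
from .learners import default_learners
from .raster import Raster, read_raster, write_raster
from .synthland import default_landscape, make_covariates, make_suitability, sample_occurrences

log = logging.getLogger("corridorscape")


def _json_default(o):
    import numpy as _np

    if isinstance(o, (_np.integer,)):
        return int(o)
    if isinstance(o, (_np.floating,)):
        return float(o)
    if isinstance(o, _np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")



@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, with study defaults.

    Distances are meters, areas km², the corridor cutoff is in
    cost-weighted distance units (resistance x meters).
    """

    seed: int = 0
    thinning_distance: float = 1000.0
    vif_threshold: float = 10.0
    train_fraction: float = 0.75
    auc_min: float = 0.8
    tss_min: float = 0.7
    dispersal_distances: tuple[float, ...] = (500.0, 1000.0)
    mspa_edge_width: int = 1
    source_min_area_km2: float = 35.0
    resistance_min: float = 1.0
    resistance_max: float = 100.0
    corridor_cutoff: float = 20000.0
    corridor_drop_above_cutoff: bool = False
    n_presence: int = 200
    n_informative: int = 3
    n_collinear: int = 1
    covariate_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in (
            "thinning_distance",
            "vif_threshold",
            "source_min_area_km2",
            "corridor_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "dispersal_distances" in raw:
            raw["dispersal_distances"] = tuple(raw["dispersal_distances"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# GeoJSON writers (plain dicts; geometries are simple enough not to need a
# full vector stack)


def sources_to_geojson(sources: mspa_mod.SourceSet, grid) -> dict:
    from shapely.geometry import MultiPoint, mapping
    from shapely.ops import unary_union

    feats = []
    half = grid.cell_size / 2.0
    for s in sources.sources:
        boxes = []
        from shapely.geometry import box

        for r, c in s.cells:
            cx, cy = grid.cell_center(int(r), int(c))
            boxes.append(box(cx - half, cy - half, cx + half, cy + half))
        geom = unary_union(boxes)
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "source_id": s.source_id,
                    "area_km2": s.area_km2,
                    "centroid_x": s.centroid[0],
                    "centroid_y": s.centroid[1],
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def corridors_to_geojson(network: cor.CorridorNetwork, grid) -> dict:
    from shapely.geometry import LineString, mapping

    feats = []
    for c in network.corridors:
        coords = [grid.cell_center(int(r), int(cc)) for r, cc in c.path]
        geom = LineString(coords) if len(coords) >= 2 else None
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom) if geom else None,
                "properties": {
                    "source_a": c.source_pair[0],
                    "source_b": c.source_pair[1],
                    "lcp_cost": c.lcp_cost,
                    "length_m": c.length_m,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


# ---------------------------------------------------------------------------
# the driver


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    landscape_spec=None,
    occurrences: pd.DataFrame | None = None,
    covariates: dict[str, Raster] | None = None,
    truth: Raster | None = None,
) -> dict:
    """Run the full analysis; returns the manifest dict.

    With no explicit inputs, a synthetic landscape (the package default,
    seeded from the config) supplies occurrences and covariates, and the
    latent field is kept as ground truth for the manifest's diagnostics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__, "stages": {}}

    # -- simulate -----------------------------------------------------------
    if occurrences is None or covariates is None:
        spec = landscape_spec or default_landscape(seed=config.seed)
        truth = make_suitability(spec)
        covariates = make_covariates(
            truth,
            n_informative=config.n_informative,
            n_collinear=config.n_collinear,
            noise_sd=config.covariate_noise_sd,
            seed=config.seed + 1,
        )
        occurrences = sample_occurrences(
            truth, n_presence=config.n_presence, seed=config.seed + 2
        )
        write_raster(truth, out / "latent_suitability.asc")
        occurrences.to_csv(out / "occurrences.csv", index=False)
        manifest["stages"]["simulate"] = {
            "landscape": {
                "width": spec.width,
                "height": spec.height,
                "cell_size": spec.cell_size,
                "n_hotspots": len(spec.hotspots),
            },
            "n_presence": int((occurrences["label"] == "presence").sum()),
            "n_background": int((occurrences["label"] == "background").sum()),
        }
    grid = next(iter(covariates.values())).grid
    if not occurrences["label"].eq("presence").any():
        raise RuntimeError("sdm stage: no presence records in the input occurrences")

    # -- sdm ----------------------------------------------------------------
    thinned = sdm.thin_occurrences(occurrences, config.thinning_distance)
    retained_layers, vif_trace = sdm.vif_screen(
        covariates, thinned, threshold=config.vif_threshold
    )
    train, test = sdm.split_train_test(thinned, config.train_fraction, seed=config.seed + 3)
    X_train = sdm.sample_stack(covariates, train, retained_layers)
    y_train = (train["label"] == "presence").to_numpy()
    X_test = sdm.sample_stack(covariates, test, retained_layers)
    y_test = (test["label"] == "presence").to_numpy()
    fits = {}
    scores = []
    for learner in default_learners(seed=config.seed + 4):
        learner.fit(X_train, y_train)
        fits[learner.learner_id] = learner
        scores.append((learner.learner_id, sdm.evaluate(learner, X_test, y_test)))
    result = sdm.gate_and_weight(scores, auc_min=config.auc_min, tss_min=config.tss_min)
    suitability = sdm.ensemble_predict(fits, result, covariates, retained_layers)
    ens_test_scores = np.zeros(len(y_test))
    for lid, _, w in result.retained:
        ens_test_scores += w * fits[lid].predict_score(X_test)
    habitat, threshold = sdm.binarize_habitat(suitability, ens_test_scores, y_test)
    write_raster(suitability, out / "suitability.asc")
    write_raster(habitat, out / "habitat.asc")
    vif_trace.to_csv(out / "vif_trace.csv", index=False)
    eval_report = {
        "per_learner": {
            lid: {"auc": ev.auc, "tss": ev.tss} for lid, ev in result.scores.items()
        },
        "retained": [
            {"learner": lid, "raw_weight": rw, "weight": w} for lid, rw, w in result.retained
        ],
        "excluded": [{"learner": lid, "reason": r} for lid, r in result.excluded],
        "binarization_threshold": threshold,
    }
    (out / "sdm_report.json").write_text(json.dumps(eval_report, indent=2, default=_json_default))
    manifest["stages"]["sdm"] = {
        "n_thinned_presences": int((thinned["label"] == "presence").sum()),
        "retained_layers": retained_layers,
        "dropped_layers": [n for n in covariates if n not in retained_layers],
        **eval_report,
    }
    if truth is not None:
        corr = float(np.corrcoef(truth.data.ravel(), suitability.data.ravel())[0, 1])
        manifest["stages"]["sdm"]["truth_correlation"] = corr

    # -- connectivity -------------------------------------------------------
    report = conn.connectivity_report(habitat, config.dispersal_distances)
    report["indices"].to_csv(out / "connectivity_indices.csv", index=False)
    report["patches"].to_csv(out / "connectivity_patches.csv", index=False)
    manifest["stages"]["connectivity"] = {
        "n_patches": len(report["patches"]),
        "indices": report["indices"].to_dict(orient="records"),
    }

    # -- mspa ---------------------------------------------------------------
    class_map = mspa_mod.mspa_classify(habitat, edge_width_s=config.mspa_edge_width)
    sources = mspa_mod.select_sources(class_map, min_area_km2=config.source_min_area_km2)
    write_raster(class_map.classes, out / "mspa_classes.asc")
    class_map.summary().to_csv(out / "mspa_summary.csv", index=False)
    (out / "sources.geojson").write_text(json.dumps(sources_to_geojson(sources, grid), default=_json_default))
    manifest["stages"]["mspa"] = {
        "class_cells": {name: class_map.count(name) for name in mspa_mod.CLASS_CODES},
        "n_sources": sources.count,
        "total_source_area_km2": sources.total_area_km2,
    }

    # -- corridors ----------------------------------------------------------
    resistance = cor.resistance_from_suitability(
        suitability, r_min=config.resistance_min, r_max=config.resistance_max
    )
    network = cor.build_network(
        sources,
        resistance,
        cutoff=config.corridor_cutoff,
        drop_above_cutoff=config.corridor_drop_above_cutoff,
    )
    (out / "corridors.geojson").write_text(json.dumps(corridors_to_geojson(network, grid), default=_json_default))
    (out / "network_stats.json").write_text(json.dumps(network.stats(), indent=2, default=_json_default))
    manifest["stages"]["corridors"] = network.stats()

    # -- prioritize ---------------------------------------------------------
    dpc_col = f"dPC_{int(max(config.dispersal_distances))}m"
    patches = report["patches"]
    summary: dict = {}
    if len(patches) and dpc_col in patches:
        ranking = prio.rank_sources(
            pd.Series(patches[dpc_col].to_numpy(), index=patches["patch_id"])
        )
        ranking.to_csv(out / "source_ranking.csv", index=False)
        summary["n_top_class_sources"] = int((ranking["importance_class"] == 4).sum())
    if network.count >= 1:
        cranking = prio.rank_corridors(network)
        cranking.to_csv(out / "corridor_ranking.csv", index=False)
        summary["n_top_class_corridors"] = int((cranking["importance_class"] == 4).sum())
    manifest["stages"]["prioritize"] = summary

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    return manifest
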