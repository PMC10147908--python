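"""Formats, configuration, logging, and the end-to-end pipeline orchestrator.

Feature tables travel as CSV with a versioned header line; detections as
GeoJSON; label maps as 16-bit TIFF; run manifests as JSON. The orchestrator
composes simulate → (render → segment → measure | direct table) → cluster →
assign → stats, deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .archetypes import ALL_FEATURES, CLUSTER_FEATURES, default_archetypes

__all__ = [
    "TABLE_VERSION",
    "RunManifest",
    "read_table",
    "write_table",
    "write_labels_tiff",
    "detections_to_geojson",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("melanotype")

TABLE_VERSION = "melanotype_table_v1"
MANDATORY_COLUMNS = ("specimen_id", "compartment", "region", *ALL_FEATURES)


def write_table(cells: pd.DataFrame, path) -> None:
    """Write a cell table as CSV under a versioned header comment."""
    path = Path(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"table is missing mandatory columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"#{TABLE_VERSION}\n")
        cells.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a versioned cell-table CSV; unknown columns are preserved."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"#{TABLE_VERSION}":
            raise ValueError(
                f"{path}: expected header '#{TABLE_VERSION}', found {header!r}"
            )
        cells = pd.read_csv(fh)
    missing = [c for c in MANDATORY_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    return cells


def write_labels_tiff(labels: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def detections_to_geojson(detections, path=None) -> dict:
    """Nucleus polygons and measurements as a GeoJSON FeatureCollection."""
    from .morphometry import nucleus_contour

    features = []
    for det in detections:
        contour = nucleus_contour(det.nucleus_mask)
        r0, c0, _, _ = det.bbox
        ring = [
            [float((c + c0) * det.pixel_size_um), float((r + r0) * det.pixel_size_um)]
            for r, c in contour
        ]
        if ring and ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "label": det.label,
                    "nucleus_area_um2": det.nucleus_area_um2,
                    "cell_area_um2": det.cell_area_um2,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    stages: dict
    outputs: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def load_config(path) -> dict:
    """Read a TOML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def run_pipeline(config, outdir) -> RunManifest:
    """Run simulate → cluster → assign → stats from a config dict or TOML path.

    Config keys (all optional):
      seed (int), scale (float, cohort scale of the reference counts),
      features (list, clustering features), jmax (int),
      compartments (list restricting which compartments to cluster).
    """
    from . import celltyping, synthetic_data
    from .stats import kruskal_wallis, chi_square_table

    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    scale = float(config.get("scale", 0.005))
    features = tuple(config.get("features", CLUSTER_FEATURES))
    jmax = int(config.get("jmax", 6))
    archetypes = default_archetypes()

    cohort_cfg = synthetic_data.default_cohort_config(scale=scale, seed=seed)
    cohort = synthetic_data.make_cohort(cohort_cfg, archetypes)
    log.info("simulated %d cells over %d specimens",
             cohort.manifest["total_cells"], len(cohort_cfg.specimens))
    write_table(cohort.cells, outdir / "cells.csv")

    stages = {"simulate": dict(cohort.manifest)}
    typed_parts = []
    reports = {}
    compartments = config.get(
        "compartments", sorted(cohort.cells["compartment"].unique())
    )
    for comp in compartments:
        sub = cohort.cells[cohort.cells["compartment"] == comp]
        if len(sub) < 2:
            continue
        props, model, mapping = celltyping.recover_type_proportions(
            sub, features, seed=seed, archetypes=archetypes, jmax=jmax
        )
        typed_parts.append(celltyping.type_cohort(sub, model, archetypes))
        reports[comp] = {
            "n_cells": int(len(sub)),
            "k": model.k,
            "silhouette": model.silhouette,
            "bic": [None if np.isnan(b) else float(b) for b in model.bic],
            "proportions": props,
        }
        log.info("%s: %d cells -> k=%d, silhouette=%.3f", comp, len(sub), model.k,
                 model.silhouette if np.isfinite(model.silhouette) else float("nan"))
    typed = pd.concat(typed_parts, ignore_index=True)
    write_table(typed, outdir / "typed.csv")

    tables = celltyping.distribution_tables(typed)
    stats_report = {}
    counts = tables.get("compartment_counts")
    if counts is not None and counts.shape[0] >= 2 and counts.shape[1] >= 2:
        res = chi_square_table(counts.to_numpy() + 0.0)
        stats_report["type_by_compartment_chi2"] = {
            "statistic": res.statistic, "p": res.p_value,
        }
    groups = [g["nucleus_circularity"].to_numpy() for _, g in typed.groupby("cell_type")]
    if len(groups) >= 3:
        res = kruskal_wallis(groups)
        stats_report["circularity_by_type_kw"] = {
            "statistic": res.statistic, "p": res.p_value,
        }
    report = {
        "clustering": reports,
        "distributions": {k: v.to_dict() for k, v in tables.items()},
        "stats": stats_report,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))

    manifest = RunManifest(
        seed=seed,
        config_hash=cohort_cfg.config_hash(),
        stages=stages,
        outputs={
            "cells": str(outdir / "cells.csv"),
            "typed": str(outdir / "typed.csv"),
            "report": str(outdir / "report.json"),
        },
    )
    manifest.write(outdir / "manifest.json")
    return manifest
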