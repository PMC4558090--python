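"""End-to-end pipeline: manifest -> per-image analysis -> cohort tables.

The pipeline is manifest-driven (a CSV naming each image, its mask, subject,
laterality and timepoint) and fail-soft: a failure on one image is logged
with its identity and the run continues; the summary lists all failures.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fileio
from .cohort import (SLOTS, ImageAnalysis, SubjectRecord, analyze_image,
                     assign_group, cohort_summary, correlation_tests,
                     longitudinal_tests, records_to_frame, zonal_tests)
from .segmentation import to_uint8

__all__ = ["PipelineConfig", "PipelineOutput", "run_pipeline"]

logger = logging.getLogger("mammodense")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    manifest: str
    output_dir: str = "mammodense_out"
    pixel_spacing_cm: float | None = None  # fallback when metadata absent
    ncols: int = 6
    nrows: int = 8
    zone_map: dict | None = None  # {(col,row): zone}; None = default bands
    weight_scheme: str = "inverse_square_physical"
    empty_cell_policy: str = "zero"
    group_bin_edges: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 100.0)
    seed: int = 0
    write_dense_maps: bool = False

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid dimensions must be positive")
        edges = tuple(self.group_bin_edges)
        if list(edges) != sorted(set(edges)) or edges[0] != 0.0 or edges[-1] != 100.0:
            raise ValueError("group bin edges must strictly increase from 0 to 100")
        self.group_bin_edges = edges

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "zone_map" in raw and isinstance(raw["zone_map"], dict):
            raw["zone_map"] = {tuple(int(v) for v in k.split(",")): z
                               for k, z in raw["zone_map"].items()}
        if "group_bin_edges" in raw:
            raw["group_bin_edges"] = tuple(float(v) for v in raw["group_bin_edges"])
        return cls(**raw)


@dataclass
class PipelineOutput:
    records: list[SubjectRecord]
    per_image: pd.DataFrame
    regional_long: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    failures: list[dict]
    output_dir: Path


def _slot(laterality: str, timepoint: str) -> str:
    return f"{'left' if laterality == 'L' else 'right'}_{timepoint}"


def _regional_rows(record_meta: dict, analysis: ImageAnalysis) -> list[dict]:
    grid = analysis.grid
    rows = []
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            rows.append({**record_meta, "col": c + 1, "row": r + 1,
                         "breast_px": int(grid.breast_px[r, c]),
                         "dense_px": int(grid.dense_px[r, c]),
                         "regional_pd": float(grid.regional_pd[r, c]),
                         "empty": bool(grid.empty[r, c])})
    return rows


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """Run segmentation, gridding, zoning and Moran's I over a manifest,
    then the cohort comparisons; write all tables under ``output_dir``.

    Deterministic given the configuration (the per-image analysis has no
    randomness; the seed feeds any downstream permutation testing).
    """
    manifest_path = Path(config.manifest)
    manifest = fileio.read_manifest(manifest_path)  # fail before creating outputs
    base = manifest_path.parent

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    analyses: dict[tuple[str, str], ImageAnalysis] = {}
    meta: dict[str, dict] = {}
    regional_rows: list[dict] = []
    failures: list[dict] = []
    try:
        for _, row in manifest.iterrows():
            sid, lat, tp = str(row["subject_id"]), str(row["laterality"]), str(row["timepoint"])
            slot = _slot(lat, tp)
            try:
                spacing = row.get("pixel_spacing_cm", None)
                spacing = float(spacing) if spacing == spacing and spacing is not None \
                    else config.pixel_spacing_cm
                image = fileio.read_image(base / str(row["path"]), spacing, lat, tp, sid)
                if "mask_path" not in row or row["mask_path"] != row["mask_path"]:
                    raise ValueError("no mask_path in manifest (masks are required inputs)")
                mask = fileio.read_mask(base / str(row["mask_path"]))
                image.pixels = to_uint8(image.pixels, mask)
                analysis = analyze_image(
                    image, mask, ncols=config.ncols, nrows=config.nrows,
                    zone_map=config.zone_map, scheme=config.weight_scheme,
                    empty_policy=config.empty_cell_policy)
            except Exception as exc:
                logger.error("image failed subject=%s slot=%s: %s", sid, slot, exc)
                failures.append({"subject_id": sid, "slot": slot, "error": str(exc)})
                continue
            analyses[(sid, slot)] = analysis
            meta.setdefault(sid, {})
            if "age_entry" in row and row["age_entry"] == row["age_entry"]:
                meta[sid]["age_entry"] = float(row["age_entry"])
            regional_rows.extend(_regional_rows(
                {"subject_id": sid, "laterality": lat, "timepoint": tp}, analysis))
            if config.write_dense_maps:
                fileio.write_mask_png(analysis.segmentation.dense_map,
                                      outdir / f"{sid}_{slot}_dense.png")
            logger.info("image ok subject=%s slot=%s threshold=%d pd=%.2f", sid, slot,
                        analysis.segmentation.threshold,
                        analysis.segmentation.overall_pd)

        records: list[SubjectRecord] = []
        for sid in manifest["subject_id"].astype(str).unique():
            slots = {s: analyses.get((sid, s)) for s in SLOTS}
            slots = {s: a for s, a in slots.items() if a is not None}
            if "left_exit" not in slots:
                logger.warning("subject %s has no left-exit image; ungrouped", sid)
                group = "ungrouped"
            else:
                group = assign_group(slots["left_exit"].segmentation.overall_pd,
                                     config.group_bin_edges)
            records.append(SubjectRecord(
                subject_id=sid, age_entry=meta.get(sid, {}).get("age_entry", math.nan),
                group=group, analyses=slots))

        per_image = records_to_frame(records)
        regional_long = pd.DataFrame(regional_rows)
        grouped = [r for r in records if r.group != "ungrouped"]
        tables: dict[str, pd.DataFrame] = {}
        if grouped:
            summary = cohort_summary(grouped)
            tables["density_summary"] = summary.density
            tables["moran_summary"] = summary.moran
            tables["zonal_tests"] = zonal_tests(grouped)
            tables["longitudinal_tests"] = longitudinal_tests(grouped)
            tables["correlation_tests"] = correlation_tests(grouped)

        per_image.to_csv(outdir / "per_image.csv", index=False)
        regional_long.to_csv(outdir / "regional_long.csv", index=False)
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        report = {
            "n_images": int(len(manifest)), "n_failures": len(failures),
            "failures": failures,
            "n_subjects": len(records),
            "group_counts": {g: int(sum(r.group == g for r in records))
                             for g in sorted({r.group for r in records})},
            "seed": config.seed,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        logger.info("run complete: %d images, %d failures", len(manifest), len(failures))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return PipelineOutput(records=records, per_image=per_image,
                          regional_long=regional_long, tables=tables,
                          failures=failures, output_dir=outdir)
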