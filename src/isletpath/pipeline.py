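"""End-to-end orchestration: tissue → cells → islets → classes → spatial →
summary.

Stage order is deliberate: cells are detected before islet objects are
instantiated section-wide, because the ≥10-cell islet filter needs the cells
first.  Every stage's random state derives from the single run seed, so a
(config, slide, seed) triple reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cells import (CellDetectionConfig, add_smoothed_features, detect_cells,
                    measure_cells)
from .classify import (SingleMeasurementClassifier, apply_object_classifier,
                       apply_threshold_classifier, classify_T_cells,
                       combine_classifiers, train_object_classifier,
                       TrainingPoints)
from .islets import (DEFAULT_SCALES_UM, create_islet_objects,
                     extract_pixel_features, train_pixel_classifier)
from .quantify import (ImmuneSummary, InsulitisCriteria, SlideSummary,
                       compute_density, infiltration_stats, islet_composition,
                       pi_ins_ratio, score_insulitis)
from .slide_io import Slide, write_measurements, write_objects_geojson
from .spatial import (CANONICAL_BINS, DistanceBins, bin_distances,
                      distance_to_islets, render_heatmap)
from .synthetic import (GroundTruth, truth_pixel_labels,
                        truth_training_points)
from .tissue import (ThresholderConfig, TissueMask, compartment_areas,
                     detect_tissue)

log = logging.getLogger(__name__)

ENDOCRINE_MARKERS = ("INS", "PI", "GCG", "CHGA", "PC1/3", "PC2", "CPE")
IMMUNE_MARKERS = ("CD45", "CD3", "CD8")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, schema-validated up front."""

    thresholder: ThresholderConfig = field(default_factory=ThresholderConfig)
    cell_detection: CellDetectionConfig = field(
        default_factory=CellDetectionConfig)
    pixel_scales_um: tuple[float, ...] = DEFAULT_SCALES_UM
    pixel_channels: tuple[str, ...] | None = None   # None → endocrine + Hoechst
    min_cells_per_islet: int = 10
    marker_thresholds: dict = field(default_factory=lambda: {
        m: 30.0 for m in ENDOCRINE_MARKERS + IMMUNE_MARKERS})
    threshold_feature: str = "Cell mean"
    immune_mode: str = "ml"                          # "threshold" or "ml"
    n_training_points: int = 100
    adjacency_radius_um: float = 15.0
    bins: DistanceBins = CANONICAL_BINS
    insulitis: InsulitisCriteria = field(default_factory=InsulitisCriteria)
    seed: int = 0

    def validate(self) -> None:
        if self.immune_mode not in ("threshold", "ml"):
            raise ValueError("immune_mode must be 'threshold' or 'ml'")
        if self.min_cells_per_islet < 1:
            raise ValueError("min_cells_per_islet must be >= 1")


@dataclass
class RunResult:
    slide_id: str
    tissue: TissueMask
    cells: pd.DataFrame
    islets: list
    endocrine_mask: np.ndarray
    summary: SlideSummary
    distance_records: dict[str, pd.DataFrame]
    bin_table: pd.DataFrame | None
    insulitis: dict
    islet_stats: pd.DataFrame
    timings_s: dict[str, float]


def run_pipeline(slide: Slide, config: RunConfig,
                 truth: GroundTruth | None = None,
                 out_dir: str | Path | None = None,
                 slide_id: str = "slide") -> RunResult:
    """Execute all stages on one slide.

    ``truth`` supplies the training annotations (pixel-label ROI and object
    training points) that an analyst would otherwise draw by hand; it is used
    for nothing else — every measurement comes from the pixels.
    """
    config.validate()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    tissue = detect_tissue(slide, config.thresholder)
    timings["tissue"] = time.perf_counter() - t0
    log.info("tissue: %.2f mm² in %d component(s)", tissue.area_mm2,
             tissue.n_components)

    t0 = time.perf_counter()
    detection = detect_cells(slide, tissue, config.cell_detection)
    cells = measure_cells(detection, slide)
    cells = add_smoothed_features(
        cells, radius_um=config.cell_detection.smoothing_radius_um)
    timings["cells"] = time.perf_counter() - t0
    log.info("cells: %d detected", len(cells))

    # --- islet pixel classifier -------------------------------------------
    t0 = time.perf_counter()
    channels = list(config.pixel_channels) if config.pixel_channels else \
        [m for m in slide.markers
         if m in ENDOCRINE_MARKERS or m == "Hoechst"]
    feats = extract_pixel_features(slide, scales_um=config.pixel_scales_um,
                                   channels=channels)
    if truth is None:
        raise ValueError("this build derives pixel-classifier training "
                         "labels from ground truth; provide `truth` or train "
                         "a classifier explicitly and use its mask")
    labels = truth_pixel_labels(truth)
    clf = train_pixel_classifier(feats, labels, seed=config.seed,
                                 scales_um=config.pixel_scales_um,
                                 channels=channels)
    islet_mask = clf.predict_mask(slide, within=tissue.mask)
    detection.cells = cells          # carry measured features forward
    islets, endocrine_mask, cells = create_islet_objects(
        islet_mask, detection, min_cells=config.min_cells_per_islet)
    timings["islets"] = time.perf_counter() - t0
    log.info("islets: %d objects (>= %d cells)", len(islets),
             config.min_cells_per_islet)

    # --- classification ----------------------------------------------------
    t0 = time.perf_counter()
    present = set(slide.markers)
    for m in ENDOCRINE_MARKERS:
        if m in present and m in config.marker_thresholds:
            cells = apply_threshold_classifier(cells, SingleMeasurementClassifier(
                feature=f"{m}: {config.threshold_feature}",
                threshold=config.marker_thresholds[m], output_class=f"{m}+"))
    if "INS+" in cells.columns and "PI+" in cells.columns:
        cells = combine_classifiers(cells, "beta", ["INS", "PI"])
        for enz in ("PC1/3", "PC2", "CPE"):
            if f"{enz}+" in cells.columns:
                cells = combine_classifiers(cells, f"beta&{enz}+",
                                            ["INS", "PI", enz])
    if "GCG+" in cells.columns:
        cells["alpha"] = cells["GCG+"]

    cells = _classify_immune(cells, slide, config, truth)
    timings["classification"] = time.perf_counter() - t0

    # --- spatial -----------------------------------------------------------
    t0 = time.perf_counter()
    immune_present = [m for m in IMMUNE_MARKERS if f"{m}+" in cells.columns]
    records: dict[str, pd.DataFrame] = {}
    bin_table = None
    if immune_present and islets:
        any_imm = np.zeros(len(cells), dtype=bool)
        for m in immune_present:
            any_imm |= cells[f"{m}+"].to_numpy(dtype=bool)
        imm_cells = cells[any_imm]
        if len(imm_cells):
            rec_all = distance_to_islets(imm_cells, islets, bins=config.bins,
                                         markers=immune_present)
            if "CD3+" in rec_all.columns and "CD3+CD8+" in cells.columns:
                sub = cells.loc[any_imm, ["cell_id", "CD3+CD8+", "CD3+CD8-"]]
                rec_all = rec_all.merge(sub, on="cell_id")
            for m in immune_present:
                records[m] = rec_all[rec_all[f"{m}+"]]
            bin_table = bin_distances(rec_all, bins=config.bins)
            # distances back onto the cell table
            cells = cells.merge(
                rec_all[["cell_id", "distance_um", "distance_bin",
                         "nearest_islet_id"]], on="cell_id", how="left")
    timings["spatial"] = time.perf_counter() - t0

    # --- quantification ----------------------------------------------------
    t0 = time.perf_counter()
    summary, islet_stats = _summarize(slide_id, slide, tissue, endocrine_mask,
                                      islets, cells, records, config)
    verdict = score_insulitis(islet_stats, config.insulitis) if len(islet_stats) \
        else {"insulitis": None, "assessable": False,
              "reason": "no islets detected",
              "qualifying_islet_ids": [], "pseudoatrophic_islet_ids": []}
    timings["quantification"] = time.perf_counter() - t0

    result = RunResult(slide_id=slide_id, tissue=tissue, cells=cells,
                       islets=islets, endocrine_mask=endocrine_mask,
                       summary=summary, distance_records=records,
                       bin_table=bin_table, insulitis=verdict,
                       islet_stats=islet_stats, timings_s=timings)
    if out_dir is not None:
        write_outputs(result, slide, config, Path(out_dir))
    return result


def _classify_immune(cells, slide, config, truth):
    present = [m for m in IMMUNE_MARKERS if m in slide.markers]
    if not present or len(cells) == 0:
        return cells

    def thr(marker):
        return SingleMeasurementClassifier(
            feature=f"{marker}: {config.threshold_feature}",
            threshold=config.marker_thresholds.get(marker, 30.0),
            output_class=f"{marker}+")

    if config.immune_mode == "threshold" or truth is None:
        for m in present:
            if m == "CD8":
                continue
            cells = apply_threshold_classifier(cells, thr(m))
        if "CD3" in present and "CD8" in present:
            cells = classify_T_cells(cells, thr("CD3"), thr("CD8"))
        return cells

    # ML path: point-trained object classifiers (points derived from truth,
    # standing in for the analyst's annotations)
    def ml(marker, subset=None, seed_off=0):
        pool = cells if subset is None else cells[subset]
        pts = truth_training_points(truth, pool, marker,
                                    config.n_training_points,
                                    seed=config.seed + seed_off)
        return train_object_classifier(cells, TrainingPoints(pts),
                                       seed=config.seed + seed_off)

    if "CD45" in present:
        cells = apply_object_classifier(cells, ml("CD45", seed_off=1))
    if "CD3" in present:
        clf_cd3 = ml("CD3", seed_off=2)
        if "CD8" in present:
            cells = apply_object_classifier(cells, clf_cd3)
            gate = cells["CD3+"].to_numpy(dtype=bool)
            clf_cd8 = ml("CD8", subset=gate, seed_off=3)
            cells = classify_T_cells(cells, clf_cd3, clf_cd8)
        else:
            cells = apply_object_classifier(cells, clf_cd3)
    return cells


def _summarize(slide_id, slide, tissue, endocrine_mask, islets, cells,
               records, config):
    t_mm2, exo_mm2, endo_mm2 = compartment_areas(tissue, endocrine_mask)
    in_islet = cells["islet_id"].to_numpy() >= 0 if len(cells) else \
        np.zeros(0, dtype=bool)
    # immune cells sitting inside an islet are not endocrine members
    imm_any = np.zeros(len(cells), dtype=bool)
    for m in IMMUNE_MARKERS:
        if f"{m}+" in cells.columns:
            imm_any |= cells[f"{m}+"].to_numpy(dtype=bool)
    member = in_islet & ~imm_any
    n_islet_cells = int(member.sum())
    has_beta = "beta" in cells.columns
    has_alpha = "alpha" in cells.columns
    n_beta = int(cells.loc[member, "beta"].sum()) if has_beta else None
    n_alpha = int(cells.loc[member, "alpha"].sum()) if has_alpha else None

    # per-islet stats
    stats_rows = []
    ratios = []
    for islet in islets:
        comp = islet_composition(islet, cells)
        row = {"islet_id": islet.id, "n_cells": comp.n_cells,
               "area_um2": comp.area_um2,
               "equivalent_diameter_um": islet.equivalent_diameter_um,
               "n_beta": comp.counts.get("beta", np.nan),
               "n_alpha": comp.counts.get("alpha", np.nan),
               "n_INS": comp.counts.get("INS+", np.nan)
               if "INS+" in cells.columns else np.nan,
               "n_PI": comp.counts.get("PI+", np.nan),
               "cell_density_per_mm2": comp.cell_density_per_mm2}
        r = pi_ins_ratio(comp)
        if r is not None:
            ratios.append(r)
        stats_rows.append(row)
    islet_stats = pd.DataFrame(stats_rows)
    if "n_INS" in islet_stats.columns and islet_stats["n_INS"].isna().all():
        islet_stats = islet_stats.drop(columns=["n_INS"])

    # per-islet immune counts (within or adjacent) for the insulitis score
    for marker, key in (("CD45", "cd45_count"), ("CD3", "cd3_count")):
        if marker in records and len(islet_stats):
            rec = records[marker]
            near = rec[rec["distance_um"].to_numpy(dtype=float)
                       <= config.adjacency_radius_um]
            counts = near.groupby("nearest_islet_id").size()
            islet_stats[key] = islet_stats["islet_id"].map(counts).fillna(0)

    immune = {}
    for marker, rec in records.items():
        n_inf, pct_inf, comp_counts = infiltration_stats(
            islets, rec, config.adjacency_radius_um)
        d = rec["distance_um"].to_numpy(dtype=float)
        strict = comp_counts["endocrine_strict"]
        bc = np.bincount(rec["distance_bin"].to_numpy(dtype=int), minlength=5)
        immune[marker] = ImmuneSummary(
            marker=marker, n_tissue=len(rec), n_endocrine=strict,
            n_endocrine_adjacent=comp_counts["endocrine_adjacent"],
            n_exocrine=len(rec) - strict,
            density_tissue=compute_density(len(rec), t_mm2),
            density_exocrine=compute_density(len(rec) - strict, exo_mm2),
            density_endocrine=compute_density(strict, endo_mm2),
            bin_counts=tuple(int(x) for x in bc),
            n_islets_infiltrated=n_inf, pct_islets_infiltrated=pct_inf)

    summary = SlideSummary(
        slide_id=slide_id, tissue_area_mm2=t_mm2, exocrine_area_mm2=exo_mm2,
        endocrine_area_mm2=endo_mm2, n_islets=len(islets),
        n_islet_cells=n_islet_cells, n_beta=n_beta, n_alpha=n_alpha,
        immune=immune, islet_table=islet_stats, pi_ins_ratios=ratios)
    summary.check_identities()
    return summary, islet_stats


def write_outputs(result: RunResult, slide: Slide, config: RunConfig,
                  out_dir: Path) -> None:
    """CSV / GeoJSON / PNG / manifest outputs for one run."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_measurements(result.cells, out_dir / "detection_measurements.csv")
    write_objects_geojson(result.islets, [], out_dir / "islets.geojson")
    pd.DataFrame([result.summary.to_row()]).to_csv(
        out_dir / "slide_summary.csv", index=False)
    result.islet_stats.to_csv(out_dir / "islet_stats.csv", index=False)
    if result.bin_table is not None:
        result.bin_table.to_csv(out_dir / "distance_bins.csv", index=False)
    with open(out_dir / "insulitis.json", "w") as fh:
        json.dump(result.insulitis, fh, indent=2)
    h_um = slide.shape[0] * slide.mpp
    w_um = slide.shape[1] * slide.mpp
    for marker, rec in result.distance_records.items():
        if len(rec):
            render_heatmap(rec, result.cells, result.islets,
                           (w_um, h_um), slide.mpp,
                           path=out_dir / f"heatmap_{marker}.png")
    manifest = {
        "isletpath_version": __version__,
        "slide_id": result.slide_id,
        "seed": config.seed,
        "parameters": _jsonable(config),
        "counts": {
            "tissue_mm2": result.summary.tissue_area_mm2,
            "n_cells": int(len(result.cells)),
            "n_islets": len(result.islets),
        },
        "timings_s": result.timings_s,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# truth comparison

RECOVERY_TOLERANCES = {
    "tissue_area_mm2": ("rel", 0.02),
    "endocrine_area_mm2": ("rel", 0.25),
    "n_islets": ("rel", 0.05),
    "n_islet_cells": ("rel", 0.10),
    "pct_beta": ("abs", 3.0),
    "density_tissue": ("rel", 0.10),
}


def compare_to_truth(result_summary: SlideSummary,
                     oracle_summary: SlideSummary,
                     tolerances: dict | None = None) -> pd.DataFrame:
    """Per-metric (estimated, true, error, pass) recovery report."""
    tol = tolerances or RECOVERY_TOLERANCES
    rows = []

    def add(metric, est, true, tol_key=None):
        kind, t = tol.get(tol_key or metric, ("rel", np.inf))
        if true in (None, 0) and kind == "rel":
            err = np.nan if est in (None, 0) else np.inf
        elif kind == "rel":
            err = abs(est - true) / abs(true)
        else:
            err = abs(est - true)
        rows.append({"metric": metric, "estimated": est, "true": true,
                     "error": err, "tolerance": t, "kind": kind,
                     "pass": bool(err <= t) if np.isfinite(err) or err == 0
                     else est == true})

    add("tissue_area_mm2", result_summary.tissue_area_mm2,
        oracle_summary.tissue_area_mm2)
    add("endocrine_area_mm2", result_summary.endocrine_area_mm2,
        oracle_summary.endocrine_area_mm2)
    add("n_islets", result_summary.n_islets, oracle_summary.n_islets)
    add("n_islet_cells", result_summary.n_islet_cells,
        oracle_summary.n_islet_cells)
    if result_summary.pct_beta is not None and \
            oracle_summary.pct_beta is not None:
        add("pct_beta", result_summary.pct_beta, oracle_summary.pct_beta)
    for m, s in result_summary.immune.items():
        if m in oracle_summary.immune:
            add(f"{m}_density_tissue", s.density_tissue,
                oracle_summary.immune[m].density_tissue,
                tol_key="density_tissue")
    return pd.DataFrame(rows)
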