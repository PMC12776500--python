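"""End-to-end pipeline: read → classify → zone → score → summarize → test → render.

Driven by a manifest CSV (one row per embryo × bone element, as written by
:func:`misalign.synth.generate_cohort`, or assembled by hand for real
exports) plus a flat config mapping. Produces ``scores.csv``,
``medians.csv``, ``test.json`` and ``heatmap.png`` in the output directory.
Every exclusion (edge-filtered, size-filtered, zero-neighbor) is logged with
counts, since filtering materially changes n.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .classify import assign_pz, classify_by_regions, distance_to_hz, filter_cells
from .geometry import PixelCalibration
from .io import read_cells_geojson, read_regions_geojson, write_score_table
from .metrics import LmsConfig, goa_scores, lms_scores
from .stats import EmbryoSample, permutation_test, summarize_median
from .viz import HeatmapSpec, render_heatmap

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "microns_per_pixel": 0.5,
    "radius_um": 30.0,
    "min_neighbors": 1,
    "fold_mode": "folded",
    "classes": ["chondrocyte", "chondro-PZ"],
    "pz_window_um": [0.0, 400.0],
    "edge_margin_um": 0.0,
    "min_area_um2": 0.0,
    "max_area_um2": float("inf"),
    "metric": "lms",  # metric summarized/tested: "lms" | "goa"
    "n_permutations": 999,
    "seed": 0,
    "heatmap_metric": "lms",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(manifest_path: str | Path, out_dir: str | Path, config: dict | None = None) -> dict:
    """Run the full scoring pipeline over a cohort manifest.

    Returns a dict with the output paths and the permutation-test result.
    Output is a pure function of (manifest contents, config, seed).
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    calibration = PixelCalibration(cfg["microns_per_pixel"])
    metric_col = {"lms": "lms_deg", "goa": "goa_deg"}[cfg["metric"]]

    all_rows: list[pd.DataFrame] = []
    first_render = None
    for rec in manifest.to_dict("records"):
        base = manifest_path.parent
        cells = _stage("read")(read_cells_geojson)(base / rec["cells_path"], calibration)
        regions = _stage("read")(read_regions_geojson)(base / rec["regions_path"], calibration)
        classify_by_regions(cells, regions)
        distances = distance_to_hz(cells, regions)
        assign_pz(cells, distances, tuple(cfg["pz_window_um"]))
        kept, dropped = filter_cells(
            cells,
            regions,
            edge_margin=cfg["edge_margin_um"],
            min_area=cfg["min_area_um2"],
            max_area=cfg["max_area_um2"],
        )
        logger.info(
            "%s/%s: %d cells, dropped edge=%d size=%d",
            rec["embryo"], rec["element"], len(kept), dropped["edge"], dropped["size"],
        )
        lms_cfg = LmsConfig(
            radius=cfg["radius_um"],
            min_neighbors=cfg["min_neighbors"],
            fold_mode=cfg["fold_mode"],
            classes=tuple(cfg["classes"]) if cfg["classes"] else None,
        )
        scores = _stage("score")(lms_scores)(kept, lms_cfg)
        axes = {c.annotation_id: rec["axis_deg"] for c in kept}
        scores["goa_deg"] = goa_scores(
            [c for c in kept if c.id in scores.index], axes
        )
        scores["distance_to_hz_um"] = distances.reindex(scores.index)
        n_zero = int((scores["neighbor_count"] == 0).sum())
        if n_zero:
            logger.info("%s/%s: %d zero-neighbor cells (LMS undefined)",
                        rec["embryo"], rec["element"], n_zero)
        scores["group"] = rec["group"]
        scores["embryo"] = rec["embryo"]
        scores["element"] = rec["element"]
        class_map = {c.id: c.class_label for c in kept}
        scores["class_label"] = [class_map[i] for i in scores.index]
        all_rows.append(scores)
        if first_render is None:
            first_render = ([c for c in kept if c.id in scores.index], scores)

    combined = pd.concat(all_rows)
    scores_path = out_dir / "scores.csv"
    combined.rename_axis("id").reset_index().sort_values(["embryo", "element", "id"]).to_csv(
        scores_path, index=False, float_format="%.6f", lineterminator="\n"
    )

    medians = summarize_median(
        combined[metric_col].reset_index(drop=True),
        combined["embryo"].reset_index(drop=True),
        combined["element"].astype(str).reset_index(drop=True),
    )
    medians_path = out_dir / "medians.csv"
    medians.to_csv(medians_path, float_format="%.6f", lineterminator="\n")

    samples = []
    groups = combined.groupby(["embryo", "element"], sort=True)
    for (embryo, element), sub in groups:
        vals = sub[metric_col].dropna().to_numpy()
        if vals.size:
            samples.append(
                EmbryoSample(str(embryo), str(sub["group"].iloc[0]), str(element), vals)
            )
    # pool elements: one sample per embryo for the overall group test
    per_embryo: dict[str, EmbryoSample] = {}
    for s in samples:
        if s.embryo_id in per_embryo:
            prev = per_embryo[s.embryo_id]
            per_embryo[s.embryo_id] = EmbryoSample(
                s.embryo_id, s.group_label, "pooled",
                list(prev.values) + list(s.values),
            )
        else:
            per_embryo[s.embryo_id] = EmbryoSample(
                s.embryo_id, s.group_label, "pooled", s.values
            )
    result = _stage("test")(permutation_test)(
        list(per_embryo.values()), cfg["n_permutations"], cfg["seed"]
    )
    test_path = out_dir / "test.json"
    with open(test_path, "w") as fh:
        json.dump({"metric": cfg["metric"], **result.to_dict()}, fh, indent=2)

    heatmap_path = out_dir / "heatmap.png"
    cells_r, scores_r = first_render
    _stage("render")(render_heatmap)(
        cells_r, scores_r, HeatmapSpec(metric=cfg["heatmap_metric"]), heatmap_path
    )
    return {
        "scores": scores_path,
        "medians": medians_path,
        "test": test_path,
        "heatmap": heatmap_path,
        "result": result,
    }
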