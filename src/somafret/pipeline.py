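"""End-to-end orchestration: simulate/load -> preprocess -> segment ->
measure -> spatial statistics, with a fully reproducible run directory.

A run directory holds the resolved config snapshot, every intermediate
artifact (stacks, label volume, per-cell table), correlation reports for
the standard neighborhood definitions (kNN k in {2, 5, 10} and the
20 μm radius), a pseudo-color rendering, and a log with object counts at
every filter stage.  One master seed drives all randomness through
named sub-streams, so a re-run with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from . import io as sfio
from .config import PipelineConfig, subseed
from .measurement import filter_by_ratio, flag_border_rois, measure_rois
from .preprocess import preprocess_stack
from .segmentation import segment_stack
from .spatial import NeighborhoodSpec, correlate_with_neighbors, permutation_null
from .synth import OpticsParams, SyntheticScene, render_stack, write_scene

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "compare_conditions", "match_records_to_truth", "STANDARD_SPECS"]

#: The neighborhood definitions every run reports on.
STANDARD_SPECS: tuple[NeighborhoodSpec, ...] = (
    NeighborhoodSpec(mode="knn", k=2),
    NeighborhoodSpec(mode="knn", k=5),
    NeighborhoodSpec(mode="knn", k=10),
    NeighborhoodSpec(mode="radius", radius_um=20.0),
)


def _spec_key(spec: NeighborhoodSpec) -> str:
    return f"knn_{spec.k}" if spec.mode == "knn" else f"radius_{spec.radius_um:g}um"


@dataclass
class RunResult:
    """Handles to a completed run's artifacts and headline numbers."""

    run_dir: Path
    records: list[sfio.CellRecord]
    retained: list[sfio.CellRecord]
    labels: np.ndarray
    correlations: dict[str, dict]
    report: dict


def run_pipeline(
    config: PipelineConfig,
    *,
    input_stack_path: str | Path | None = None,
    scene: SyntheticScene | None = None,
    optics: OpticsParams | None = None,
    out_dir: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
    n_perm: int = 0,
    write_stacks: bool = True,
) -> RunResult:
    """Execute the full analysis on a real stack or a simulated scene.

    Exactly one of ``input_stack_path`` and ``scene`` must be given.
    ``n_perm > 0`` additionally runs the seeded permutation test for the
    default k=5 neighborhood.  ``write_stacks=False`` skips persisting
    the large raw/preprocessed stacks (tables and reports are always
    written).  Any stage failure propagates with partial outputs left in
    place.
    """
    if (input_stack_path is None) == (scene is None):
        raise ValueError("provide exactly one of input_stack_path or scene")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("somafret")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict() | {"config_hash": config.config_hash()}, indent=2, sort_keys=True)
        )
        stage = "simulate/load"
        if scene is not None:
            optics = optics or OpticsParams()
            logger.info("simulating scene: %d cells, %d distractors", len(scene.cells), len(scene.distractors))
            stack = render_stack(scene, optics, seed=subseed(config.seed, "noise"))
            stack = sfio.ImageStack(
                data=stack.data.astype(np.float32), voxel_size_um=stack.voxel_size_um
            )
            write_scene(scene, out_dir / "scene.json")
            if write_stacks:
                sfio.write_stack(stack, out_dir / "stack.tif")
        else:
            stack = sfio.read_stack(input_stack_path, voxel_size_override)

        stage = "preprocess"
        logger.info("step 1-2: top-hat (r=%d) and median (r=%d) filtering",
                    config.tophat_radius_vox, config.median_radius_vox)
        pre = preprocess_stack(
            stack, config.tophat_radius_vox, config.median_radius_vox, three_d=config.filter_3d
        )
        pre = sfio.ImageStack(data=pre.data.astype(np.float32), voxel_size_um=pre.voxel_size_um)
        if write_stacks:
            sfio.write_stack(pre, out_dir / "preprocessed.tif")

        stage = "segment"
        logger.info("step 3-4: 3D iterative thresholding (MSER) and opening filter")
        labels, removed = segment_stack(
            pre,
            threshold_levels=config.threshold_levels,
            volume_min_vox=config.volume_min_vox,
            volume_max_vox=config.volume_max_vox,
            delta_levels=config.delta_levels,
            opening_radius_vox=config.opening_radius_vox,
        )
        sfio.write_labels(labels, out_dir / "labels.tif")

        stage = "measure"
        records = measure_rois(pre, labels, excluded=removed)
        if config.exclude_border:
            records = flag_border_rois(records, labels)
        retained, excluded = filter_by_ratio(records, config.ratio_threshold)
        all_records = sorted(retained + excluded, key=lambda r: r.label)
        sfio.write_records_table(all_records, out_dir / "records.csv")
        counts: dict[str, int] = {}
        for r in all_records:
            counts[r.excluded_reason] = counts.get(r.excluded_reason, 0) + 1
        n_initial = len(all_records)
        logger.info(
            "filter audit: %d initial ROIs = %d retained + %s excluded",
            n_initial, len(retained),
            {k: v for k, v in sorted(counts.items()) if k != "none"},
        )

        stage = "spatial"
        correlations: dict[str, dict] = {}
        cent = np.array([r.centroid_um for r in retained]).reshape(-1, 3)
        labs = [r.label for r in retained]
        ratios = [r.ratio_720_670 for r in retained]
        for spec in STANDARD_SPECS:
            key = _spec_key(spec)
            try:
                result, table = correlate_with_neighbors(
                    labs, cent, ratios, spec, alpha=config.alpha,
                    projected_2d=config.distances_2d,
                )
                entry = result.to_dict() | {"spec": spec.describe()}
                table.to_csv(out_dir / f"scatter_{key}.csv", index=False, float_format="%.17g")
            except ValueError as exc:
                entry = {"spec": spec.describe(), "error": str(exc)}
            correlations[key] = entry
        if n_perm > 0 and len(retained) >= 6:
            p_emp, _, _ = permutation_null(
                labs, cent, ratios, NeighborhoodSpec(mode="knn", k=config.neighbor_k),
                n_perm=n_perm, seed=subseed(config.seed, "permutation"),
                projected_2d=config.distances_2d,
            )
            correlations[f"knn_{config.neighbor_k}"]["permutation_p"] = p_emp

        stage = "render"
        if retained:
            rs = [r.ratio_720_670 for r in retained]
            lo, hi = min(rs), max(rs)
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            sfio.render_pseudocolor(retained, labels, (lo, hi), out_dir / "pseudocolor.png")

        report = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_initial_rois": n_initial,
            "n_retained": len(retained),
            "n_excluded_by_reason": {k: v for k, v in sorted(counts.items()) if k != "none"},
            "mean_retained_ratio": (
                float(np.mean([r.ratio_720_670 for r in retained])) if retained else None
            ),
            "correlations": correlations,
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return RunResult(
            run_dir=out_dir,
            records=all_records,
            retained=retained,
            labels=labels,
            correlations=correlations,
            report=report,
        )
    except Exception:
        logger.exception("pipeline stage %r failed; partial outputs kept in %s", stage, out_dir)
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def compare_conditions(run_a: str | Path, run_b: str | Path) -> dict:
    """Compare two completed runs (e.g. pre/post inhibitor).

    Reports each run's mean retained ratio, the relative difference in
    percent (positive when run B is lower than run A), and both runs'
    correlation results side by side; flags any config mismatch.
    """
    run_a, run_b = Path(run_a), Path(run_b)
    out: dict = {}
    reports = []
    for run in (run_a, run_b):
        rp = run / "report.json"
        if not rp.exists():
            raise FileNotFoundError(f"missing report.json in run directory {run}")
        reports.append(json.loads(rp.read_text()))
    cfgs = []
    for run in (run_a, run_b):
        cp = run / "config.json"
        if not cp.exists():
            raise FileNotFoundError(f"missing config.json in run directory {run}")
        cfg = json.loads(cp.read_text())
        cfg.pop("seed", None)
        cfg.pop("config_hash", None)
        cfgs.append(cfg)
    mean_a = reports[0]["mean_retained_ratio"]
    mean_b = reports[1]["mean_retained_ratio"]
    if mean_a is None or mean_b is None:
        raise ValueError("one of the runs retained no cells; cannot compare")
    out["mean_ratio_a"] = mean_a
    out["mean_ratio_b"] = mean_b
    out["relative_difference_pct"] = 100.0 * (mean_a - mean_b) / mean_a
    out["correlations_a"] = reports[0]["correlations"]
    out["correlations_b"] = reports[1]["correlations"]
    out["config_mismatch"] = cfgs[0] != cfgs[1]
    if out["config_mismatch"]:
        diff = {
            k: (cfgs[0].get(k), cfgs[1].get(k))
            for k in set(cfgs[0]) | set(cfgs[1])
            if cfgs[0].get(k) != cfgs[1].get(k)
        }
        out["config_diff"] = diff
        logger.warning("compared runs use different configs: %s", diff)
    return out


def match_records_to_truth(
    records: list[sfio.CellRecord],
    scene: SyntheticScene,
    max_distance_factor: float = 1.0,
) -> dict:
    """One-to-one greedy matching of retained ROIs to planted cells.

    An ROI matches a planted cell when its centroid lies within
    ``max_distance_factor x`` that cell's soma radius; pairs are matched
    greedily by ascending distance, each cell and each ROI used at most
    once.  Returns recovery/spurious counts and the matched
    (true_ratio, measured_ratio) pairs — the basis of the segmentation-
    recovery and ratio-fidelity validations.
    """
    retained = [r for r in records if r.retained]
    n_cells = len(scene.cells)
    if not retained or n_cells == 0:
        return {
            "n_true_cells": n_cells,
            "n_retained_rois": len(retained),
            "n_matched": 0,
            "recovery_rate": 0.0,
            "spurious_rate": 1.0 if retained else 0.0,
            "pairs": [],
        }
    roi_cent = np.array([r.centroid_um for r in retained])
    true_cent = scene.cell_centers()
    d = cdist(roi_cent, true_cent)
    radii = np.array([c.radius_um for c in scene.cells])
    cand = np.argwhere(d <= max_distance_factor * radii[None, :])
    order = np.argsort(d[cand[:, 0], cand[:, 1]], kind="stable")
    used_roi: set[int] = set()
    used_cell: set[int] = set()
    pairs = []
    for ri, ci in cand[order]:
        ri, ci = int(ri), int(ci)
        if ri in used_roi or ci in used_cell:
            continue
        used_roi.add(ri)
        used_cell.add(ci)
        pairs.append(
            {
                "label": retained[ri].label,
                "true_ratio": scene.cells[ci].true_ratio,
                "measured_ratio": retained[ri].ratio_720_670,
                "distance_um": float(d[ri, ci]),
            }
        )
    n_matched = len(pairs)
    return {
        "n_true_cells": n_cells,
        "n_retained_rois": len(retained),
        "n_matched": n_matched,
        "recovery_rate": n_matched / n_cells,
        "spurious_rate": (len(retained) - n_matched) / len(retained),
        "pairs": pairs,
    }
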