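"""End-to-end analysis: image(s) in, morphometry table and group report out.

The stage order is fixed: normalize → flatten illumination → top-hat →
adaptive threshold → artifact removal → skeletonize (with branching points)
→ summarize → group statistics.  Runs are deterministic for fixed inputs and
configuration; every output table embeds the configuration hash and package
version.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import FibrometryError
from .io import read_image, write_csv, write_image, write_json
from .morphometry import MorphometrySummary, skeletonize, summarize
from .preprocessing import (
    CalibratedImage,
    flatten_illumination,
    normalize_and_orient,
    tophat_enhance,
)
from .segmentation import (
    BinaryMask,
    adaptive_threshold,
    fill_small_holes,
    remove_artifacts,
)
from .stats import group_summary, ttest

__all__ = [
    "PARAMETER_COLUMNS",
    "process_image",
    "analyze_images",
    "compare_groups",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: morphometric parameters reported per image, with their physical units
PARAMETER_COLUMNS = {
    "positive_area_pct": "%",
    "bp_density_per_mm2": "/mm2",
    "total_length_mm": "mm",
    "mean_thickness_um": "um",
}

_CSV_COLUMNS = [
    "image",
    "group",
    "positive_area_pct",
    "bp_density_per_mm2",
    "total_length_mm",
    "mean_thickness_um",
    "n_branch_points",
    "image_area_mm2",
    "config_hash",
]


def process_image(
    image: np.ndarray | CalibratedImage,
    config: PipelineConfig,
    exclusion_mask: BinaryMask | None = None,
    return_intermediates: bool = False,
):
    """Run the full single-image chain and return its morphometry summary.

    ``image`` is either a raw 8-/16-bit array (calibrated by
    ``config.um_per_px``) or an already calibrated image.  With
    ``return_intermediates`` the per-stage images are returned as well, for
    debugging and visual QC.
    """
    t0 = time.perf_counter()
    oriented = normalize_and_orient(
        image, None if isinstance(image, CalibratedImage) else config.um_per_px
    )
    flat = flatten_illumination(oriented, config.background_scale_px)
    enhanced = tophat_enhance(flat, config.tophat_radius_px)
    raw_mask = adaptive_threshold(
        enhanced, config.threshold_window_px, config.threshold_offset
    )
    mask = remove_artifacts(
        raw_mask,
        min_object_px=config.min_object_px,
        circularity_cutoff=config.circularity_cutoff,
        exclusion_mask=exclusion_mask,
    )
    mask = fill_small_holes(mask, config.fill_holes_px)
    skel = skeletonize(
        mask,
        prune_spurs_px=config.skeleton_prune_px,
        bp_merge_radius_px=config.bp_merge_radius_px,
    )
    summary = summarize(mask, skel, estimator=config.length_estimator)
    logger.info(
        "processed image: %d fg px, %d bp, %.3f mm, %.1f ms (config %s)",
        summary.n_foreground_px,
        summary.n_branch_points,
        summary.total_length_mm,
        1e3 * (time.perf_counter() - t0),
        config.config_hash(),
    )
    if return_intermediates:
        return summary, {
            "normalized": oriented,
            "flattened": flat,
            "tophat": enhanced,
            "raw_mask": raw_mask,
            "mask": mask,
            "skeleton": skel,
        }
    return summary


def _summary_row(name: str, group: str, s: MorphometrySummary, cfg_hash: str) -> dict:
    return {
        "image": name,
        "group": group,
        "positive_area_pct": s.positive_area_pct,
        "bp_density_per_mm2": s.bp_density_per_mm2,
        "total_length_mm": s.total_length_mm,
        "mean_thickness_um": s.mean_thickness_um,
        "n_branch_points": s.n_branch_points,
        "image_area_mm2": s.image_area_mm2,
        "config_hash": cfg_hash,
    }


def analyze_images(
    items: Iterable[tuple[str, str, np.ndarray | CalibratedImage]],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Process ``(name, group, image)`` items into a per-image table."""
    cfg_hash = config.config_hash()
    rows = [
        _summary_row(name, group, process_image(img, config), cfg_hash)
        for name, group, img in items
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def compare_groups(per_image: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Two-group statistics table: means, SEMs, n, t, df, p per parameter."""
    groups = sorted(per_image["group"].unique())
    if len(groups) != 2:
        raise FibrometryError(
            f"group comparison requires exactly 2 groups, got {groups}"
        )
    ga, gb = groups
    rows = []
    comparisons = list(PARAMETER_COLUMNS.items())
    if len(comparisons) > 4:
        logger.warning(
            "%d comparisons without multiple-testing correction", len(comparisons)
        )
    for param, units in comparisons:
        a = group_summary(
            per_image.loc[per_image["group"] == ga, param], param, units
        )
        b = group_summary(
            per_image.loc[per_image["group"] == gb, param], param, units
        )
        res = ttest(a, b, variant=config.ttest_variant)
        rows.append(
            {
                "parameter": param,
                "units": units,
                "group_a": ga,
                "group_b": gb,
                "n_a": a.n,
                "n_b": b.n,
                "mean_a": a.mean,
                "sem_a": a.sem,
                "mean_b": b.mean,
                "sem_b": b.sem,
                "t_statistic": res.t_statistic,
                "df": res.df,
                "p_value": res.p_value,
                "variant": res.variant,
                "config_hash": config.config_hash(),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    images: Sequence[tuple[str | Path, str]],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    save_intermediates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Analyze image files with group labels; optionally write result tables.

    ``images`` is a sequence of ``(path, group_label)`` pairs.  Unreadable
    images are skipped with a logged error; if all fail a
    :class:`FibrometryError` is raised.  When two groups are present a group
    statistics table is produced as well.  Outputs (``per_image.csv``,
    ``group_stats.csv``, ``report.json``) land in ``out_dir``.
    """
    rows = []
    failures = []
    cfg_hash = config.config_hash()
    for path, group in images:
        path = Path(path)
        try:
            raw = read_image(path)
        except (OSError, FibrometryError) as exc:
            logger.error("skipping %s: %s", path, exc)
            failures.append(str(path))
            continue
        if save_intermediates and out_dir is not None:
            summary, inter = process_image(raw, config, return_intermediates=True)
            stem = Path(out_dir) / "intermediates" / path.stem
            for stage in ("normalized", "flattened", "tophat"):
                write_image(f"{stem}_{stage}.tif", inter[stage].pixels)
            write_image(f"{stem}_mask.tif", inter["mask"].mask.astype(np.uint8) * 255)
            write_image(
                f"{stem}_skeleton.tif",
                inter["skeleton"].skeleton.astype(np.uint8) * 255,
            )
        else:
            summary = process_image(raw, config)
        rows.append(_summary_row(path.name, group, summary, cfg_hash))
    if not rows:
        raise FibrometryError(f"no readable images among {len(failures)} input(s)")
    per_image = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    stats_table = None
    counts = per_image["group"].value_counts()
    if len(counts) == 2 and counts.min() >= 2:
        stats_table = compare_groups(per_image, config)
    if out_dir is not None:
        out = Path(out_dir)
        write_csv(out / "per_image.csv", per_image)
        report = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": cfg_hash,
            "n_images": len(rows),
            "failed_images": failures,
            "coordinate_convention": "(row, col), 0-based, origin top-left",
        }
        if stats_table is not None:
            write_csv(out / "group_stats.csv", stats_table)
            report["group_stats"] = stats_table.to_dict(orient="records")
        write_json(out / "report.json", report)
    return per_image, stats_table
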