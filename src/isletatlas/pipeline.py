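"""Pipeline orchestration: simulate -> segment -> quantify -> report.

A run is driven by a validated configuration (YAML on disk or a plain
dict): either a phantom preset + seed, or input volume paths with a
channel map. All stages are single-process and deterministic under a
fixed seed; every reported number in the text report is read from a
table cell, never recomputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import io, phantom, segmentation, spatial, stats
from .grid import StudyResult, VoxelGrid

log = logging.getLogger("isletatlas")

_SCHEMA: dict[str, dict] = {
    "input": {"path", "channels", "voxel_size_um", "magnification_tag",
              "region_mask_path", "preset", "seed", "noise"},
    "segmentation": {"largest_islet_diameter_um", "nerve_channel",
                     "min_islet_volume_um3", "min_nerve_volume_um3",
                     "intensity_threshold", "connectivity"},
    "spatial": {"distance_cutoff_um", "ganglion_volume_range_um3",
                "ganglion_min_sphericity", "ganglion_background_diameter_um",
                "cell_diameter_um", "detect_ganglia"},
    "stats": {"alpha", "per_animal", "batch"},
    "output": {"dir", "qc_mip", "log_level"},
}


def validate_config(config: dict) -> dict:
    """Validate a pipeline config against the schema; unknown sections or
    keys are rejected before any compute."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for section, content in config.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise ValueError(
                f"unknown keys in [{section}]: {sorted(unknown)}")
    inp = config.get("input", {})
    if "path" not in inp and "preset" not in inp:
        raise ValueError("config [input] needs either 'path' or 'preset'")
    if "path" in inp and "channels" not in inp:
        raise ValueError("config [input] with a path needs a channel map")
    return config


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg or {})


def _acquire(config: dict) -> tuple[VoxelGrid, phantom.PhantomGroundTruth | None]:
    inp = config.get("input", {})
    if "preset" in inp:
        pcfg = phantom.preset(inp["preset"])
        if not inp.get("noise", True):
            pcfg.poisson_scale = 0.0
            pcfg.gaussian_sigma = 0.0
        grid, truth = phantom.simulate(pcfg, int(inp.get("seed", 0)))
        return grid, truth
    grid = io.read_volume(
        inp["path"],
        channel_names=inp.get("channels"),
        voxel_size_um=inp.get("voxel_size_um"),
        magnification_tag=inp.get("magnification_tag", "custom"),
    )
    if inp.get("region_mask_path"):
        grid.region_mask = io.read_mask(inp["region_mask_path"])
    return grid, None


def run(config: dict) -> StudyResult:
    """Execute the full low-resolution pipeline for one sample.

    Stages: acquire (file or phantom preset), islet segmentation, nerve
    segmentation, distance-transform innervation metrics, optional
    ganglion detection, per-region summary. Any stage error aborts with
    the stage name attached.
    """
    config = validate_config(config)
    seg_cfg = config.get("segmentation", {})
    sp_cfg = config.get("spatial", {})
    out_cfg = config.get("output", {})

    stage = "acquire"
    try:
        grid, truth = _acquire(config)
        nerve_channel = seg_cfg.get("nerve_channel")
        if nerve_channel is None:
            nerve_channel = next(
                (c for c in ("nf200", "th", "vacht") if grid.has_channel(c)),
                None)

        stage = "segment_islets"
        islets = segmentation.segment_islets(
            grid,
            largest_islet_diameter_um=seg_cfg.get(
                "largest_islet_diameter_um",
                segmentation.DEFAULT_LARGEST_ISLET_DIAMETER_UM),
            min_object_volume_um3=seg_cfg.get("min_islet_volume_um3", 0.0),
        )
        log.info("segmented %d islets", islets.n_objects)

        # output paths are excluded so identical analyses written to
        # different directories produce identical bytes
        result = StudyResult(params={"config": {
            k: v for k, v in config.items() if k != "output"}})
        nerve_mask = np.zeros(grid.shape, dtype=bool)
        if nerve_channel is not None:
            stage = "segment_nerves"
            nerves = segmentation.segment_nerves(
                grid, nerve_channel,
                min_object_volume_um3=seg_cfg.get("min_nerve_volume_um3", 0.0))
            nerve_mask = nerves.mask
            log.info("segmented %d nerve objects", nerves.n_objects)

        stage = "islet_nerve_distances"
        records = spatial.islet_nerve_distances(
            islets, nerve_mask,
            distance_cutoff_um=sp_cfg.get("distance_cutoff_um",
                                          spatial.NEAR_NERVE_CUTOFF_UM))
        result.tables["islets"] = records

        if len(records):
            stage = "classify_innervation"
            result.tables["innervation"] = spatial.classify_innervation(records)
            result.tables["innervated_comparison"] = (
                stats.innervated_comparison(records))

        stage = "region_summary"
        result.tables["summary"] = stats.region_summary(
            records, nerve_mask, islets.mask, grid.tissue_mask(),
            grid.voxel_size_um, grid.region_mask)

        if sp_cfg.get("detect_ganglia", True) and nerve_channel is not None:
            stage = "ganglia"
            ganglia = segmentation.segment_ganglia(
                grid, nerve_channel,
                volume_range_um3=tuple(sp_cfg.get(
                    "ganglion_volume_range_um3", (20_000.0, 400_000.0))),
                min_sphericity=sp_cfg.get("ganglion_min_sphericity", 0.4),
                background_diameter_um=sp_cfg.get(
                    "ganglion_background_diameter_um",
                    segmentation.GANGLION_BACKGROUND_DIAMETER_UM))
            gtable, density = spatial.ganglion_metrics(
                ganglia, islets.mask, grid.tissue_mask(), grid.voxel_size_um)
            result.tables["ganglia"] = gtable
            result.stats["ganglion_density_per_mm3"] = density

        if truth is not None:
            result.params["phantom_realized"] = truth.realized
        result.params["voxel_size_um"] = list(grid.voxel_size_um)

        if out_cfg.get("dir"):
            stage = "write"
            io.write_results(result, out_cfg["dir"])
            if out_cfg.get("qc_mip", True):
                for ch in grid.channels:
                    io.save_mip_png(grid, ch,
                                    f"{out_cfg['dir']}/qc_mip_{ch}.png")
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def group_stats(per_sample: pd.DataFrame, metrics: list[str],
                group_col: str = "group") -> dict:
    """Run the normality-gated comparison for each metric of a per-sample
    table; returns metric -> GroupStatsResult dict.

    Staining-intensity metrics are only comparable within one staining
    batch; mixing batches for an intensity metric is refused.
    """
    out = {}
    for m in metrics:
        if "intensity" in m and "batch" in per_sample.columns:
            if per_sample["batch"].nunique() > 1:
                raise ValueError(
                    f"intensity metric {m!r} cannot be compared across "
                    "staining batches; subset to one batch first")
        out[m] = stats.group_compare(per_sample, m, group_col).to_dict()
    return out


def report(result: StudyResult) -> str:
    """One-page markdown summary of a StudyResult.

    Every number is read from a table cell; the reporter performs no
    computation of its own.
    """
    if not result.tables:
        raise ValueError("empty StudyResult")
    lines = ["# isletatlas run summary", ""]
    summary = result.tables.get("summary")
    if summary is not None and len(summary):
        lines.append("## Regional summary")
        cols = [
            ("beta_volume_percent", "beta cell volume (%)"),
            ("islets_per_mm3", "islets / mm^3"),
            ("median_islet_volume_um3", "median islet volume (um^3)"),
            ("endocrine_nerve_density_percent", "endocrine nerve density (%)"),
            ("exocrine_nerve_density_percent", "exocrine nerve density (%)"),
            ("innervated_fraction_percent", "innervated islets (%)"),
            ("innervated_share_percent", "innervated share of islet volume (%)"),
        ]
        for _, row in summary.iterrows():
            lines.append(f"### region: {row['region']}")
            for col, label in cols:
                if col in row and pd.notna(row[col]):
                    lines.append(f"- {label}: {row[col]:.4g}")
            bins = [c for c in summary.columns if c.startswith("volume_bin")]
            if bins:
                vals = ", ".join(f"{row[b]:.2f}" for b in bins)
                lines.append(f"- volume-bin percentages: {vals}")
            lines.append("")
    inn = result.tables.get("innervation")
    if inn is not None and len(inn):
        lines.append("## Innervation partition")
        for _, row in inn.iterrows():
            lines.append(
                f"- {row['region']}: {row['innervated_percent']:.2f}% of "
                f"{row['n_islets']} islets contact a nerve; "
                f"{row['near_nerve_percent']:.2f}% are within the near-nerve "
                "cutoff")
        lines.append("")
    comp = result.tables.get("innervated_comparison")
    if comp is not None and len(comp):
        lines.append("## Innervated vs non-innervated islets")
        for _, row in comp.iterrows():
            if pd.notna(row["mean_volume_ratio"]):
                lines.append(
                    f"- {row['region']}: mean volume ratio "
                    f"{row['mean_volume_ratio']:.2f}-fold; innervated share "
                    f"{row['innervated_share_percent']:.2f}%")
            else:
                lines.append(f"- {row['region']}: ratio undefined "
                             "(one class absent)")
        lines.append("")
    gang = result.tables.get("ganglia")
    if gang is not None:
        lines.append("## Intrapancreatic ganglia")
        lines.append(f"- count: {len(gang)}")
        if "ganglion_density_per_mm3" in result.stats:
            lines.append(
                f"- density: {result.stats['ganglion_density_per_mm3']:.2f} "
                "per mm^3")
        lines.append("")
    for metric, block in result.stats.items():
        if isinstance(block, dict) and "test" in block:
            lines.append(f"## {metric}")
            lines.append(f"- test: {block['test']}; p = {block['p_value']:.4g}"
                         f" ({'significant' if block['significant'] else 'ns'})")
            lines.append("")
    return "\n".join(lines)
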