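"""Reading and writing volumes (OME-TIFF / TIFF) and result tables.

Volumes are stored channel-first (``CZYX``); voxel sizes are carried in
OME ``PhysicalSize*`` attributes so a written grid round-trips with its
calibration. Result tables are plain CSV (UTF-8, '.' decimal) plus a
JSON stats file and a JSON manifest.
"""

from __future__ import annotations

import json
import os
import re

import numpy as np
import tifffile

from .grid import StudyResult, VoxelGrid


def _ome_physical_sizes(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (z, y, x) physical sizes in um from OME metadata, if present."""
    xml = tif.ome_metadata
    if not xml:
        return None
    sizes = {}
    for axis in "XYZ":
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', xml)
        if m:
            sizes[axis] = float(m.group(1))
    if {"X", "Y", "Z"} <= sizes.keys():
        return (sizes["Z"], sizes["Y"], sizes["X"])
    return None


def read_volume(
    path: str,
    channel_names: list[str] | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
    magnification_tag: str = "custom",
) -> VoxelGrid:
    """Read a TIFF / OME-TIFF stack into a :class:`VoxelGrid`.

    An explicit ``voxel_size_um`` overrides OME metadata; if neither is
    available a ``ValueError`` is raised (the pipeline is meaningless
    without physical calibration).
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_size = _ome_physical_sizes(tif)

    # Normalize to (C, Z, Y, X); accept ZYX, CZYX and ZCYX layouts.
    if axes in ("ZYX", "QYX", "IYX"):
        data = data[None]
    elif axes == "CZYX":
        pass
    elif axes == "ZCYX":
        data = np.moveaxis(data, 1, 0)
    elif data.ndim == 3:
        data = data[None]
    elif data.ndim != 4:
        raise ValueError(f"unsupported TIFF axes {axes!r} in {path}")

    if voxel_size_um is None:
        voxel_size_um = meta_size
    if voxel_size_um is None:
        raise ValueError(
            f"missing voxel size: {path} has no OME physical sizes and no "
            "explicit voxel_size_um was given"
        )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[0])]
    if len(channel_names) != data.shape[0]:
        raise ValueError(
            f"channel-count mismatch: file has {data.shape[0]} channels, "
            f"{len(channel_names)} names given"
        )
    # Integer inputs (8/16-bit cameras) are promoted to float32 internally.
    data = np.asarray(data, dtype=np.float32)
    return VoxelGrid(
        data=data,
        channels=list(channel_names),
        voxel_size_um=tuple(voxel_size_um),
        magnification_tag=magnification_tag,
    )


def write_volume(grid: VoxelGrid, path: str) -> None:
    """Write a grid as OME-TIFF, preserving channel order and voxel size."""
    z, y, x = grid.voxel_size_um
    tifffile.imwrite(
        path,
        grid.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": x,
            "PhysicalSizeY": y,
            "PhysicalSizeZ": z,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(grid.channels)},
        },
    )


def write_mask(mask: np.ndarray, path: str) -> None:
    """Write an integer mask (e.g. region sidecar) as plain TIFF."""
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask(path: str) -> np.ndarray:
    return tifffile.imread(path)


def max_projection(grid: VoxelGrid, channel: str) -> np.ndarray:
    """Maximum-intensity projection along z, for QC rendering only."""
    return grid.channel(channel).max(axis=0)


def save_mip_png(grid: VoxelGrid, channel: str, path: str) -> None:
    """Save a QC maximum-intensity projection as an 8-bit PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mip = max_projection(grid, channel)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mip, cmap="magma", interpolation="nearest")
    ax.set_title(f"MIP {channel}")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_results(result: StudyResult, out_dir: str) -> list[str]:
    """Write every table of a :class:`StudyResult` to ``out_dir``.

    Tables go to ``<name>.csv`` (RFC-4180, header row, '.' decimal),
    stats and parameters to JSON, and a ``manifest.json`` lists every
    file written. Re-running with identical input produces identical
    bytes. Returns the manifest as a list of file names.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: list[str] = []
    for name, table in sorted(result.tables.items()):
        if table is None:
            continue
        fname = f"{name}.csv"
        table.to_csv(os.path.join(out_dir, fname), index=False, lineterminator="\n")
        manifest.append(fname)
    if result.stats:
        with open(os.path.join(out_dir, "stats.json"), "w") as fh:
            json.dump(result.stats, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        manifest.append("stats.json")
    if result.params:
        with open(os.path.join(out_dir, "params.json"), "w") as fh:
            json.dump(result.params, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        manifest.append("params.json")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump({"files": manifest}, fh, indent=2)
        fh.write("\n")
    return manifest
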