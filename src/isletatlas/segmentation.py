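"""Surface-style segmentation of islets, nerves, ganglia and cells.

The commercial workflow this package replaces builds "surfaces" with a
local-contrast background subtraction controlled by two physical scales:
a *background diameter* (structures larger than this are treated as
background; called the threshold factor in the original software) and a
*smoothing factor* (the detail grain of the surface). Both are realized
here as Gaussian operations in physical units so that results are
independent of voxel pitch and anisotropy:

1. pre-smoothing with FWHM = smoothing factor,
2. baseline estimate = blur with sigma = background_diameter / 2,
3. subtraction clamped at zero,
4. Otsu threshold (or an absolute override),
5. connected components with per-object morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .grid import VoxelGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SegmentationParams:
    """Physical-unit parameters of the surface segmentation.

    ``background_diameter_um`` is the scale above which structure is
    considered background (the original software's "threshold factor");
    ``smoothing_um`` the pre-smoothing FWHM ("smoothing factor").
    ``intensity_threshold`` is ``"auto_otsu"`` or an absolute value on
    the background-subtracted image.
    """

    channel: str
    background_diameter_um: float
    smoothing_um: float = 0.0
    intensity_threshold: float | str = "auto_otsu"
    min_object_volume_um3: float = 0.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.background_diameter_um <= self.smoothing_um:
            raise ValueError("background_diameter_um must exceed smoothing_um")
        if self.smoothing_um < 0:
            raise ValueError("smoothing_um must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


#: Largest expected islet diameter; the islet background scale defaults to
#: this per-dataset value (the original analysis set it per sample).
DEFAULT_LARGEST_ISLET_DIAMETER_UM = 250.0

#: Nerve-fiber background scale in um.
NERVE_BACKGROUND_DIAMETER_UM = 12.2

#: Surface smoothing factors by magnification (um).
ISLET_SMOOTHING_UM = {"1.3x": 10.0, "4x": 3.25, "12x": 3.25, "confocal10x": 3.25}
NERVE_SMOOTHING_UM = 3.25

#: Blob-preserving background scale used when hunting ganglion-sized
#: NF200+ objects (the 12.2 um nerve scale suppresses their interiors).
GANGLION_BACKGROUND_DIAMETER_UM = 150.0

#: TH+ beta cells masquerading as nerve objects are excluded below this
#: volume when they sit inside an insulin+ islet and overlap insulin.
TH_BETA_CELL_VOLUME_UM3 = 120.0


@dataclass
class LabeledObjects:
    """Integer label grid plus a per-object morphometry table.

    The table has one row per object id (contiguous from 1) with voxel
    count, ``volume_um3`` (= count x voxel volume exactly), centroid in
    um, per-channel intensity sum/mean, region id and a border flag.
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size_um: tuple[float, float, float]

    @property
    def n_objects(self) -> int:
        return len(self.table)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def __len__(self) -> int:
        return self.n_objects


def _blur(img: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Gaussian blur; large sigmas use a 3-pass box-filter approximation.

    Three box passes of width w ~ sigma*sqrt(12/3) converge to a Gaussian
    and run in O(N) independent of sigma, which matters for the ~25-voxel
    background scales of whole-pancreas islet presets.
    """
    sigma_vox = np.asarray(sigma_vox, dtype=float)
    if sigma_vox.max() <= 8.0:
        return ndi.gaussian_filter(img, sigma_vox, mode="nearest")
    out = img.astype(np.float32, copy=True)
    sizes = np.maximum(np.round(sigma_vox * 2.0).astype(int) | 1, 1)
    for _ in range(3):
        out = ndi.uniform_filter(out, size=tuple(sizes), mode="nearest")
    return out


def local_contrast_threshold(
    grid: VoxelGrid, params: SegmentationParams
) -> np.ndarray:
    """Local-contrast background subtraction + threshold -> binary mask.

    Constant (spatially uniform) images yield an empty mask: background
    subtraction removes any flat offset before thresholding.
    """
    img = grid.channel(params.channel).astype(np.float32)
    vs = np.asarray(grid.voxel_size_um, dtype=float)
    if params.background_diameter_um < vs.max():
        raise ValueError(
            f"background diameter {params.background_diameter_um} um is below "
            f"one voxel ({tuple(vs)} um)"
        )
    if params.smoothing_um > 0:
        img = _blur(img, params.smoothing_um * FWHM_TO_SIGMA / vs)
    baseline = _blur(img, (params.background_diameter_um / 2.0) / vs)
    sub = np.clip(img - baseline, 0.0, None)
    if sub.max() <= 0:
        return np.zeros(grid.shape, dtype=bool)
    if params.intensity_threshold == "auto_otsu":
        thr = threshold_otsu(sub)
    else:
        thr = float(params.intensity_threshold)
    return sub > thr


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def _region_majority(labels: np.ndarray, n: int, region_mask: np.ndarray) -> np.ndarray:
    """Majority region code per object (0..2), vectorized via bincount."""
    fg = labels > 0
    lab = labels[fg].astype(np.int64)
    reg = region_mask[fg].astype(np.int64)
    nreg = int(reg.max()) + 1 if reg.size else 1
    counts = np.bincount(lab * nreg + reg, minlength=(n + 1) * nreg)
    counts = counts.reshape(n + 1, nreg)
    return counts[1:].argmax(axis=1)


def measure_objects(
    labels: np.ndarray,
    n_objects: int,
    voxel_size_um: tuple[float, float, float],
    intensity_channels: dict[str, np.ndarray] | None = None,
    region_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build the per-object table for a label grid with ids 1..n."""
    ids = np.arange(1, n_objects + 1)
    voxvol = float(np.prod(voxel_size_um))
    counts = np.bincount(labels.ravel(), minlength=n_objects + 1)[1:]
    table = pd.DataFrame({"id": ids, "voxel_count": counts})
    table["volume_um3"] = counts * voxvol

    if n_objects:
        com = ndi.center_of_mass(np.ones_like(labels, dtype=np.uint8), labels, ids)
        com = np.asarray(com, dtype=float)
    else:
        com = np.zeros((0, 3))
    for ax, name in enumerate(("z", "y", "x")):
        table[f"centroid_{name}_um"] = com[:, ax] * voxel_size_um[ax] if n_objects else []

    border = np.zeros(n_objects + 1, dtype=bool)
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=ax)
            border[np.unique(face)] = True
    table["touches_border"] = border[1:]

    if region_mask is not None and n_objects:
        table["region"] = _region_majority(labels, n_objects, region_mask)
    else:
        table["region"] = np.zeros(n_objects, dtype=int)

    for name, chan in (intensity_channels or {}).items():
        sums = ndi.sum_labels(chan, labels, ids) if n_objects else np.array([])
        table[f"intensity_sum_{name}"] = sums
        with np.errstate(invalid="ignore"):
            table[f"intensity_mean_{name}"] = np.where(counts > 0, sums / counts, 0.0)
    return table


def _relabel(labels: np.ndarray, keep_ids: np.ndarray) -> tuple[np.ndarray, int]:
    """Keep the given ids, relabeling contiguously from 1."""
    mapping = np.zeros(labels.max() + 1, dtype=labels.dtype)
    mapping[keep_ids] = np.arange(1, len(keep_ids) + 1)
    return mapping[labels], len(keep_ids)


def connected_components(
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    connectivity: int = 26,
    min_object_volume_um3: float = 0.0,
    intensity_channels: dict[str, np.ndarray] | None = None,
    region_mask: np.ndarray | None = None,
) -> LabeledObjects:
    """Label a binary mask and measure every object.

    Objects smaller than ``min_object_volume_um3`` are dropped and the
    remaining ids made contiguous from 1. Before that filter the summed
    object volume equals the mask volume exactly (conservation).
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    if min_object_volume_um3 > 0 and n:
        voxvol = float(np.prod(voxel_size_um))
        counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        keep = np.flatnonzero(counts * voxvol >= min_object_volume_um3) + 1
        labels, n = _relabel(labels, keep)
    table = measure_objects(labels, n, voxel_size_um, intensity_channels, region_mask)
    return LabeledObjects(labels=labels.astype(np.int32), table=table,
                          voxel_size_um=tuple(voxel_size_um))


def _intensity_map(grid: VoxelGrid) -> dict[str, np.ndarray]:
    return {name: grid.channel(name) for name in grid.channels}


def islet_params(
    magnification_tag: str,
    largest_islet_diameter_um: float = DEFAULT_LARGEST_ISLET_DIAMETER_UM,
    channel: str = "insulin",
    min_object_volume_um3: float = 0.0,
) -> SegmentationParams:
    """Islet preset: background scale = largest islet diameter,
    smoothing 10 um at 1.3x and 3.25 um at higher magnification."""
    if magnification_tag not in ISLET_SMOOTHING_UM:
        raise KeyError(f"no islet preset for magnification {magnification_tag!r}")
    return SegmentationParams(
        channel=channel,
        background_diameter_um=largest_islet_diameter_um,
        smoothing_um=ISLET_SMOOTHING_UM[magnification_tag],
        min_object_volume_um3=min_object_volume_um3,
    )


def nerve_params(
    channel: str = "nf200", min_object_volume_um3: float = 0.0
) -> SegmentationParams:
    """Nerve preset: background 12.2 um, smoothing 3.25 um."""
    return SegmentationParams(
        channel=channel,
        background_diameter_um=NERVE_BACKGROUND_DIAMETER_UM,
        smoothing_um=NERVE_SMOOTHING_UM,
        min_object_volume_um3=min_object_volume_um3,
    )


def segment_islets(
    grid: VoxelGrid,
    magnification_tag: str | None = None,
    largest_islet_diameter_um: float = DEFAULT_LARGEST_ISLET_DIAMETER_UM,
    channel: str = "insulin",
    min_object_volume_um3: float = 0.0,
) -> LabeledObjects:
    """Segment insulin+ islets with the magnification's islet preset.

    Insulin+ structures below 1000 um^3 are retained (they are binned
    separately downstream), so the default minimum volume is zero.
    """
    tag = magnification_tag or grid.magnification_tag
    params = islet_params(tag, largest_islet_diameter_um, channel,
                          min_object_volume_um3)
    mask = local_contrast_threshold(grid, params)
    return connected_components(
        mask, grid.voxel_size_um, params.connectivity,
        params.min_object_volume_um3, _intensity_map(grid), grid.region_mask,
    )


def segment_nerves(
    grid: VoxelGrid,
    nerve_channel: str = "nf200",
    min_object_volume_um3: float = 0.0,
) -> LabeledObjects:
    """Segment nerve fibers on an NF200 / TH / VAChT channel."""
    params = nerve_params(nerve_channel, min_object_volume_um3)
    mask = local_contrast_threshold(grid, params)
    return connected_components(
        mask, grid.voxel_size_um, params.connectivity,
        params.min_object_volume_um3, _intensity_map(grid), grid.region_mask,
    )


def filter_th_beta_cells(
    nerve_objects: LabeledObjects,
    islet_mask: np.ndarray,
    insulin_mask: np.ndarray,
) -> LabeledObjects:
    """Remove TH+ beta cells misdetected as nerve objects.

    An object is removed iff its volume is below 120 um^3 AND all of its
    voxels lie inside an insulin+ islet AND it overlaps insulin
    foreground. Everything else is retained; ids are relabeled
    contiguously.
    """
    labels = nerve_objects.labels
    if islet_mask.shape != labels.shape or insulin_mask.shape != labels.shape:
        raise ValueError("mask shapes differ from nerve label grid")
    n = nerve_objects.n_objects
    if n == 0:
        return nerve_objects
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    inside = np.bincount((labels * islet_mask.astype(labels.dtype)).ravel(),
                         minlength=n + 1)[1:]
    overlap = np.bincount((labels * insulin_mask.astype(labels.dtype)).ravel(),
                          minlength=n + 1)[1:]
    vols = nerve_objects.table["volume_um3"].to_numpy()
    remove = (vols < TH_BETA_CELL_VOLUME_UM3) & (inside == counts) & (overlap > 0)
    keep_ids = np.flatnonzero(~remove) + 1
    new_labels, n_new = _relabel(labels, keep_ids)
    table = nerve_objects.table.loc[~remove].reset_index(drop=True).copy()
    table["id"] = np.arange(1, n_new + 1)
    return LabeledObjects(labels=new_labels, table=table,
                          voxel_size_um=nerve_objects.voxel_size_um)


def _mesh_surface_area(mask: np.ndarray, voxel_size_um) -> float:
    from skimage.measure import marching_cubes, mesh_surface_area

    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=voxel_size_um)
    return float(mesh_surface_area(verts, faces))


def sphericity(volume_um3: float, surface_area_um2: float) -> float:
    """psi = pi^(1/3) (6V)^(2/3) / A; 1 for a sphere, small for tubes."""
    return float(np.pi ** (1 / 3) * (6 * volume_um3) ** (2 / 3) / surface_area_um2)


def segment_ganglia(
    grid: VoxelGrid,
    nerve_channel: str = "nf200",
    volume_range_um3: tuple[float, float] = (20_000.0, 400_000.0),
    min_sphericity: float = 0.4,
    background_diameter_um: float = GANGLION_BACKGROUND_DIAMETER_UM,
) -> LabeledObjects:
    """Detect intrapancreatic ganglia as compact NF200+ blobs.

    The channel is segmented with a blob-preserving background scale,
    then components are kept when their volume falls in
    ``volume_range_um3`` and mesh sphericity reaches ``min_sphericity``
    (tubular fiber fragments fail the sphericity gate). An externally
    supplied ganglion label grid can bypass this via
    :func:`spatial.ganglion_metrics`.
    """
    params = SegmentationParams(
        channel=nerve_channel,
        background_diameter_um=background_diameter_um,
        smoothing_um=NERVE_SMOOTHING_UM,
    )
    mask = local_contrast_threshold(grid, params)
    objs = connected_components(mask, grid.voxel_size_um, 26, 0.0,
                                _intensity_map(grid), grid.region_mask)
    if objs.n_objects == 0:
        return objs
    vols = objs.table["volume_um3"].to_numpy()
    lo, hi = volume_range_um3
    candidate = (vols >= lo) & (vols <= hi)
    keep = []
    slices = ndi.find_objects(objs.labels)
    for i in np.flatnonzero(candidate):
        sl = slices[i]
        sub = objs.labels[sl] == (i + 1)
        area = _mesh_surface_area(sub, grid.voxel_size_um)
        if sphericity(vols[i], area) >= min_sphericity:
            keep.append(i + 1)
    keep_ids = np.asarray(keep, dtype=int)
    new_labels, n_new = _relabel(objs.labels, keep_ids) if len(keep_ids) else (
        np.zeros_like(objs.labels), 0)
    table = objs.table.loc[keep_ids - 1].reset_index(drop=True).copy() if n_new else (
        objs.table.iloc[:0].copy())
    if n_new:
        table["id"] = np.arange(1, n_new + 1)
    return LabeledObjects(labels=new_labels, table=table,
                          voxel_size_um=objs.voxel_size_um)


def segment_cells(
    grid: VoxelGrid,
    channel: str,
    cell_diameter_um: float = 8.0,
    background_diameter_um: float = 30.0,
    smoothing_um: float = 2.0,
) -> LabeledObjects:
    """Watershed segmentation of endocrine cells at high resolution.

    Seeds are local maxima of the anisotropy-aware distance transform
    with a minimum separation of one cell diameter; adjacent cells that
    cannot be split remain a single object (a stated limitation of this
    kind of contact analysis).
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    params = SegmentationParams(
        channel=channel,
        background_diameter_um=background_diameter_um,
        smoothing_um=smoothing_um,
    )
    mask = local_contrast_threshold(grid, params)
    if not mask.any():
        return connected_components(mask, grid.voxel_size_um, 26, 0.0,
                                    _intensity_map(grid), grid.region_mask)
    vs = np.asarray(grid.voxel_size_um, dtype=float)
    edt = ndi.distance_transform_edt(mask, sampling=vs)
    # blur at a quarter cell diameter merges the tied plateau maxima of
    # the EDT so each cell yields a single seed
    edt = ndi.gaussian_filter(edt, 0.25 * cell_diameter_um / vs)
    # box footprint ~ 0.8 cell diameters per axis in physical units
    half = np.maximum(np.round(0.8 * cell_diameter_um / vs).astype(int), 1)
    footprint = np.ones(tuple(2 * half + 1), dtype=bool)
    coords = peak_local_max(edt, footprint=footprint, labels=mask,
                            exclude_border=False,
                            threshold_abs=0.2 * cell_diameter_um)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-edt, markers, mask=mask)
    n = int(labels.max())
    table = measure_objects(labels, n, grid.voxel_size_um,
                            _intensity_map(grid), grid.region_mask)
    return LabeledObjects(labels=labels.astype(np.int32), table=table,
                          voxel_size_um=grid.voxel_size_um)
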