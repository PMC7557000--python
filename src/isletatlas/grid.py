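"""In-memory containers for multi-channel 3D microscopy volumes.

Axis order is fixed as (z, y, x) throughout the package, all physical
lengths are micrometres, and volumes are cubic micrometres; cubic
millimetres appear only in reported densities (1 mm^3 = 1e9 um^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Voxel sizes (z, y, x) in um for the supported acquisition settings.
#: Light-sheet 1.3x/4x/12x and a 10x confocal setting with 5 um z-steps.
MAGNIFICATION_VOXEL_SIZES = {
    "1.3x": (5.0, 5.0, 5.0),
    "4x": (5.0, 1.63, 1.63),
    "12x": (2.0, 0.602, 0.602),
    "confocal10x": (5.0, 1.67, 1.67),
}

#: Region mask codes: 0 = outside tissue.
REGION_CODES = {0: "outside", 1: "duodenal", 2: "splenic"}
REGION_NAMES = ("total", "duodenal", "splenic")


@dataclass
class VoxelGrid:
    """A stack of named channels on a common (z, y, x) voxel grid.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)`` with non-negative
        scalar intensities.
    channels
        Channel names in the order of the first axis of ``data``
        (e.g. ``["insulin", "nf200"]``).
    voxel_size_um
        Physical voxel pitch ``(z, y, x)`` in micrometres.
    magnification_tag
        One of :data:`MAGNIFICATION_VOXEL_SIZES` keys or ``"custom"``.
    region_mask
        Optional integer grid of the same spatial shape; 0 = outside
        tissue, 1 = duodenal, 2 = splenic.
    """

    data: np.ndarray
    channels: list[str]
    voxel_size_um: tuple[float, float, float]
    magnification_tag: str = "custom"
    region_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("data must have shape (channels, z, y, x)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for "
                f"{self.data.shape[0]} channel grids"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or min(self.voxel_size_um) <= 0:
            raise ValueError("voxel_size_um must be three positive reals")
        if self.magnification_tag not in MAGNIFICATION_VOXEL_SIZES and (
            self.magnification_tag != "custom"
        ):
            raise ValueError(f"unknown magnification_tag {self.magnification_tag!r}")
        if self.magnification_tag in MAGNIFICATION_VOXEL_SIZES:
            expected = MAGNIFICATION_VOXEL_SIZES[self.magnification_tag]
            if not np.allclose(self.voxel_size_um, expected):
                raise ValueError(
                    f"magnification {self.magnification_tag} implies voxel size "
                    f"{expected}, got {self.voxel_size_um}; use tag 'custom'"
                )
        if self.region_mask is not None:
            self.region_mask = np.asarray(self.region_mask)
            if self.region_mask.shape != self.shape:
                raise ValueError("region_mask shape differs from channel shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D grid of a named channel."""
        try:
            i = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; have {self.channels}"
            ) from None
        return self.data[i]

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    def tissue_mask(self) -> np.ndarray:
        """Boolean tissue support: region mask > 0, or the full grid."""
        if self.region_mask is not None:
            return self.region_mask > 0
        return np.ones(self.shape, dtype=bool)

    def tissue_volume_um3(self, region: int | None = None) -> float:
        """Tissue volume in um^3, optionally restricted to one region code."""
        if self.region_mask is None:
            n = int(np.prod(self.shape)) if region is None else 0
        elif region is None:
            n = int(np.count_nonzero(self.region_mask))
        else:
            n = int(np.count_nonzero(self.region_mask == region))
        return n * self.voxel_volume_um3


@dataclass
class SampleMetadata:
    """Per-sample study metadata joined onto quantification tables."""

    sample_id: str
    group: str
    blood_glucose_mg_dl: float | None = None
    batch: str = "default"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group label must be non-empty")
        if self.blood_glucose_mg_dl is not None and self.blood_glucose_mg_dl < 0:
            raise ValueError("blood glucose must be >= 0")


@dataclass
class StudyResult:
    """Container for the per-object tables and summaries of one run.

    ``tables`` maps table names (``islets``, ``ganglia``, ``cells``,
    ``summary`` ...) to DataFrames; ``stats`` holds structured test
    results; ``params`` records the fully-resolved run parameters.
    """

    tables: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
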