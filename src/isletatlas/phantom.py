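"""Ground-truthed synthetic phantoms of pancreatic tissue.

The phantoms are statistical emulations, not anatomical simulations:
islets are ellipsoids whose volume distribution, innervated count
fraction and innervated volume share are calibrated to whole-organ
measurements; nerves are random tube trees enriched inside designated
islets; ganglia are spheres placed at a controlled surface distance
from islets; the high-resolution mode renders a single islet packed
with spherical endocrine cells and terminal nerve twigs. Every phantom
carries its generative truth (label grids + tables recomputable from
them by voxel counting), so every pipeline stage can be validated at
desk scale without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import minimize
from scipy.stats import norm

from .grid import VoxelGrid

MM3_IN_UM3 = 1e9

#: Normalized target islet-volume bin weights over the bins
#: [0,1000), [1000,50k), [50k,500k), [500k,inf) um^3. The printed
#: weights 3.13/39.29/36.58/20.0 sum to 99.0 and are renormalized.
ISLET_BIN_TARGETS = (3.13, 39.29, 36.58, 20.0)
ISLET_BIN_EDGES = (1000.0, 50_000.0, 500_000.0)


# --------------------------------------------------------------------------
# size-distribution calibration


@lru_cache(maxsize=None)
def fit_lognormal_mixture_to_bins(
    bin_edges: tuple[float, ...] = ISLET_BIN_EDGES,
    bin_weights: tuple[float, ...] = ISLET_BIN_TARGETS,
    vmin: float = 100.0,
    vmax: float = 8.181e6,
) -> tuple[float, float, float, float, float]:
    """Fit a 2-component lognormal mixture to target volume-bin weights.

    Deterministic moment/quantile matching: Nelder-Mead least squares on
    the truncated mixture CDF evaluated at the bin edges, from a fixed
    starting point. Returns ``(w, mu1, sigma1, mu2, sigma2)`` of
    ``w LN(mu1, s1) + (1-w) LN(mu2, s2)`` truncated to [vmin, vmax].
    vmax defaults to the volume of a 250 um sphere (the largest expected
    islet diameter).
    """
    w = np.asarray(bin_weights, dtype=float)
    w = w / w.sum()
    targets = np.cumsum(w)[:-1]
    ledges = np.log(np.asarray(bin_edges, dtype=float))
    lvmin, lvmax = np.log(vmin), np.log(vmax)

    def cdf(lv, p):
        wt = 1.0 / (1.0 + np.exp(-p[0]))
        m1, s1, m2, s2 = p[1], np.exp(p[2]), p[3], np.exp(p[4])

        def F(x):
            return wt * norm.cdf((x - m1) / s1) + (1 - wt) * norm.cdf((x - m2) / s2)

        return (F(lv) - F(lvmin)) / (F(lvmax) - F(lvmin))

    def loss(p):
        return float(np.sum((cdf(ledges, p) - targets) ** 2))

    x0 = np.array([0.0, 9.5, np.log(1.5), 12.5, np.log(1.5)])
    res = minimize(loss, x0, method="Nelder-Mead",
                   options=dict(maxiter=20000, xatol=1e-10, fatol=1e-16))
    p = res.x
    return (
        float(1.0 / (1.0 + np.exp(-p[0]))),
        float(p[1]), float(np.exp(p[2])),
        float(p[3]), float(np.exp(p[4])),
    )


def islet_bin_probabilities(
    bin_edges=ISLET_BIN_EDGES, bin_weights=ISLET_BIN_TARGETS,
    vmin: float = 100.0, vmax: float = 8.181e6,
) -> np.ndarray:
    """Analytic bin probabilities (in %) of the fitted truncated mixture."""
    w, m1, s1, m2, s2 = fit_lognormal_mixture_to_bins(
        tuple(bin_edges), tuple(bin_weights), vmin, vmax
    )

    def F(x):
        lv = np.log(x)
        return w * norm.cdf((lv - m1) / s1) + (1 - w) * norm.cdf((lv - m2) / s2)

    lo, hi = F(vmin), F(vmax)
    cum = np.array([(F(e) - lo) / (hi - lo) for e in bin_edges])
    return np.diff(np.concatenate([[0.0], cum, [1.0]])) * 100.0


# --------------------------------------------------------------------------
# configuration


@dataclass
class PhantomConfig:
    """Generative parameters of a phantom; defaults are the healthy
    C57BL/6 whole-pancreas calibration."""

    # grid / tissue
    shape: tuple[int, int, int] = (128, 512, 512)
    voxel_size_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    magnification_tag: str = "1.3x"
    tissue_inplane_fraction: float = 0.96   # ellipse semi-axes / half-extent
    tissue_z_fraction: float = 0.90         # slab thickness / z extent

    # islet model
    islet_volume_fraction: float = 0.0131   # beta volume / tissue volume
    bin_weights: tuple[float, ...] = ISLET_BIN_TARGETS
    bin_edges: tuple[float, ...] = ISLET_BIN_EDGES
    min_islet_volume_um3: float = 100.0
    largest_islet_diameter_um: float = 250.0
    axis_ratio_max: float = 1.5
    islet_gap_um: float = 15.0
    volume_scale: float = 1.0               # disease shift of the whole distribution
    beta_scale_vs_nondiabetic: float | None = None

    # innervation model
    innervated_count_fraction: float = 0.061
    innervated_volume_share: float = 0.43
    #: global endocrine nerve density target: nerve volume inside islets /
    #: total islet volume (the per-innervated-islet fill is this divided by
    #: the innervated volume share). Exocrine analog over non-islet tissue.
    #: Defaults keep the endocrine:exocrine ratio above sixfold.
    endocrine_nerve_fraction: float = 0.02
    exocrine_nerve_fraction: float = 0.003
    tube_radius_um: tuple[float, float] = (2.0, 4.0)
    tube_step_um: float = 5.0
    tube_persistence: float = 0.85          # direction correlation per step
    nerve_channel: str = "nf200"

    # ganglion model
    ganglion_density_per_mm3: float = 21.5
    ganglion_mean_volume_um3: float = 83_467.0
    ganglion_volume_cv: float = 0.6
    ganglion_volume_bounds_um3: tuple[float, float] = (25_000.0, 350_000.0)
    ganglion_distance_mean_um: float = 47.3
    ganglion_distance_sd_um: float = 20.0
    #: ganglion-to-islet distances are defined relative to proper islets;
    #: insulin+ specks below this volume (five or fewer beta cells) are
    #: not a meaningful distance reference.
    ganglion_islet_reference_min_volume_um3: float = 1000.0

    # cell model (high-resolution single-islet mode)
    cell_islet_diameter_um: float = 120.0
    cell_radius_um: float = 3.8
    #: cell lattice pitch (z, y, x); the z pitch of 15 um (3 optical
    #: sections) keeps each cell resolved in a single 5 um z-plane, the
    #: regime where per-cell contact counting is unambiguous.
    cell_spacing_um: tuple[float, float, float] = (15.0, 10.0, 10.0)
    cell_beta_fraction: float = 0.80
    beta_contact_fraction: float = 0.094
    alpha_contact_fraction: float = 0.47
    twig_radius_um: float = 1.8
    twig_length_um: float = 25.0
    n_distractor_twigs: int = 15

    # intensity / noise model
    intensity: dict = field(default_factory=lambda: {
        "tissue_insulin": 30.0, "islet": 900.0,
        "tissue_nerve": 20.0, "nerve": 600.0, "ganglion": 700.0,
        "cell": 800.0,
    })
    poisson_scale: float = 0.0   # photons per intensity unit; 0 disables
    gaussian_sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("innervated_count_fraction", "innervated_volume_share",
                     "endocrine_nerve_fraction", "exocrine_nerve_fraction",
                     "cell_beta_fraction", "beta_contact_fraction",
                     "alpha_contact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ganglion_density_per_mm3 < 0:
            raise ValueError("ganglion density must be >= 0")

    @property
    def max_islet_volume_um3(self) -> float:
        r = self.largest_islet_diameter_um / 2.0
        return 4.0 / 3.0 * np.pi * r**3

    def mixture_params(self):
        return fit_lognormal_mixture_to_bins(
            tuple(self.bin_edges), tuple(self.bin_weights),
            self.min_islet_volume_um3, self.max_islet_volume_um3,
        )

    def implied_mean_volume_ratio(self) -> float:
        """Mean-volume ratio implied by the joint (count fraction f,
        volume share s) calibration: r = s (1 - f) / (f (1 - s))."""
        f, s = self.innervated_count_fraction, self.innervated_volume_share
        return s * (1 - f) / (f * (1 - s))


def preset(name: str) -> PhantomConfig:
    """Return the calibrated configuration for a named study condition."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[name]()


def _c57() -> PhantomConfig:
    return PhantomConfig()


def _c57_th() -> PhantomConfig:
    # Sympathetic (TH) fibers contact far more islets than NF200 overall.
    return PhantomConfig(
        nerve_channel="th",
        innervated_count_fraction=0.277,
        innervated_volume_share=0.60,
        endocrine_nerve_fraction=0.030,
    )


def _nod_nondiabetic() -> PhantomConfig:
    return PhantomConfig(
        innervated_count_fraction=0.146,
        innervated_volume_share=0.60,
        ganglion_density_per_mm3=18.9,
        ganglion_mean_volume_um3=61_779.0,
        ganglion_distance_mean_um=40.0,
    )


def _nod_diabetic() -> PhantomConfig:
    # Beta volume at 10% of the nondiabetic level, nerve densification,
    # smaller islets (median down by more than half), remote ganglia.
    cfg = PhantomConfig(
        islet_volume_fraction=0.0131 * 0.10,
        beta_scale_vs_nondiabetic=0.10,
        volume_scale=0.45,
        innervated_count_fraction=0.098,
        innervated_volume_share=0.60,
        endocrine_nerve_fraction=0.05,
        ganglion_density_per_mm3=28.2,
        ganglion_mean_volume_um3=59_348.0,
        ganglion_distance_mean_um=171.7,
        ganglion_distance_sd_um=60.0,
    )
    return cfg


def _stz_d5() -> PhantomConfig:
    cfg = PhantomConfig(
        islet_volume_fraction=0.0131 * 0.7,
        endocrine_nerve_fraction=0.05,
        innervated_volume_share=0.54,
    )
    cfg.intensity["islet"] = 675.0
    return cfg


def _stz_d15() -> PhantomConfig:
    # Beta volume 40% of control; insulin intensity halved; ganglia 30%
    # smaller; islet nerve density doubled.
    cfg = PhantomConfig(
        islet_volume_fraction=0.0131 * 0.4,
        endocrine_nerve_fraction=0.05,
        exocrine_nerve_fraction=0.005,
        innervated_volume_share=0.54,
        ganglion_mean_volume_um3=83_467.0 * 0.7,
    )
    cfg.intensity["islet"] = 450.0
    return cfg


def _human_control() -> PhantomConfig:
    return PhantomConfig(
        islet_volume_fraction=0.012,     # within the 0.47-2.2% donor range
        innervated_count_fraction=0.009,
        innervated_volume_share=0.25,
        endocrine_nerve_fraction=0.005,
        exocrine_nerve_fraction=0.005,   # endo ~ exo in healthy human tissue
        beta_contact_fraction=0.0415,
        ganglion_mean_volume_um3=250_000.0,
    )


def _human_t2d() -> PhantomConfig:
    return PhantomConfig(
        islet_volume_fraction=0.009,     # within the 0.85-0.97% donor range
        volume_scale=0.6,
        innervated_count_fraction=0.044,
        innervated_volume_share=0.35,
        endocrine_nerve_fraction=0.010,
        exocrine_nerve_fraction=0.008,
        beta_contact_fraction=0.0607,
        ganglion_mean_volume_um3=250_000.0,
    )


PRESETS = {
    "mouse_c57_default": _c57,
    "mouse_c57_th": _c57_th,
    "nod_nondiabetic": _nod_nondiabetic,
    "nod_diabetic": _nod_diabetic,
    "stz_d5": _stz_d5,
    "stz_d15": _stz_d15,
    "human_control": _human_control,
    "human_t2d": _human_t2d,
}


# --------------------------------------------------------------------------
# ground truth container


@dataclass
class PhantomGroundTruth:
    """True label grids and tables of one rendered phantom."""

    islet_labels: np.ndarray | None = None
    nerve_mask: np.ndarray | None = None
    ganglion_labels: np.ndarray | None = None
    cell_labels: np.ndarray | None = None
    islet_table: pd.DataFrame | None = None
    ganglion_table: pd.DataFrame | None = None
    cell_table: pd.DataFrame | None = None
    realized: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# sampling


def tissue_margin_um(config: PhantomConfig, vox: np.ndarray) -> np.ndarray:
    """Conservative distance (um) from voxel centers to the tissue
    boundary of the elliptical-cylinder slab (analytic, no EDT)."""
    vox = np.atleast_2d(vox)
    nz, ny, nx = config.shape
    vs = np.asarray(config.voxel_size_um, dtype=float)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay = config.tissue_inplane_fraction * ny / 2.0
    ax = config.tissue_inplane_fraction * nx / 2.0
    rho = np.sqrt(((vox[:, 1] - cy) / ay) ** 2 + ((vox[:, 2] - cx) / ax) ** 2)
    inplane = (1.0 - rho) * min(ay * vs[1], ax * vs[2])
    z0 = int(round(nz * (1 - config.tissue_z_fraction) / 2))
    z1 = nz - z0
    zlo = (vox[:, 0] - z0 + 0.5) * vs[0]
    zhi = (z1 - 1 - vox[:, 0] + 0.5) * vs[0]
    return np.minimum(inplane, np.minimum(zlo, zhi))


def make_tissue_mask(config: PhantomConfig) -> np.ndarray:
    """Elliptical-cylinder tissue slab split into duodenal (x-low, code 1)
    and splenic (x-high, code 2) halves; 0 outside tissue."""
    nz, ny, nx = config.shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay = config.tissue_inplane_fraction * ny / 2.0
    ax = config.tissue_inplane_fraction * nx / 2.0
    inplane = ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
    z0 = int(round(nz * (1 - config.tissue_z_fraction) / 2))
    z1 = nz - z0
    slab = (z >= z0) & (z < z1)
    mask = (inplane & slab).astype(np.uint8)
    region = np.where(mask > 0, np.where(x < cx, 1, 2), 0).astype(np.uint8)
    return region


def sample_islet_volumes(
    config: PhantomConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw islet volumes (um^3) from the calibrated truncated mixture."""
    w, m1, s1, m2, s2 = config.mixture_params()
    lvmin = np.log(config.min_islet_volume_um3)
    lvmax = np.log(config.max_islet_volume_um3)
    comp = rng.random(n) < w
    mu = np.where(comp, m1, m2)
    sig = np.where(comp, s1, s2)
    # inverse-CDF truncation per component
    lo = norm.cdf((lvmin - mu) / sig)
    hi = norm.cdf((lvmax - mu) / sig)
    u = lo + rng.random(n) * (hi - lo)
    vols = np.exp(mu + sig * norm.ppf(u))
    return vols * config.volume_scale


def _truncated_lognormal_mean(mu: float, sigma: float,
                              vmin: float, vmax: float) -> float:
    a = (np.log(vmin) - mu) / sigma
    b = (np.log(vmax) - mu) / sigma
    z = norm.cdf(b) - norm.cdf(a)
    if z <= 0:
        return vmax
    num = norm.cdf(b - sigma) - norm.cdf(a - sigma)
    return float(np.exp(mu + sigma**2 / 2.0) * num / z)


def truncated_mixture_mean(config: PhantomConfig) -> float:
    """Analytic mean islet volume of the fitted truncated mixture
    (before any disease volume scaling)."""
    w, m1, s1, m2, s2 = config.mixture_params()
    vmin, vmax = config.min_islet_volume_um3, config.max_islet_volume_um3

    def part(mu, sig):
        a = (np.log(vmin) - mu) / sig
        b = (np.log(vmax) - mu) / sig
        return (np.exp(mu + sig**2 / 2.0)
                * (norm.cdf(b - sig) - norm.cdf(a - sig)),
                norm.cdf(b) - norm.cdf(a))

    n1, z1 = part(m1, s1)
    n2, z2 = part(m2, s2)
    return float((w * n1 + (1 - w) * n2) / (w * z1 + (1 - w) * z2))


def _solve_innervated_mu(target_mean: float, sigma: float,
                         vmin: float, vmax: float) -> float:
    """Location parameter of the innervated-islet lognormal such that its
    [vmin, vmax]-truncated mean equals the target."""
    from scipy.optimize import brentq

    hi_reachable = _truncated_lognormal_mean(np.log(vmax) + 5 * sigma,
                                             sigma, vmin, vmax)
    target = min(target_mean, 0.98 * hi_reachable)
    return float(brentq(
        lambda mu: _truncated_lognormal_mean(mu, sigma, vmin, vmax) - target,
        np.log(vmin), np.log(vmax) + 5 * sigma, xtol=1e-8))


def sample_innervated_volumes(config: PhantomConfig, k: int,
                              rng: np.random.Generator,
                              sigma: float = 0.6) -> np.ndarray:
    """Draw the innervated population: a size-biased lognormal whose
    truncated mean is r x the base mean, with r = s(1-f)/(f(1-s)) the
    mean-volume ratio implied by the count fraction f and volume share s."""
    if k == 0:
        return np.zeros(0)
    r = config.implied_mean_volume_ratio()
    base_mean = truncated_mixture_mean(config)
    vmin, vmax = config.min_islet_volume_um3, config.max_islet_volume_um3
    mu = _solve_innervated_mu(r * base_mean, sigma, vmin, vmax)
    lo = norm.cdf((np.log(vmin) - mu) / sigma)
    hi = norm.cdf((np.log(vmax) - mu) / sigma)
    u = lo + rng.random(k) * (hi - lo)
    return np.exp(mu + sigma * norm.ppf(u)) * config.volume_scale


def sample_islets(config: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample islet specifications: volumes, ellipsoid semi-axes, centers
    (um), and innervated designation.

    The two-population calibration: non-innervated islets follow the
    fitted bin-weight mixture; innervated islets follow a size-biased
    lognormal whose mean realizes the implied mean-volume ratio. The
    innervated draws are then rescaled as a group so their volume share
    matches the target, and the whole set rescaled by a bounded factor
    so the summed volume matches the configured tissue fraction (the
    rendered beta volume percent is a generative condition, not a
    sampling accident). Centers are drawn uniformly in tissue with
    non-overlap rejection.
    """
    region = make_tissue_mask(config)
    tissue = region > 0
    voxvol = float(np.prod(config.voxel_size_um))
    tissue_um3 = tissue.sum() * voxvol
    target_total = config.islet_volume_fraction * tissue_um3

    # largest islet that geometrically fits the tissue slab
    vs_arr = np.asarray(config.voxel_size_um, dtype=float)
    fit_r = (config.shape[0] * vs_arr[0] * config.tissue_z_fraction / 2.0
             - 2.0 * vs_arr.max())
    fit_vmax = 4.0 / 3.0 * np.pi * max(fit_r, vs_arr.max()) ** 3
    vcap = min(config.max_islet_volume_um3, fit_vmax)

    f = config.innervated_count_fraction
    s = config.innervated_volume_share
    base_mean = truncated_mixture_mean(config) * config.volume_scale
    mean_all = base_mean * (1 - f) / (1 - s) if (0 < f and 0 < s < 1) else base_mean
    n_total = max(1, int(round(target_total / mean_all))) if target_total > 0 else 0
    if n_total == 0:
        return pd.DataFrame(columns=[
            "volume_um3", "rz_um", "ry_um", "rx_um",
            "cz_um", "cy_um", "cx_um", "innervated"])
    k = int(round(f * n_total))
    non = sample_islet_volumes(config, n_total - k, rng)
    inn = sample_innervated_volumes(config, k, rng)
    non = np.minimum(non, vcap)
    inn = np.minimum(inn, vcap)
    if k and s < 1 and non.sum() > 0 and inn.sum() > 0:
        c_inn = np.clip(s / (1 - s) * non.sum() / inn.sum(), 0.25, 4.0)
        inn = np.minimum(inn * c_inn, vcap)
    vols = np.concatenate([non, inn])
    flags = np.zeros(n_total, dtype=bool)
    flags[n_total - k:] = True
    scale = np.clip(target_total / vols.sum(), 0.5, 2.0)
    vols = np.minimum(vols * scale, vcap)

    # ellipsoid semi-axes with product = r0^3 (volume preserved)
    r0 = (3.0 * vols / (4.0 * np.pi)) ** (1.0 / 3.0)
    l1 = rng.uniform(1.0, config.axis_ratio_max, vols.size)
    l2 = rng.uniform(1.0, config.axis_ratio_max, vols.size)
    norm3 = (l1 * l2) ** (1.0 / 3.0)
    axes = np.stack([l1 / norm3, l2 / norm3, 1.0 / norm3], axis=1) * r0[:, None]
    for i in range(vols.size):
        rng.shuffle(axes[i])

    # placement, large first, spherical-bound non-overlap rejection
    vs = np.asarray(config.voxel_size_um)
    order = np.argsort(-vols)
    centers = np.full((vols.size, 3), np.nan)
    placed_r: list[float] = []
    placed_c: list[np.ndarray] = []
    shape = np.asarray(config.shape)
    for idx in order:
        rmax = axes[idx].max()
        ok = False
        for _ in range(2000):
            vox = rng.integers(0, shape)
            if not tissue[tuple(vox)]:
                continue
            if tissue_margin_um(config, vox)[0] < rmax + vs.max():
                continue
            c = (vox + 0.5) * vs
            good = True
            for rc, cc in zip(placed_r, placed_c):
                if np.linalg.norm(c - cc) < rc + rmax + config.islet_gap_um:
                    good = False
                    break
            if good:
                centers[idx] = c
                placed_r.append(rmax)
                placed_c.append(c)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "islet placement rejection budget exceeded; targets infeasible "
                f"at volume fraction {config.islet_volume_fraction}"
            )
    return pd.DataFrame({
        "volume_um3": vols,
        "rz_um": axes[:, 0], "ry_um": axes[:, 1], "rx_um": axes[:, 2],
        "cz_um": centers[:, 0], "cy_um": centers[:, 1], "cx_um": centers[:, 2],
        "innervated": flags,
    })


# --------------------------------------------------------------------------
# rasterization helpers


def _rasterize_ellipsoid(mask_or_labels, center_um, radii_um, voxel_size_um,
                         value=True) -> int:
    """Paint an axis-aligned ellipsoid (center-in-voxel test); returns the
    number of voxels painted."""
    vs = np.asarray(voxel_size_um, dtype=float)
    shape = mask_or_labels.shape
    c = np.asarray(center_um, dtype=float)
    r = np.asarray(radii_um, dtype=float)
    lo = np.maximum(np.floor((c - r) / vs - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((c + r) / vs + 0.5).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return 0
    zz, yy, xx = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)],
                             indexing="ij")
    d = (((zz + 0.5) * vs[0] - c[0]) / r[0]) ** 2 \
        + (((yy + 0.5) * vs[1] - c[1]) / r[1]) ** 2 \
        + (((xx + 0.5) * vs[2] - c[2]) / r[2]) ** 2
    inside = d <= 1.0
    sub = mask_or_labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside] = value
    return int(inside.sum())


def _ball_offsets(radius_um: float, voxel_size_um) -> np.ndarray:
    """Voxel offsets whose centers lie within radius_um (anisotropic)."""
    vs = np.asarray(voxel_size_um, dtype=float)
    ext = np.maximum(np.floor(radius_um / vs).astype(int), 0)
    zz, yy, xx = np.meshgrid(*[np.arange(-e, e + 1) for e in ext],
                             indexing="ij")
    d2 = (zz * vs[0]) ** 2 + (yy * vs[1]) ** 2 + (xx * vs[2]) ** 2
    sel = d2 <= radius_um**2
    off = np.stack([zz[sel], yy[sel], xx[sel]], axis=1)
    if off.size == 0:
        off = np.zeros((1, 3), dtype=int)
    return off


def rasterize_tube(points_um: np.ndarray, radius_um: float,
                   shape: tuple[int, int, int], voxel_size_um,
                   out: np.ndarray | None = None) -> np.ndarray:
    """Rasterize a polyline tube into a boolean grid (center-in test).

    ``points_um`` are polyline vertices in physical coordinates; the
    polyline is resampled at half the smallest voxel pitch before
    stamping an anisotropic ball at each sample.
    """
    vs = np.asarray(voxel_size_um, dtype=float)
    if out is None:
        out = np.zeros(shape, dtype=bool)
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim == 1:
        pts = pts[None]
    # resample densely along segments
    dense = [pts[0]]
    step = vs.min() / 2.0
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            dense.append(a + t * (b - a))
    dense = np.asarray(dense)
    off = _ball_offsets(radius_um, vs)
    vox = np.floor(dense / vs).astype(int)
    vox = np.unique(vox, axis=0)
    allv = (vox[:, None, :] + off[None, :, :]).reshape(-1, 3)
    good = np.all((allv >= 0) & (allv < np.asarray(shape)), axis=1)
    allv = allv[good]
    out[allv[:, 0], allv[:, 1], allv[:, 2]] = True
    return out


# --------------------------------------------------------------------------
# nerves


def draw_nerves(
    config: PhantomConfig,
    islet_labels: np.ndarray,
    islet_specs: pd.DataFrame,
    region: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Draw the nerve mask: intra-islet arbors in every innervated islet
    plus exocrine tube trees that avoid all islets.

    Endocrine arbors are random walks constrained to the islet's voxels,
    grown until the intra-islet nerve volume reaches the configured
    fraction of that islet's volume (guaranteeing voxel overlap, i.e.
    distance-0 innervation). Exocrine tubes are persistent random walks
    excluded from a 3-voxel dilation of the islet mask, stopped when the
    exocrine volume fraction target is met. Returns the mask and the
    realized endocrine/exocrine voxel statistics.
    """
    shape = islet_labels.shape
    vs = np.asarray(config.voxel_size_um, dtype=float)
    tissue = region > 0
    islet_mask = islet_labels > 0
    nerve = np.zeros(shape, dtype=bool)

    # --- endocrine arbors: per-islet fill = global density / volume share
    share = config.innervated_volume_share
    fill = config.endocrine_nerve_fraction / share if share > 0 else 0.0
    endo_target_total = 0
    for row in islet_specs.itertuples():
        if not row.innervated:
            continue
        lab = row.Index + 1
        voxels = np.argwhere(islet_labels == lab)
        if len(voxels) == 0:
            continue
        n_target = max(1, int(round(fill * len(voxels))))
        endo_target_total += n_target
        occupied = set()
        pos = voxels[np.argmin(np.abs(voxels - voxels.mean(axis=0)).sum(axis=1))]
        pos = tuple(pos)
        occupied.add(pos)
        steps = 0
        max_steps = 200 * n_target
        vset = {tuple(v) for v in voxels}
        while len(occupied) < n_target and steps < max_steps:
            steps += 1
            d = rng.integers(-1, 2, size=3)
            nxt = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
            if nxt in vset:
                pos = nxt
                occupied.add(pos)
            elif steps % 20 == 0:
                pos = tuple(voxels[rng.integers(len(voxels))])
        idx = np.asarray(list(occupied))
        nerve[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    # --- exocrine tubes
    excl = ndi.binary_dilation(islet_mask, iterations=3)
    exo_tissue_vox = int(np.count_nonzero(tissue & ~islet_mask))
    exo_target = int(round(config.exocrine_nerve_fraction * exo_tissue_vox))
    cand = np.argwhere(tissue & ~excl)
    exo_count = 0
    guard = 0
    while exo_count < exo_target and guard < 10_000 and len(cand):
        guard += 1
        radius = rng.uniform(*config.tube_radius_um)
        off = _ball_offsets(radius, vs)
        start = cand[rng.integers(len(cand))].astype(float) + 0.5
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = start
        length = int(rng.integers(100, 500))
        for _ in range(length):
            jitter = rng.normal(size=3) * (1 - config.tube_persistence)
            direction = direction * config.tube_persistence + jitter
            direction /= np.linalg.norm(direction)
            step_vox = direction * config.tube_step_um / vs
            nxt = pos + step_vox
            v = np.floor(nxt).astype(int)
            if (np.any(v < 0) or np.any(v >= np.asarray(shape))
                    or not tissue[tuple(v)] or excl[tuple(v)]):
                # bounce: try a fresh direction a few times, else stop
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                continue
            pos = nxt
            pts = (v[None, :] + off)
            good = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
            pts = pts[good]
            sel = ~excl[pts[:, 0], pts[:, 1], pts[:, 2]]
            pts = pts[sel]
            before = nerve[pts[:, 0], pts[:, 1], pts[:, 2]]
            exo_count += int((~before).sum())
            nerve[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            if exo_count >= exo_target:
                break

    stats = {
        "endocrine_nerve_voxels": int(np.count_nonzero(nerve & islet_mask)),
        "exocrine_nerve_voxels": int(np.count_nonzero(nerve & ~islet_mask)),
        "endocrine_target_voxels": endo_target_total,
        "exocrine_target_voxels": exo_target,
    }
    isl_vox = int(islet_mask.sum())
    stats["endocrine_density_percent"] = (
        100.0 * stats["endocrine_nerve_voxels"] / isl_vox if isl_vox else 0.0
    )
    stats["exocrine_density_percent"] = (
        100.0 * stats["exocrine_nerve_voxels"] / exo_tissue_vox
        if exo_tissue_vox else 0.0
    )
    return nerve, stats


# --------------------------------------------------------------------------
# ganglia


def place_ganglia(
    config: PhantomConfig,
    islet_mask: np.ndarray,
    region: np.ndarray,
    forbidden: np.ndarray,
    rng: np.random.Generator,
    distance_reference: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place spherical ganglia at controlled surface distances from islets.

    The count is Poisson at the configured density; volumes are
    lognormal around the target mean (bounded); surface-to-islet
    distances follow a gamma law with the configured mean/SD. Returns
    the ganglion label grid and the truth table.
    """
    shape = islet_mask.shape
    vs = np.asarray(config.voxel_size_um, dtype=float)
    voxvol = float(np.prod(vs))
    tissue = region > 0
    tissue_mm3 = tissue.sum() * voxvol / MM3_IN_UM3
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    n = rng.poisson(config.ganglion_density_per_mm3 * tissue_mm3)
    if n == 0 or config.ganglion_density_per_mm3 == 0:
        return labels, pd.DataFrame(rows)

    ref = islet_mask if distance_reference is None else distance_reference
    if ref.any():
        edt = ndi.distance_transform_edt(~ref, sampling=vs).astype(np.float32)
    else:
        edt = np.full(shape, np.float32(np.inf))
    blocked = forbidden | islet_mask  # ganglia never overlap nerves/islets

    sd, mean = config.ganglion_distance_sd_um, config.ganglion_distance_mean_um
    shape_g = (mean / sd) ** 2
    scale_g = sd**2 / mean
    lo_v, hi_v = config.ganglion_volume_bounds_um3
    sigma2 = np.log(1.0 + config.ganglion_volume_cv**2)
    mu_ln = np.log(config.ganglion_mean_volume_um3) - sigma2 / 2.0

    def _stamp_ok(c_um, r):
        """Rasterize locally; return voxel indices if placement is free."""
        lo = np.maximum(np.floor((c_um - r) / vs - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((c_um + r) / vs + 0.5).astype(int) + 1,
                        np.asarray(shape))
        zz, yy, xx = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)],
                                 indexing="ij")
        d2 = (((zz + 0.5) * vs[0] - c_um[0]) / r) ** 2 \
            + (((yy + 0.5) * vs[1] - c_um[1]) / r) ** 2 \
            + (((xx + 0.5) * vs[2] - c_um[2]) / r) ** 2
        inside = d2 <= 1.0
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        if blocked[sub][inside].any() or (labels[sub][inside] > 0).any():
            return None
        if not tissue[sub][inside].all():
            return None
        return sub, inside

    gid = 0
    for _ in range(n):
        vol = 0.0
        while not (lo_v <= vol <= hi_v):
            vol = float(np.exp(rng.normal(mu_ln, np.sqrt(sigma2))))
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        d = 0.0
        while d < vs.max():
            d = float(rng.gamma(shape_g, scale_g))
        band = np.abs(edt - (d + r)) <= vs.max() / 2.0
        cand = np.argwhere(band)
        if len(cand) == 0:
            continue
        margins = tissue_margin_um(config, cand)
        cand = cand[margins >= r + vs.max()]
        for _try in range(100):
            if len(cand) == 0:
                break
            vox = cand[rng.integers(len(cand))]
            c = (vox + 0.5) * vs
            hit = _stamp_ok(c, r)
            if hit is None:
                continue
            sub, inside = hit
            # voxel-accurate surface distance of the stamped sphere must
            # match the drawn value, else the voxelization biases the
            # realized distance law upward by a voxel or two
            realized = float(edt[sub][inside].min())
            if abs(realized - d) > vs.max() / 2.0:
                continue
            gid += 1
            lab_sub = labels[sub]
            lab_sub[inside] = gid
            labels[sub] = lab_sub
            nvox = int(inside.sum())
            rows.append({
                "id": gid, "target_volume_um3": vol,
                "voxel_count": nvox, "volume_um3": nvox * voxvol,
                "cz_um": c[0], "cy_um": c[1], "cx_um": c[2],
                "target_distance_um": d,
                "realized_distance_um": realized,
                "region": int(region[tuple(vox)]),
            })
            break
    return labels, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# rendering


def _apply_noise(img: np.ndarray, config: PhantomConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.poisson_scale > 0:
        img = rng.poisson(img * config.poisson_scale).astype(np.float32)
        img /= config.poisson_scale
    if config.gaussian_sigma > 0:
        img = img + rng.normal(0.0, config.gaussian_sigma, img.shape)
    return np.clip(img, 0.0, None).astype(np.float32)


def simulate(config: PhantomConfig,
             seed: int | np.random.Generator = 0
             ) -> tuple[VoxelGrid, PhantomGroundTruth]:
    """Generate a full low-resolution phantom: tissue, islets, nerves,
    ganglia, rendered channels with the configured noise, plus truth.

    Deterministic: the same config and seed give bit-identical volumes.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    region = make_tissue_mask(config)
    vs = np.asarray(config.voxel_size_um, dtype=float)
    voxvol = float(np.prod(vs))

    specs = sample_islets(config, rng)
    islet_labels = np.zeros(config.shape, dtype=np.int32)
    for row in specs.itertuples():
        _rasterize_ellipsoid(
            islet_labels,
            (row.cz_um, row.cy_um, row.cx_um),
            (row.rz_um, row.ry_um, row.rx_um),
            vs, value=row.Index + 1,
        )
    islet_mask = islet_labels > 0

    nerve_mask, nerve_stats = draw_nerves(config, islet_labels, specs, region, rng)
    # keep ganglia clear of tubes so detection never merges them
    forbidden = ndi.binary_dilation(nerve_mask, iterations=3)
    # distance reference: islets large enough to be real islets
    counts0 = np.bincount(islet_labels.ravel())
    ref_ids = np.flatnonzero(
        counts0 * voxvol >= config.ganglion_islet_reference_min_volume_um3)
    ref_ids = ref_ids[ref_ids > 0]
    islet_ref = np.isin(islet_labels, ref_ids)
    ganglion_labels, ganglion_table = place_ganglia(
        config, islet_mask, region, forbidden, rng,
        distance_reference=islet_ref)

    inten = config.intensity
    tissue = region > 0
    insulin = np.zeros(config.shape, dtype=np.float32)
    insulin[tissue] = inten["tissue_insulin"]
    insulin[islet_mask] = inten["islet"]
    nerve_ch = np.zeros(config.shape, dtype=np.float32)
    nerve_ch[tissue] = inten["tissue_nerve"]
    nerve_ch[nerve_mask] = inten["nerve"]
    nerve_ch[ganglion_labels > 0] = inten["ganglion"]
    insulin = _apply_noise(insulin, config, rng)
    nerve_ch = _apply_noise(nerve_ch, config, rng)

    grid = VoxelGrid(
        data=np.stack([insulin, nerve_ch]),
        channels=["insulin", config.nerve_channel],
        voxel_size_um=tuple(config.voxel_size_um),
        magnification_tag=config.magnification_tag,
        region_mask=region,
    )

    # truth tables by voxel counting
    n_islets = len(specs)
    counts = np.bincount(islet_labels.ravel(), minlength=n_islets + 1)[1:]
    inn_counts = np.bincount((islet_labels * nerve_mask).ravel(),
                             minlength=n_islets + 1)[1:]
    islet_table = specs.copy()
    islet_table.insert(0, "id", np.arange(1, n_islets + 1))
    islet_table["target_volume_um3"] = islet_table.pop("volume_um3")
    islet_table["voxel_count"] = counts
    islet_table["volume_um3"] = counts * voxvol
    islet_table["intra_islet_nerve_volume_um3"] = inn_counts * voxvol
    regs = []
    for row in specs.itertuples():
        vox = np.minimum(
            np.floor(np.array([row.cz_um, row.cy_um, row.cx_um]) / vs).astype(int),
            np.asarray(config.shape) - 1,
        )
        regs.append(int(region[tuple(vox)]))
    islet_table["region"] = regs

    truth = PhantomGroundTruth(
        islet_labels=islet_labels,
        nerve_mask=nerve_mask,
        ganglion_labels=ganglion_labels,
        islet_table=islet_table,
        ganglion_table=ganglion_table,
        realized={
            "n_islets": n_islets,
            "islet_voxels": int(islet_mask.sum()),
            "tissue_voxels": int(tissue.sum()),
            "beta_volume_percent": 100.0 * islet_mask.sum() / tissue.sum(),
            "innervated_count_fraction": (
                float(specs["innervated"].mean()) if n_islets else 0.0),
            "innervated_volume_share_percent": (
                100.0 * specs.loc[specs["innervated"], "volume_um3"].sum()
                / specs["volume_um3"].sum() if n_islets else 0.0),
            "n_ganglia": len(ganglion_table),
            **nerve_stats,
        },
    )
    return grid, truth


# --------------------------------------------------------------------------
# high-resolution cell-mode phantom


def simulate_cell_phantom(config: PhantomConfig,
                          seed: int | np.random.Generator = 0
                          ) -> tuple[VoxelGrid, PhantomGroundTruth]:
    """Render a single-islet subvolume at confocal spacing with packed
    spherical beta/alpha cells and terminal nerve twigs.

    Exactly ``round(beta_contact_fraction x n_beta)`` beta cells (and
    the alpha analog) receive a nerve twig that overlaps them by a
    couple of voxels; twigs never touch other cells, so the generative
    contact fractions are realized exactly in the truth table.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vs = np.asarray((5.0, 1.67, 1.67))
    R = config.cell_islet_diameter_um / 2.0
    margin = 30.0
    ext = 2 * (R + margin)
    shape = tuple(int(np.ceil(ext / v)) for v in vs)
    center = np.asarray(shape) * vs / 2.0

    # cell lattice inside the islet sphere
    sp = np.asarray(config.cell_spacing_um, dtype=float)
    rc = config.cell_radius_um
    grids = [np.arange(margin, ext - margin, s) for s in sp]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    jitter = rng.uniform(-0.5, 0.5, size=pts.shape)
    jitter[:, 0] = 0.0
    pts = pts + jitter
    # snap cell centers to z-slice centers so each cell lives in one plane
    pts[:, 0] = (np.floor(pts[:, 0] / vs[0]) + 0.5) * vs[0]
    keep = np.linalg.norm(pts - center, axis=1) <= (R - rc)
    pts = pts[keep]
    n_cells = len(pts)
    order = rng.permutation(n_cells)
    n_beta = int(round(config.cell_beta_fraction * n_cells))
    is_beta = np.zeros(n_cells, dtype=bool)
    is_beta[order[:n_beta]] = True

    cell_labels = np.zeros(shape, dtype=np.int32)
    for i, p in enumerate(pts):
        _rasterize_ellipsoid(cell_labels, p, (rc, rc, rc), vs, value=i + 1)
    cell_mask = cell_labels > 0

    # Designated contacts receive a short terminal stub that overlaps the
    # target cell by a few voxels; a stub is only accepted when it touches
    # no other cell, and failed cells are replaced from the remaining pool
    # so the realized contact count matches round(fraction x n) exactly.
    contact = np.zeros(n_cells, dtype=bool)
    nerve = np.zeros(shape, dtype=bool)
    twig_r = config.twig_radius_um
    penetration = 3.5  # um of overlap into the target cell
    stub_out = 4.0     # um the stub extends beyond the cell surface
    for beta_flag, frac in ((True, config.beta_contact_fraction),
                            (False, config.alpha_contact_fraction)):
        idx = np.flatnonzero(is_beta == beta_flag)
        k = int(round(frac * len(idx)))
        queue = list(rng.permutation(idx))
        placed = 0
        while placed < k and queue:
            i = int(queue.pop())
            c = pts[i]
            for _try in range(60):
                ang = rng.uniform(0, 2 * np.pi)
                direction = np.array([0.0, np.sin(ang), np.cos(ang)])
                start = c + direction * (rc + stub_out)
                end = c + direction * (rc - penetration)
                tmp = rasterize_tube(np.stack([start, end]), twig_r, shape, vs)
                other = tmp & cell_mask & (cell_labels != i + 1)
                if other.any() or not (tmp & (cell_labels == i + 1)).any():
                    continue
                nerve |= tmp
                contact[i] = True
                placed += 1
                break

    # distractor twigs: nerve signal that contacts no cell
    dil = ndi.binary_dilation(cell_mask, iterations=2)
    for _ in range(config.n_distractor_twigs):
        for _try in range(50):
            p = rng.uniform([0, 0, 0], np.asarray(shape) * vs)
            ang = rng.uniform(0, 2 * np.pi)
            direction = np.array([0.0, np.sin(ang), np.cos(ang)])
            q = p + direction * config.twig_length_um
            tmp = rasterize_tube(np.stack([p, q]), twig_r, shape, vs)
            if (tmp & dil).any():
                continue
            nerve |= tmp
            break

    inten = config.intensity
    insulin = np.where(cell_mask & np.isin(cell_labels, np.flatnonzero(is_beta) + 1),
                       inten["cell"], 0.0).astype(np.float32)
    glucagon = np.where(cell_mask & ~np.isin(cell_labels, np.flatnonzero(is_beta) + 1),
                        inten["cell"], 0.0).astype(np.float32)
    nerve_ch = np.where(nerve, inten["nerve"], 0.0).astype(np.float32)
    insulin = _apply_noise(insulin, config, rng)
    glucagon = _apply_noise(glucagon, config, rng)
    nerve_ch = _apply_noise(nerve_ch, config, rng)

    grid = VoxelGrid(
        data=np.stack([insulin, glucagon, nerve_ch]),
        channels=["insulin", "glucagon", config.nerve_channel],
        voxel_size_um=tuple(vs),
        magnification_tag="confocal10x",
    )
    voxvol = float(np.prod(vs))
    counts = np.bincount(cell_labels.ravel(), minlength=n_cells + 1)[1:]
    cell_table = pd.DataFrame({
        "id": np.arange(1, n_cells + 1),
        "cell_type": np.where(is_beta, "beta", "alpha"),
        "voxel_count": counts,
        "volume_um3": counts * voxvol,
        "cz_um": pts[:, 0], "cy_um": pts[:, 1], "cx_um": pts[:, 2],
        "contact_designated": contact,
    })
    truth = PhantomGroundTruth(
        cell_labels=cell_labels,
        nerve_mask=nerve,
        cell_table=cell_table,
        realized={
            "n_cells": n_cells,
            "n_beta": int(is_beta.sum()),
            "beta_contact_fraction": (
                float(contact[is_beta].mean()) if is_beta.any() else 0.0),
            "alpha_contact_fraction": (
                float(contact[~is_beta].mean()) if (~is_beta).any() else 0.0),
        },
    )
    return grid, truth


def config_to_dict(config: PhantomConfig) -> dict:
    d = asdict(config)
    return d
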