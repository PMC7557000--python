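# Methods

`isletatlas` quantifies pancreatic islets and their innervation in
whole-organ 3D fluorescence volumes (cleared-tissue light-sheet stacks
and high-resolution confocal subvolumes), and ships a calibrated
synthetic phantom generator so that every stage of the pipeline can be
validated against known ground truth at desk scale.

## Image model and segmentation

Input volumes are multi-channel scalar grids on a fixed (z, y, x) axis
order with per-axis voxel sizes in micrometres. All physical quantities
are expressed in um / um^3; mm^3 appears only in reported densities
(1 mm^3 = 1e9 um^3). Supported acquisition settings and their voxel
sizes: light-sheet 1.3x (5 x 5 x 5 um), 4x (5 x 1.63 x 1.63), 12x
(2 x 0.602 x 0.602) and 10x confocal (5 x 1.67 x 1.67). Integer camera
data (8/16-bit) is promoted to float32 internally.

Object detection follows the surface-style workflow of commercial
volume-rendering packages, expressed as explicit operators in physical
units so the result is voxel-pitch independent:

1. **Pre-smoothing** — Gaussian with FWHM equal to the *smoothing
   factor* (10 um for islets at 1.3x, 3.25 um for islets and nerves at
   4x and above).
2. **Background estimate** — Gaussian blur with sigma = *background
   diameter* / 2. The background diameter is the scale above which
   structure counts as background: the largest expected islet diameter
   for islets (default 250 um, a per-dataset setting), 12.2 um for
   nerve fibers, and 150 um for ganglion-sized blobs (the 12.2 um
   nerve scale hollows out compact objects tens of micrometres across,
   so ganglion detection gets its own blob-preserving scale).
   For sigma above 8 voxels the Gaussian is computed as three
   box-filter passes (O(N) independent of sigma; the approximation
   error is far below the thresholding granularity).
3. **Subtraction** clamped at zero; a spatially constant image
   therefore yields an empty mask.
4. **Threshold** — global Otsu on the subtracted image by default, with
   an absolute override. Otsu places the islet boundary at roughly the
   half-maximum of the smoothed edge, which reproduces ellipsoid
   volumes almost exactly for objects larger than ~50 voxels; objects
   a few voxels across are eroded by up to one shell (see
   *Limitations*).
5. **Connected components** under 26-connectivity by default
   (filamentous nerves fragment under 6-connectivity), with an optional
   minimum object volume. Per-object tables carry voxel count, volume
   (count x voxel volume, exactly), centroid, per-channel intensity
   sum/mean, majority region and a border flag; objects touching the
   volume border are flagged but kept.

Sympathetic-marker (TH) channels contain TH+ beta cells as well as
fibers; these are removed by rule rather than by hand: an object is
excluded iff its volume is below 120 um^3 AND it lies entirely inside
an insulin+ islet AND it overlaps insulin foreground.

Ganglia are detected among nerve-channel components as compact blobs:
volume within [20,000, 400,000] um^3 and marching-cubes sphericity
psi = pi^(1/3) (6V)^(2/3) / A >= 0.4 (both configurable); an externally
supplied ganglion label grid bypasses detection. Endocrine cells at
high resolution are segmented by watershed on the anisotropy-aware
distance transform of the cell mask, seeded by distance-transform
maxima separated by at least one cell diameter (8 um); the distance
transform is pre-blurred at a quarter cell diameter to collapse the
tied plateau maxima of small convex cells into a single seed. Adjacent
cells the watershed cannot split remain one object.

## Distance-transform geometry

Distances are exact anisotropic Euclidean distances between voxel
centers; the error of any reported distance is therefore bounded by one
voxel pitch. An islet is **innervated** when its minimum distance to
nerve foreground is exactly 0 (voxel overlap, the "touching"
criterion); the secondary **near-nerve** criterion uses a configurable
cutoff of 1.6 um (about one in-plane voxel at 4x). Both are always
computed and reported side by side. An empty nerve mask yields
undefined (NaN) distances, never an infinite sentinel. Per-cell
contacts use the same distance-0 rule. Ganglion-to-islet distance is
the minimum over ganglion voxels of the islet distance field — a
surface-to-surface distance up to voxel quantization.

## Summary metrics and statistics

Per region (total / duodenal / splenic, regions supplied as an integer
sidecar mask): beta cell volume percent (insulin+ volume / tissue
volume x 100), islets per mm^3, median and mean islet volume, volume
bin percentages over [0, 1000), [1000, 50,000), [50,000, 500,000),
[500,000, inf) um^3, normalized insulin intensity (mean islet intensity
over a reference — the sample's whole-tissue mean by default, a control
group mean for cross-group comparisons), endocrine nerve density
(nerve volume inside islets / islet volume), exocrine nerve density
(nerve outside islets / non-islet tissue), innervated fraction, the
innervated share of summed islet volume, the innervated:non-innervated
mean volume ratio, and nerve-marker intensity per islet volume.
Endocrine plus exocrine nerve volume equals total nerve volume by
construction and is asserted on every run. Equivalent sphere diameter
d = 2 (3V / 4 pi)^(1/3) converts the bin edges to 12 and 98 um.

Group comparisons are normality-gated: Shapiro-Wilk per group at alpha
0.05; all groups Gaussian -> unpaired two-tailed t test (2 groups) or
one-way ANOVA with Tukey HSD (3+); otherwise Mann-Whitney (exact for
small untied samples) or Kruskal-Wallis with Dunn's multiple
comparisons. Dunn's test is implemented directly (pairwise z on mean
ranks with tie correction, Bonferroni family adjustment). No correction
is applied across metrics. Median confidence intervals use the exact
binomial order-statistic method. Correlations are likewise gated:
Pearson when both variables pass Shapiro-Wilk, Spearman otherwise.
Staining-intensity metrics are refused across staining batches, since
intensities are only comparable within a batch.

## The phantom generator

The phantoms are statistical emulations, not anatomical simulations:
they reproduce the joint distributions the analysis measures, not
tissue appearance. The default (healthy C57BL/6 mouse) calibration:

| parameter | default | basis |
|---|---|---|
| grid | 512 x 512 x 128 voxels at 5 um | whole-pancreas 1.3x setting |
| tissue | elliptical-cylinder slab, ~65% of the grid (~2.7 mm^3) | desk-scale organ |
| beta volume fraction | 1.31% of tissue | whole-organ measurement |
| islet volume law | 2-component lognormal mixture, truncated to [100 um^3, d = 250 um] | fitted to bin weights 3.13/39.29/36.58/20.0% (normalized; as printed they sum to 99.0) |
| innervated islet fraction | 6.1% by count | contact-criterion fraction |
| innervated volume share | 43% of summed islet volume | implies mean-ratio r = s(1-f)/(f(1-s)) ~ 11.6 |
| endocrine / exocrine nerve density | 2.0% / 0.3% | keeps the endocrine:exocrine ratio above sixfold |
| ganglia | Poisson at 21.5 / mm^3; lognormal volume, mean 83,467 um^3, CV 0.6, bounded [25k, 350k] | sparse compact blobs |
| ganglion-islet distance | gamma, mean 47.3 um, SD 20 um, >= one voxel | surface-to-surface |
| beta cell contacts | 9.4% of beta cells (alpha: 47%) | cell-mode calibration |
| noise | Poisson scaling + additive Gaussian, both disabled at 0 | acquisition noise model |

The mixture is fitted once, deterministically (Nelder-Mead least
squares on the truncated CDF at the bin edges from a fixed start); the
fit reproduces the normalized bin weights to < 0.01 points.

**Two-population innervation calibration.** At desk-scale islet counts
(~60-120 islets per phantom versus tens of thousands per real organ) no
subset of 6% of draws from the single size law can carry 43% of the
volume, so innervated islets are drawn from their own lognormal
(sigma = 0.6) whose truncated mean is solved to be r times the base
mean, then rescaled as a group so the volume share is met exactly, and
the full set rescaled (bounded factor) so the summed volume matches the
configured tissue fraction. Consequently the phantom's overall volume
histogram is slightly heavier in the top bin than the pure sampler; the
bin-weight law is the property of the sampler (`sample_islet_volumes`),
the innervation joint law the property of the placed phantom.

Islets are axis-aligned ellipsoids (axis ratio <= 1.5) placed uniformly
in tissue with spherical-bound non-overlap rejection and a 15 um
minimum gap, large first. Nerves are drawn as (a) random-walk arbors
confined to each innervated islet, grown to the per-islet fill that
realizes the endocrine density target (guaranteeing distance-0
contact), and (b) persistent-random-walk exocrine tubes (radius 2-4 um)
that keep three voxels clear of every islet, stopped at the exocrine
volume target — so non-innervated islets never touch a nerve. Ganglia
are spheres placed where the islet distance field matches the drawn
gamma distance; the realized voxelized surface distance is checked
against the drawn value (within half a voxel) so the distance law
survives quantization. Ganglion distances are defined relative to
islets of at least 1000 um^3; smaller insulin+ specks are five or fewer
beta cells and below the detection scale, and letting them anchor the
distance reference produces rare large outliers. Ganglia also keep
clear of nerve tubes (3-voxel dilation) so blob detection never merges
a ganglion with a fiber.

**Cell mode** renders one islet (120 um diameter) at confocal spacing
(5 x 1.67 x 1.67 um) packed with spherical cells (radius 3.8 um, 80%
beta / 20% alpha) on a jittered lattice with 15 um z-pitch, snapped to
z-slice centers so each cell is resolved in a single optical plane —
the regime in which per-cell contact counting is unambiguous. Exactly
round(fraction x n) cells per type receive a short terminal nerve stub
that penetrates the cell by ~3.5 um; a stub is only accepted if it
touches no other cell, failed cells are replaced from the pool, so the
generative contact fractions are realized exactly. Non-contacting
distractor segments provide nerve signal away from cells. The per-islet
intra-islet nerve layout (single arbor; terminal stubs in cell mode) is
a deliberate simplification — no per-islet nerve-volume distribution is
available to calibrate against.

Disease presets rescale the same machinery: autoimmune-diabetic NOD
(beta volume at 10% of nondiabetic, volume law shifted down, endocrine
nerve density doubled, ganglia at 171.7 um from islets), STZ day 5/15
(beta volume 70%/40% of control, insulin intensity reduced, nerve
densification, 30% smaller ganglia at day 15), a sympathetic-marker
variant (27.7% of islets TH-contacted), and human control / type-2
diabetes presets (beta fractions inside the reported donor ranges,
near-equal endocrine and exocrine densities, lower contact fractions,
larger ganglia).

Determinism: one `numpy.random.Generator` drives a phantom; the same
config and seed give bit-identical volumes and truth tables.

## What passing tests do and do not show

The phantoms exercise every operator against exact ground truth, but
they are geometric idealizations: ellipsoidal islets with hard edges
and uniform intensity, tubular nerves, spherical ganglia, no
immune infiltrate, vasculature, staining gradients, tiling artifacts or
depth-dependent attenuation. Recovery of the calibration targets on
phantoms demonstrates that the measurement chain is unbiased under the
stated geometry and noise model — not that segmentation parameters are
optimal for any particular real acquisition.

## Problem sizes and numerical choices

Validation runs use the default 512 x 512 x 128 grid for whole-organ
recovery (one phantom generates and analyzes in about two minutes on
one CPU), pooled replicates for ganglion statistics (their density
estimate is Poisson-limited, SE ~1.3 / mm^3 across five default-size
phantoms), five cell-mode subvolumes (~2000 beta cells pooled) for
contact statistics, and reduced grids (64-96 z-planes, 160-320 in
plane) for unit and property tests. The distance transform is validated
by exhaustive brute-force comparison on grids up to 16^3. Otsu
thresholds are computed on the background-subtracted image; degenerate
(empty or constant) images short-circuit to an empty mask. Tie-breaks
in watershed seeding are resolved by the quarter-diameter blur of the
distance transform rather than by arbitrary plateau order.

## Limitations

- Islets smaller than ~30 voxels are eroded by up to one voxel shell
  (and 1-2 voxel specks can be missed entirely) by the global-Otsu
  surface; the paper of record for this workflow bins sub-1000 um^3
  insulin+ structures separately for the same reason. Reported
  distances carry a one-voxel-pitch quantization bound.
- The measured innervated:non-innervated volume ratio is biased
  slightly downward relative to the generative ratio because
  rasterization inflates the relative volume of the smallest islets.
- Contact counting reports cells contacted, never contacts per cell;
  merged adjacent cells count as one.
- Group statistics treat the sample (animal/donor) as the unit when fed
  per-sample tables and islets as units when fed per-islet tables; both
  are supported and the caller's table choice is logged, but no
  mixed-effects nesting is attempted.
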