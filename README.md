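# isletatlas

Whole-organ 3D quantification of pancreatic islets and their
innervation — an open, tested reimplementation of the surface-based
morphometry used on cleared-tissue light-sheet volumes, for
diabetes researchers who need reproducible islet/nerve metrics without
proprietary rendering software.

Given multi-channel volumes (insulin plus a neural marker such as
NF200, TH or VAChT), the package measures, per pancreas and per
anatomical region (duodenal / splenic):

- **β cell mass** as insulin⁺ volume percent, islet counts per mm³,
  median islet volume and the islet volume distribution over the bins
  [0, 1000), [1000, 50 000), [50 000, 500 000), [500 000, ∞) μm³
  (equivalent sphere diameters d = 2·(3V/4π)^⅓: the inner edges
  correspond to 12 and 98 μm);
- **innervation**: endocrine nerve density (nerve volume inside islets
  per islet volume) versus exocrine nerve density, the fraction of
  islets touching a nerve (minimum anisotropic Euclidean distance = 0,
  with a secondary < 1.6 μm near-nerve criterion), and the volume
  contrast between innervated and non-innervated islets;
- **intrapancreatic ganglia**: density per mm³, volumes, and
  surface distances to the nearest islet;
- **cell-level contacts** at high resolution: the percentage of β (or
  α) cells whose watershed-segmented bodies share a voxel with nerve
  foreground;
- **group statistics** with a normality gate: Shapiro–Wilk per group,
  then t test / ANOVA + Tukey or Mann–Whitney / Kruskal–Wallis + Dunn,
  α = 0.05.

Because the original imaging data of this kind are typically not
deposited, the package ships a ground-truthed synthetic phantom
generator (`isletatlas.phantom`) whose presets are calibrated to
published whole-organ values (β volume 1.31 % of tissue, 6.1 % of
islets innervated carrying 43 % of islet volume, 21.5 ganglia/mm³ of
mean volume 83 467 μm³ at 47.3 μm from islets, 9.4 % of β cells
contacting nerves, and diabetic-model presets with β-cell loss and
nerve densification). Every pipeline stage is validated against these
phantoms' exact voxel-level truth.

## Worked example

Simulate the healthy-mouse phantom, run the full pipeline and print the
summary (identical results for identical seeds):

```bash
isletatlas run --preset mouse_c57_default --seed 42 --no-noise --out results/c57
```

which ends with the measured summary (abridged):

```
## Regional summary
### region: total
- beta cell volume (%): 1.309
- islets / mm^3: 22.53
- median islet volume (um^3): 1.694e+05
- endocrine nerve density (%): 2.003
- exocrine nerve density (%): 0.3638
- innervated islets (%): 6.452
- innervated share of islet volume (%): 43.04
- volume-bin percentages: 4.84, 35.48, 24.19, 35.48

## Innervated vs non-innervated islets
- total: mean volume ratio 10.96-fold; innervated share 43.04%

## Intrapancreatic ganglia
- count: 57
- density: 20.72 per mm^3
```

Reading this: the segmentation measured a β cell volume of 1.309 % of
tissue (the preset's generative condition is 1.31 %); 6.45 % of the 62
detected islets overlap a nerve, and those islets are 10.96-fold larger
on average than non-innervated ones, so they hold 43.0 % of the summed
islet volume; endocrine nerve density exceeds exocrine ~5.5-fold; and
blob detection recovered the ganglia at 20.7 /mm³. The same measurements
run on real OME-TIFF stacks via
`isletatlas run --config my_study.yaml --out results/sample1`, where the
YAML maps channels, voxel sizes and an optional duodenal/splenic region
mask (see `isletatlas.pipeline.validate_config` for the schema).

From Python, the operators compose directly:

```python
from isletatlas import (read_volume, segment_islets, segment_nerves,
                        islet_nerve_distances, classify_innervation,
                        region_summary)

grid = read_volume("pancreas.ome.tif", ["insulin", "nf200"],
                   voxel_size_um=(5, 5, 5), magnification_tag="1.3x")
islets = segment_islets(grid)
nerves = segment_nerves(grid)
records = islet_nerve_distances(islets, nerves.mask)
print(classify_innervation(records))
print(region_summary(records, nerves.mask, islets.mask,
                     grid.tissue_mask(), grid.voxel_size_um))
```

Group comparisons run on per-sample tables:

```bash
isletatlas stats --table per_sample.csv --metric beta_volume_percent
```

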