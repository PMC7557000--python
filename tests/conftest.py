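import pytest

from isletatlas import phantom


def noise_free(cfg: phantom.PhantomConfig) -> phantom.PhantomConfig:
    cfg.poisson_scale = 0.0
    cfg.gaussian_sigma = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_phantom():
    """Fast noise-free C57 phantom on a reduced grid (few islets)."""
    cfg = noise_free(phantom.preset("mouse_c57_default"))
    cfg.shape = (64, 192, 192)
    return phantom.simulate(cfg, 11)


@pytest.fixture(scope="session")
def midsize_phantom():
    """Mid-size noise-free C57 phantom with enough islets for
    innervation statistics."""
    cfg = noise_free(phantom.preset("mouse_c57_default"))
    cfg.shape = (96, 320, 320)
    return phantom.simulate(cfg, 5)


@pytest.fixture(scope="session")
def full_run():
    """Full default-size C57 phantom plus the measured pipeline outputs
    (shared across the recovery tests; generation dominates runtime)."""
    from isletatlas import segmentation, spatial, stats

    cfg = noise_free(phantom.preset("mouse_c57_default"))
    grid, truth = phantom.simulate(cfg, 42)
    islets = segmentation.segment_islets(grid)
    nerves = segmentation.segment_nerves(grid)
    records = spatial.islet_nerve_distances(islets, nerves.mask)
    summary = stats.region_summary(
        records, nerves.mask, islets.mask, grid.tissue_mask(),
        grid.voxel_size_um, grid.region_mask)
    ganglia = segmentation.segment_ganglia(grid)
    gtable, gdensity = spatial.ganglion_metrics(
        ganglia, islets.mask, grid.tissue_mask(), grid.voxel_size_um)
    return {
        "grid": grid, "truth": truth, "islets": islets, "nerves": nerves,
        "records": records, "summary": summary,
        "ganglia": gtable, "ganglion_density": gdensity,
    }
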