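import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from isletatlas import stats
from isletatlas.stats import (
    correlate,
    equivalent_sphere_diameter,
    group_compare,
    innervated_comparison,
    median_confidence_interval,
    region_summary,
    volume_distribution,
)


@pytest.mark.parametrize("volume,expected", [
    (1000.0, 12), (500_000.0, 98), (4.0 / 3.0 * np.pi, 2),
])
def test_equivalent_sphere_diameter(volume, expected):
    exact, rounded = equivalent_sphere_diameter(volume)
    assert rounded == expected
    if volume == 4.0 / 3.0 * np.pi:
        assert exact == pytest.approx(2.0)


def test_equivalent_sphere_diameter_rejects_nonpositive():
    with pytest.raises(ValueError):
        equivalent_sphere_diameter(0.0)


def test_volume_distribution_examples():
    p, med = volume_distribution([500, 2000, 60_000, 600_000])
    assert np.allclose(p, [25, 25, 25, 25])
    p, _ = volume_distribution([2000, 3000, 40_000])
    assert np.allclose(p, [0, 100, 0, 0])
    with pytest.raises(ValueError):
        volume_distribution([])


def test_bin_percentages_sum_to_100():
    rng = np.random.default_rng(0)
    v = np.exp(rng.normal(10, 2, 500))
    p, _ = volume_distribution(v)
    assert p.sum() == pytest.approx(100.0, abs=1e-6)
    assert ((0 <= p) & (p <= 100)).all()


def test_innervated_comparison_arithmetic():
    rec = pd.DataFrame({
        "volume_um3": [100.0, 300.0, 10.0, 30.0],
        "innervated": [True, True, False, False],
        "region": [1, 1, 2, 2],
    })
    out = innervated_comparison(rec)
    total = out[out["region"] == "total"].iloc[0]
    assert total["mean_volume_ratio"] == pytest.approx(10.0)
    assert total["innervated_share_percent"] == pytest.approx(400 / 440 * 100)


def test_innervated_comparison_degenerate_classes():
    one_class = pd.DataFrame({"volume_um3": [5.0, 6.0],
                              "innervated": [True, True], "region": [1, 1]})
    out = innervated_comparison(one_class)
    assert np.isnan(out.iloc[0]["mean_volume_ratio"])
    equal = pd.DataFrame({"volume_um3": [50.0, 50.0],
                          "innervated": [True, False], "region": [1, 1]})
    assert innervated_comparison(equal).iloc[0]["mean_volume_ratio"] == (
        pytest.approx(1.0))


def _toy_masks():
    tissue = np.zeros((10, 10, 10), dtype=bool)
    tissue[:, :, :] = True  # 1000 voxels
    islet = np.zeros_like(tissue)
    islet[0, 0, :10] = True
    islet[0, 1, :3] = True  # 13 voxels
    nerve = np.zeros_like(tissue)
    return tissue, islet, nerve


def test_region_summary_beta_volume_percent():
    tissue, islet, nerve = _toy_masks()
    rec = pd.DataFrame({"volume_um3": [13 * 125.0], "region": [1],
                        "innervated": [False]})
    out = region_summary(rec, nerve, islet, tissue, (5.0, 5.0, 5.0))
    assert out.iloc[0]["beta_volume_percent"] == pytest.approx(1.3)


def test_region_summary_nerve_densities():
    tissue = np.ones((10, 10, 10), dtype=bool)
    islet = np.zeros_like(tissue)
    islet[0, :10, :10] = True  # 100 voxels
    nerve = np.zeros_like(tissue)
    nerve[0, 0, :5] = True       # 5 voxels inside the islet
    nerve[5, 0, :5] = True       # 5 voxels outside
    rec = pd.DataFrame({"volume_um3": [100 * 125.0], "region": [1],
                        "innervated": [True]})
    out = region_summary(rec, nerve, islet, tissue, (5.0, 5.0, 5.0))
    row = out.iloc[0]
    assert row["endocrine_nerve_density_percent"] == pytest.approx(5.0)
    assert row["exocrine_nerve_density_percent"] == pytest.approx(5 / 900 * 100)
    # conservation: endocrine + exocrine = total nerve volume
    assert (row["endocrine_nerve_volume_um3"] + row["exocrine_nerve_volume_um3"]
            == pytest.approx(nerve.sum() * 125.0))


def test_insulin_normalization_identity():
    tissue, islet, nerve = _toy_masks()
    rec = pd.DataFrame({"volume_um3": [1625.0], "region": [1],
                        "innervated": [False],
                        "intensity_mean_insulin": [815.0]})
    out = region_summary(rec, nerve, islet, tissue, (5.0, 5.0, 5.0),
                         insulin_reference=815.0)
    assert out.iloc[0]["normalized_insulin_intensity"] == pytest.approx(1.0)


def test_region_summary_empty_islets():
    tissue, islet, nerve = _toy_masks()
    rec = pd.DataFrame(columns=["volume_um3", "region", "innervated"])
    out = region_summary(rec, nerve, np.zeros_like(islet), tissue,
                         (5.0, 5.0, 5.0))
    row = out.iloc[0]
    assert row["n_islets"] == 0 and row["islets_per_mm3"] == 0
    assert np.isnan(row["median_islet_volume_um3"])


def test_identical_samples_never_significant():
    table = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                          "m": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
    res = group_compare(table, "m")
    assert res.test == "t"
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_mannwhitney_exact_p_one_tenth():
    """[1,2,3] vs [4,5,6]: the most extreme of the 20 rank arrangements,
    exact two-sided p = 2/20 = 0.1."""
    table = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                          "m": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    res = group_compare(table, "m", force_nonparametric=True)
    assert res.test == "MannWhitney"
    assert res.p_value == pytest.approx(0.1)


def test_significance_threshold_rule():
    res = stats.GroupStatsResult(
        metric="m", groups=["a", "b"], n={}, mean={}, sem={}, median={},
        median_ci={}, shapiro_p={}, test="t", statistic=1.0, p_value=0.06)
    assert not res.significant
    res.p_value = 0.04999
    assert res.significant


def test_normality_gate_routes_to_anova_or_kruskal():
    rng = np.random.default_rng(0)
    normal = pd.DataFrame({
        "group": np.repeat(["a", "b", "c"], 20),
        "m": np.concatenate([rng.normal(0, 1, 20), rng.normal(0.2, 1, 20),
                             rng.normal(3, 1, 20)]),
    })
    res = group_compare(normal, "m")
    assert res.test == "ANOVA+Tukey"
    assert res.pairwise is not None and len(res.pairwise) == 3
    skewed = normal.assign(m=np.exp(normal["m"] * 2))
    res2 = group_compare(skewed, "m")
    assert res2.test == "KruskalWallis+Dunn"
    assert res2.pairwise is not None
    assert ((res2.pairwise["p_value"] >= 0) & (res2.pairwise["p_value"] <= 1)).all()


def test_dunn_flags_match_separation():
    """Dunn post hoc flags the clearly separated pair and not the
    overlapping one."""
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 25)
    b = a + 0.05
    c = rng.normal(8, 1, 25)
    out = stats.dunn_test({"a": a, "b": b, "c": c})
    row_ab = out[(out.group_a == "a") & (out.group_b == "b")].iloc[0]
    row_ac = out[(out.group_a == "a") & (out.group_b == "c")].iloc[0]
    assert not row_ab["significant"]
    assert row_ac["significant"]


def test_group_compare_input_validation():
    table = pd.DataFrame({"group": ["a"] * 3, "m": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        group_compare(table, "m")
    small = pd.DataFrame({"group": ["a", "a", "a", "b", "b"],
                          "m": [1.0, 2.0, 3.0, 4.0, 5.0]})
    with pytest.raises(ValueError):
        group_compare(small, "m")


def test_median_ci_coverage_by_enumeration():
    """The order-statistic interval must reach nominal coverage under
    the exact binomial law."""
    n = 25
    med, lo, hi = median_confidence_interval(np.arange(1.0, n + 1))
    k_lo = int(lo)  # order statistic index (values are 1..n)
    coverage = 1.0 - 2.0 * sps.binom.cdf(k_lo - 1, n, 0.5)
    assert coverage >= 0.95
    assert lo <= med <= hi


def test_correlate_perfect_and_sign():
    x = np.arange(1.0, 11.0)
    res = correlate(x, 2 * x)
    assert res["r"] == pytest.approx(1.0)
    assert res["p_value"] < 0.05 and res["significant"]
    rng = np.random.default_rng(0)
    res2 = correlate(x, -x + rng.normal(0, 1e-9, 10))
    assert res2["r"] == pytest.approx(-1.0, abs=1e-6)
    assert res2["sign"] == -1


def test_correlate_validation():
    with pytest.raises(ValueError):
        correlate([1, 2, 3], [1, 2])
    with pytest.raises(ValueError):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_correlate_p_matches_permutation_oracle():
    """Analytic p agrees with a permutation null within Monte-Carlo
    error (the independent oracle)."""
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 12)
    y = 0.8 * x + rng.normal(0, 1, 12)
    res = correlate(x, y)
    stat = abs(res["r"])
    exceed = 0
    n_perm = 5000
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if res["method"] == "pearson":
            r = abs(sps.pearsonr(x, yp).statistic)
        else:
            r = abs(sps.spearmanr(x, yp).statistic)
        exceed += r >= stat
    p_perm = (exceed + 1) / (n_perm + 1)
    se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(p_perm - res["p_value"]) < max(4 * se, 0.02)
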