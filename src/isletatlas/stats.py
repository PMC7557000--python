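"""Summary morphometry and normality-gated group statistics.

The inferential layer mirrors standard practice in whole-organ islet
morphometry: Shapiro-Wilk per group at alpha 0.05; if every group looks
Gaussian use an unpaired two-tailed t test (2 groups) or one-way ANOVA
with Tukey's post hoc (>=3 groups); otherwise Mann-Whitney (2) or
Kruskal-Wallis with Dunn's post hoc (>=3). No correction is applied
across metrics, only within a post hoc family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

ALPHA = 0.05

#: Islet volume bin edges in um^3; bins are closed-open, last open-ended.
VOLUME_BIN_EDGES_UM3 = (1000.0, 50_000.0, 500_000.0)


def equivalent_sphere_diameter(volume_um3: float) -> tuple[float, int]:
    """Diameter of the sphere with the given volume: d = 2 (3V / 4 pi)^(1/3).

    Returns the exact diameter in um and its integer-rounded value for
    reporting (1000 um^3 ~ 12 um, 500,000 um^3 ~ 98 um).
    """
    volume_um3 = float(volume_um3)
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    d = 2.0 * (3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return d, int(round(d))


def volume_distribution(
    volumes_um3, bin_edges=VOLUME_BIN_EDGES_UM3
) -> tuple[np.ndarray, float]:
    """Percentage of islets per volume bin, plus the median volume."""
    v = np.asarray(volumes_um3, dtype=float)
    if v.size == 0:
        raise ValueError("no volumes given")
    edges = np.concatenate([[0.0], np.asarray(bin_edges, dtype=float), [np.inf]])
    counts, _ = np.histogram(v, bins=edges)
    return 100.0 * counts / v.size, float(np.median(v))


def median_confidence_interval(
    values, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Median with an exact binomial order-statistic confidence interval.

    Uses the smallest symmetric pair of order statistics whose binomial
    coverage reaches the requested level; degenerates to the data range
    for very small n.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("no values")
    med = float(np.median(v))
    if n == 1:
        return med, v[0], v[0]
    # P(order stat k..n-k+1 brackets the median) = 1 - 2 P(X < k), X~Bin(n,1/2)
    k = 0
    for j in range(1, n // 2 + 1):
        cov = 1.0 - 2.0 * sps.binom.cdf(j - 1, n, 0.5)
        if cov >= confidence:
            k = j
    if k == 0:
        return med, v[0], v[-1]
    return med, float(v[k - 1]), float(v[n - k])


def innervated_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Compare innervated vs non-innervated islets, overall and per region.

    Per region: mean and median volume of each class, the ratio of mean
    volumes (NaN when a class is absent) and the innervated share of the
    summed islet volume in percent.
    """
    if len(records) == 0:
        raise ValueError("no islet records")
    from .grid import REGION_NAMES

    rows = []
    for code, name in enumerate(REGION_NAMES):
        sub = records if code == 0 else records[records["region"] == code]
        if len(sub) == 0:
            continue
        inn = sub.loc[sub["innervated"], "volume_um3"].to_numpy()
        non = sub.loc[~sub["innervated"], "volume_um3"].to_numpy()
        total = sub["volume_um3"].sum()
        row = {
            "region": name,
            "n_innervated": inn.size,
            "n_noninnervated": non.size,
            "mean_innervated_um3": inn.mean() if inn.size else np.nan,
            "mean_noninnervated_um3": non.mean() if non.size else np.nan,
            "median_innervated_um3": np.median(inn) if inn.size else np.nan,
            "median_noninnervated_um3": np.median(non) if non.size else np.nan,
            "innervated_share_percent": 100.0 * inn.sum() / total if total else np.nan,
        }
        if inn.size and non.size and non.mean() > 0:
            row["mean_volume_ratio"] = inn.mean() / non.mean()
        else:
            row["mean_volume_ratio"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def region_summary(
    islet_records: pd.DataFrame,
    nerve_mask: np.ndarray,
    islet_mask: np.ndarray,
    tissue_mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    region_mask: np.ndarray | None = None,
    insulin_reference: float | None = None,
    bin_edges=VOLUME_BIN_EDGES_UM3,
) -> pd.DataFrame:
    """The headline per-region summary of one sample.

    Covers: beta cell volume percent, islets per mm^3, median/mean islet
    volume, normalized insulin intensity, endocrine nerve volume per
    islet, endocrine and exocrine nerve density percent, volume-bin
    percentages, innervated-islet summary and NF200 intensity per islet
    volume. Endocrine + exocrine nerve volume equals the total nerve
    volume by construction (asserted).

    ``insulin_reference`` is the normalization denominator for insulin
    intensity (defaults to this sample's whole-tissue mean, i.e. the
    "normalized to whole pancreas" convention; pass a control-group mean
    for cross-group figures).
    """
    from .grid import REGION_NAMES

    nerve_mask = np.asarray(nerve_mask, dtype=bool)
    islet_mask = np.asarray(islet_mask, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    voxvol = float(np.prod(voxel_size_um))

    endo_total = np.count_nonzero(nerve_mask & islet_mask)
    exo_total = np.count_nonzero(nerve_mask & ~islet_mask & tissue_mask)
    outside = np.count_nonzero(nerve_mask & ~tissue_mask)
    assert endo_total + exo_total + outside == np.count_nonzero(nerve_mask)

    rows = []
    for code, name in enumerate(REGION_NAMES):
        if code == 0:
            rsel = tissue_mask
            sub = islet_records
        else:
            if region_mask is None:
                continue
            rsel = region_mask == code
            sub = islet_records[islet_records["region"] == code]
        tissue_vox = int(np.count_nonzero(rsel))
        if tissue_vox == 0:
            continue
        tissue_um3 = tissue_vox * voxvol
        islet_vox = int(np.count_nonzero(islet_mask & rsel))
        endo_vox = int(np.count_nonzero(nerve_mask & islet_mask & rsel))
        exo_vox = int(np.count_nonzero(nerve_mask & ~islet_mask & rsel))
        n_islets = len(sub)
        vols = sub["volume_um3"].to_numpy() if n_islets else np.zeros(0)
        row = {
            "region": name,
            "n_islets": n_islets,
            "tissue_volume_mm3": tissue_um3 / 1e9,
            "beta_volume_percent": 100.0 * islet_vox / tissue_vox,
            "islets_per_mm3": n_islets / (tissue_um3 / 1e9),
            "median_islet_volume_um3": float(np.median(vols)) if n_islets else np.nan,
            "mean_islet_volume_um3": float(vols.mean()) if n_islets else np.nan,
            "endocrine_nerve_volume_um3": endo_vox * voxvol,
            "exocrine_nerve_volume_um3": exo_vox * voxvol,
            "endocrine_nerve_volume_per_islet_um3": (
                endo_vox * voxvol / n_islets if n_islets else np.nan
            ),
            "endocrine_nerve_density_percent": (
                100.0 * endo_vox / islet_vox if islet_vox else np.nan
            ),
            "exocrine_nerve_density_percent": (
                100.0 * exo_vox / (tissue_vox - islet_vox)
                if tissue_vox > islet_vox
                else np.nan
            ),
        }
        if n_islets:
            bins, _ = volume_distribution(vols, bin_edges)
        else:
            bins = np.full(len(bin_edges) + 1, np.nan)
        for i, b in enumerate(bins):
            row[f"volume_bin{i}_percent"] = b
        # insulin intensity normalization
        if n_islets and "intensity_mean_insulin" in sub:
            mean_int = float(sub["intensity_mean_insulin"].mean())
            ref = insulin_reference if insulin_reference else mean_int
            row["normalized_insulin_intensity"] = mean_int / ref if ref else np.nan
        else:
            row["normalized_insulin_intensity"] = np.nan
        if n_islets and "innervated" in sub:
            comp = innervated_comparison(sub.assign(region=0))
            row["innervated_fraction_percent"] = (
                100.0 * sub["innervated"].sum() / n_islets
            )
            row["innervated_share_percent"] = comp.loc[0, "innervated_share_percent"]
            row["mean_volume_ratio_innervated"] = comp.loc[0, "mean_volume_ratio"]
        if n_islets and "intensity_sum_nf200" in sub:
            with np.errstate(invalid="ignore", divide="ignore"):
                row["nf200_intensity_per_islet_volume"] = float(
                    (sub["intensity_sum_nf200"] / sub["volume_um3"]).mean()
                )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupStatsResult:
    """Outcome of one normality-gated group comparison."""

    metric: str
    groups: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sem: dict[str, float]
    median: dict[str, float]
    median_ci: dict[str, tuple[float, float]]
    shapiro_p: dict[str, float]
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = {
            "metric": self.metric,
            "groups": self.groups,
            "n": self.n,
            "mean": self.mean,
            "sem": self.sem,
            "median": self.median,
            "median_ci": {k: list(v) for k, v in self.median_ci.items()},
            "shapiro_p": self.shapiro_p,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def dunn_test(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's multiple-comparisons test after Kruskal-Wallis.

    Pairwise z statistics on mean ranks with tie correction; two-sided
    p values with Bonferroni adjustment over the family (the convention
    of common prism-style analysis suites).
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = len(samples[g])
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_value": p,
                     "significant": p < ALPHA})
    return pd.DataFrame(rows)


def group_compare(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    groups: list[str] | None = None,
    force_nonparametric: bool = False,
) -> GroupStatsResult:
    """Normality-gated comparison of one metric across groups.

    Requires >=2 groups with n>=3 each (Shapiro-Wilk needs 3). The gate:
    all groups normal at alpha 0.05 -> t test / ANOVA+Tukey; any group
    non-normal (or ``force_nonparametric``) -> Mann-Whitney (exact for
    small untied samples) / Kruskal-Wallis+Dunn.
    """
    if groups is None:
        groups = list(pd.unique(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = {
        g: table.loc[table[group_col] == g, metric].dropna().to_numpy(dtype=float)
        for g in groups
    }
    for g, v in samples.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has n={v.size} < 3")

    shapiro_p = {}
    for g, v in samples.items():
        if np.ptp(v) == 0:
            shapiro_p[g] = 0.0  # degenerate: constant sample, not Gaussian
        else:
            shapiro_p[g] = float(sps.shapiro(v).pvalue)
    all_normal = all(p >= ALPHA for p in shapiro_p.values()) and not force_nonparametric

    pairwise = None
    vals = [samples[g] for g in groups]
    if len(groups) == 2:
        a, b = vals
        if all_normal:
            test = "t"
            res = sps.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
            if np.isnan(stat):  # identical constant samples
                stat, p = 0.0, 1.0
        else:
            test = "MannWhitney"
            method = "exact" if (len(a) + len(b) <= 25) else "auto"
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        if all_normal:
            test = "ANOVA+Tukey"
            res = sps.f_oneway(*vals)
            stat, p = float(res.statistic), float(res.pvalue)
            tk = sps.tukey_hsd(*vals)
            rows = []
            for i, j in itertools.combinations(range(len(groups)), 2):
                rows.append({
                    "group_a": groups[i], "group_b": groups[j],
                    "statistic": float(tk.statistic[i, j]),
                    "p_value": float(tk.pvalue[i, j]),
                    "significant": float(tk.pvalue[i, j]) < ALPHA,
                })
            pairwise = pd.DataFrame(rows)
        else:
            test = "KruskalWallis+Dunn"
            res = sps.kruskal(*vals)
            stat, p = float(res.statistic), float(res.pvalue)
            pairwise = dunn_test(samples)

    med_ci = {g: median_confidence_interval(v)[1:] for g, v in samples.items()}
    return GroupStatsResult(
        metric=metric,
        groups=list(groups),
        n={g: int(v.size) for g, v in samples.items()},
        mean={g: float(v.mean()) for g, v in samples.items()},
        sem={g: float(sps.sem(v)) if v.size > 1 else np.nan
             for g, v in samples.items()},
        median={g: float(np.median(v)) for g, v in samples.items()},
        median_ci=med_ci,
        shapiro_p=shapiro_p,
        test=test,
        statistic=stat,
        p_value=p,
        pairwise=pairwise,
    )


def correlate(x, y) -> dict:
    """Normality-gated correlation: Pearson when both variables pass
    Shapiro-Wilk at alpha 0.05, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("mismatched lengths")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    px = float(sps.shapiro(x).pvalue)
    py = float(sps.shapiro(y).pvalue)
    if px >= ALPHA and py >= ALPHA:
        res = sps.pearsonr(x, y)
        method = "pearson"
    else:
        res = sps.spearmanr(x, y)
        method = "spearman"
    r, p = float(res.statistic), float(res.pvalue)
    return {
        "method": method,
        "r": r,
        "p_value": p,
        "n": int(x.size),
        "significant": p < ALPHA,
        "sign": int(np.sign(r)),
        "shapiro_p_x": px,
        "shapiro_p_y": py,
    }
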