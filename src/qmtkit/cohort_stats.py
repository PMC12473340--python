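"""ROI extraction and the cohort-comparison statistics.

The analysis convention is ROI-first: signals are averaged over each
muscle ROI and every index is computed once per ROI ("roi_signal_mean");
a voxelwise-map-then-average mode ("map_mean") is also available.  Group
comparisons follow a normality-gated branch: normally distributed data
(T1) goes to a two-way age-by-region ANOVA, everything else to
Mann-Whitney / Kruskal-Wallis tests with Bonferroni-adjusted post hocs,
Hodges-Lehmann shift estimates with exact rank-based confidence intervals,
and rank-biserial standardized effect sizes.  All tests are two-sided at
alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RegionComparison",
    "AnovaReport",
    "MissingROIError",
    "roi_means",
    "extract_roi_values",
    "normality_gate",
    "hodges_lehmann",
    "rank_biserial",
    "compare_age_groups",
    "compare_regions",
    "anova_t1",
    "correlate_with_t1",
]

ALPHA = 0.05

#: Rank-biserial magnitude thresholds: |r| < 0.3 small, <= 0.5 medium, else large.
MAGNITUDE_THRESHOLDS = (0.3, 0.5)


class MissingROIError(ValueError):
    """A requested label is absent from the label volume."""


@dataclass(frozen=True)
class GroupComparison:
    """Two-group (young vs senior) comparison of one index."""

    index_name: str
    p_two_sided: float
    hl_estimate: float
    ci_low: float
    ci_high: float
    rank_biserial_r: float
    magnitude: str
    direction: str
    n_young: int
    n_senior: int


@dataclass
class RegionComparison:
    """Kruskal-Wallis across muscles plus Bonferroni-adjusted post hocs."""

    index_name: str
    kw_statistic: float
    kw_p: float
    posthoc: pd.DataFrame  # muscle_a, muscle_b, u, p_raw, p_adj


@dataclass
class AnovaReport:
    """Two-way (age x region) ANOVA of T1 with Levene diagnostic."""

    table: pd.DataFrame
    p_age: float
    p_region: float
    p_interaction: float
    levene_p: float
    posthoc: pd.DataFrame


def roi_means(volume: np.ndarray, labels: np.ndarray, label_ids=None) -> dict:
    """Mean of a 3D map (or per-volume means of a 4D stack) over each label."""
    volume = np.asarray(volume, dtype=float)
    labels = np.asarray(labels)
    if volume.shape[: labels.ndim] != labels.shape:
        raise ValueError("geometry mismatch between labels and volume")
    if label_ids is None:
        label_ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    out = {}
    missing = []
    for lab in label_ids:
        m = labels == lab
        if not m.any():
            missing.append(lab)
            continue
        out[lab] = volume[m].mean(axis=0)
    if missing:
        raise MissingROIError(f"labels absent from the label volume: {missing}")
    return out


def extract_roi_values(
    data: np.ndarray,
    labels: np.ndarray,
    mode: str = "roi_signal_mean",
    index_fn=None,
    label_ids=None,
) -> dict:
    """Per-ROI index values.

    * ``roi_signal_mean`` (default): signals of a 4D stack are averaged over
      the ROI first, then ``index_fn(mean_signal_vector)`` is evaluated once
      per ROI (returns the vectors themselves if ``index_fn`` is None).
    * ``map_mean``: ``data`` is a precomputed 3D index map, averaged per ROI.
    """
    if mode == "map_mean":
        if np.asarray(data).ndim != 3:
            raise ValueError("map_mean mode expects a 3D index map")
        return roi_means(data, labels, label_ids)
    if mode == "roi_signal_mean":
        if np.asarray(data).ndim != 4:
            raise ValueError("roi_signal_mean mode expects a 4D signal stack")
        vectors = roi_means(data, labels, label_ids)
        if index_fn is None:
            return vectors
        return {lab: index_fn(vec) for lab, vec in vectors.items()}
    raise ValueError(f"unknown extraction mode {mode!r}")


def normality_gate(values) -> str:
    """Shapiro-Wilk branch decision: 'normal' (p >= 0.05) or 'non_normal'."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("normality testing needs at least 3 values")
    if np.ptp(values) == 0:
        return "non_normal"  # degenerate: a constant is not usably Gaussian
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.shapiro(values).pvalue
    return "normal" if p >= ALPHA else "non_normal"


def hodges_lehmann(x, y) -> float:
    """Median of all pairwise differences x_i - y_j (two-sample HL estimator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.median(x[:, None] - y[None, :]))


def rank_biserial(x, y) -> float:
    """Rank-biserial correlation r = 1 - 2 U_y / (n_x n_y).

    Positive when x tends to exceed y; +1 at complete separation
    (every x above every y), -1 at the reverse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u_x = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    n = x.size * y.size
    u_y = n - u_x
    return float(1.0 - 2.0 * u_y / n)


def _u_null_cdf(m: int, n: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic for sizes (m, n).

    Counts N(m, n, u) via the recurrence
    N(m, n, u) = N(m-1, n, u-n) + N(m, n-1, u).
    """
    max_u = m * n
    # table[i][j] = counts array over u for sizes (i, j)
    prev = [np.array([1.0]) for _ in range(n + 1)]  # i = 0
    for i in range(1, m + 1):
        cur = [np.array([1.0])]  # j = 0
        for j in range(1, n + 1):
            size = i * j + 1
            a = np.zeros(size)
            sub = prev[j]  # N(i-1, j, u - j)
            a[j : j + sub.size] += sub
            subb = cur[j - 1]  # N(i, j-1, u)
            a[: subb.size] += subb
            cur.append(a)
        prev = cur
    counts = prev[n]
    assert counts.size == max_u + 1
    return np.cumsum(counts) / counts.sum()


def _hl_confidence_interval(x, y, alpha: float = ALPHA) -> tuple[float, float]:
    """Rank-based CI for the location shift (exact null for small samples).

    For m*n <= 400 the exact Mann-Whitney null distribution picks the
    order statistics of the pairwise differences; above that a normal
    approximation to U is used.  Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    mn = m * n
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    if mn <= 400:
        cdf = _u_null_cdf(m, n)
        below = np.nonzero(cdf <= alpha / 2.0)[0]
        w = int(below[-1]) if below.size else -1
    else:
        z = sps.norm.ppf(alpha / 2.0)
        w = int(np.floor(mn / 2.0 + z * np.sqrt(mn * (m + n + 1) / 12.0)))
        w = max(w, -1)
    k = w + 1
    if k < 1:
        return float(diffs[0]), float(diffs[-1])
    return float(diffs[k - 1]), float(diffs[mn - k])


def _magnitude(r: float) -> str:
    a = abs(r)
    if a < MAGNITUDE_THRESHOLDS[0]:
        return "small"
    if a <= MAGNITUDE_THRESHOLDS[1]:
        return "medium"
    return "large"


def _index_values(table: pd.DataFrame, index_name: str) -> pd.DataFrame:
    sub = table[table["index"] == index_name]
    if sub.empty:
        raise ValueError(f"no rows for index {index_name!r}")
    return sub


def compare_age_groups(table: pd.DataFrame, index_name: str) -> GroupComparison:
    """Young-vs-senior Mann-Whitney comparison of one index.

    Per-muscle ROI values are pooled across all five muscles within each
    group.  Reports the two-sided p, the Hodges-Lehmann young-senior shift
    with its 95% CI, and the rank-biserial effect size with its
    qualitative magnitude.
    """
    sub = _index_values(table, index_name)
    young = sub.loc[sub["group"] == "young", "value"].to_numpy(float)
    senior = sub.loc[sub["group"] == "senior", "value"].to_numpy(float)
    if young.size < 2 or senior.size < 2:
        raise ValueError("both groups need at least 2 values")
    res = sps.mannwhitneyu(young, senior, alternative="two-sided")
    hl = hodges_lehmann(young, senior)
    lo, hi = _hl_confidence_interval(young, senior)
    r = rank_biserial(young, senior)
    if hl > 0:
        direction = "Y > O"
    elif hl < 0:
        direction = "O > Y"
    else:
        direction = "none"
    return GroupComparison(
        index_name=index_name,
        p_two_sided=float(res.pvalue),
        hl_estimate=hl,
        ci_low=lo,
        ci_high=hi,
        rank_biserial_r=r,
        magnitude=_magnitude(r),
        direction=direction,
        n_young=int(young.size),
        n_senior=int(senior.size),
    )


def compare_regions(table: pd.DataFrame, index_name: str) -> RegionComparison:
    """Kruskal-Wallis across muscles (groups pooled) with Bonferroni post hocs.

    Pairwise Mann-Whitney tests run only when the omnibus test is
    significant; the Bonferroni factor equals the number of muscle pairs.
    """
    sub = _index_values(table, index_name)
    muscles = sorted(sub["muscle"].unique())
    if len(muscles) < 2:
        raise ValueError("region comparison needs at least 2 muscles")
    groups = [sub.loc[sub["muscle"] == m, "value"].to_numpy(float) for m in muscles]
    kw = sps.kruskal(*groups)
    cols = ["muscle_a", "muscle_b", "u", "p_raw", "p_adj"]
    rows = []
    if kw.pvalue < ALPHA:
        pairs = [(i, j) for i in range(len(muscles)) for j in range(i + 1, len(muscles))]
        bonf = len(pairs)
        for i, j in pairs:
            res = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            rows.append(
                {
                    "muscle_a": muscles[i],
                    "muscle_b": muscles[j],
                    "u": float(res.statistic),
                    "p_raw": float(res.pvalue),
                    "p_adj": min(1.0, float(res.pvalue) * bonf),
                }
            )
    posthoc = pd.DataFrame(rows, columns=cols)
    return RegionComparison(
        index_name=index_name,
        kw_statistic=float(kw.statistic),
        kw_p=float(kw.pvalue),
        posthoc=posthoc,
    )


def anova_t1(table: pd.DataFrame, index_name: str = "T1") -> AnovaReport:
    """Two-way factorial (age x region) ANOVA of T1.

    Type-II sums of squares; Levene's test across the age-by-muscle cells
    is attached as a homogeneity diagnostic.  Bonferroni-adjusted pairwise
    t-tests across muscles are run only on a significant region effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = _index_values(table, index_name).copy()
    cells = sub.groupby(["group", "muscle"])["value"].count()
    n_groups = sub["group"].nunique()
    n_muscles = sub["muscle"].nunique()
    if len(cells) < n_groups * n_muscles:
        raise ValueError("empty cells in the age x region design")
    if (cells < 2).any():
        raise ValueError("each age x region cell needs at least 2 values")
    model = smf.ols("value ~ C(group) * C(muscle)", data=sub).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    p_age = float(tab.loc["C(group)", "PR(>F)"])
    p_region = float(tab.loc["C(muscle)", "PR(>F)"])
    p_inter = float(tab.loc["C(group):C(muscle)", "PR(>F)"])
    cell_values = [g["value"].to_numpy(float) for _, g in sub.groupby(["group", "muscle"])]
    levene_p = float(sps.levene(*cell_values).pvalue)

    cols = ["muscle_a", "muscle_b", "t", "p_raw", "p_adj"]
    rows = []
    if p_region < ALPHA:
        muscles = sorted(sub["muscle"].unique())
        pairs = [(i, j) for i in range(len(muscles)) for j in range(i + 1, len(muscles))]
        for i, j in pairs:
            a = sub.loc[sub["muscle"] == muscles[i], "value"]
            b = sub.loc[sub["muscle"] == muscles[j], "value"]
            res = sps.ttest_ind(a, b)
            rows.append(
                {
                    "muscle_a": muscles[i],
                    "muscle_b": muscles[j],
                    "t": float(res.statistic),
                    "p_raw": float(res.pvalue),
                    "p_adj": min(1.0, float(res.pvalue) * len(pairs)),
                }
            )
    return AnovaReport(
        table=tab,
        p_age=p_age,
        p_region=p_region,
        p_interaction=p_inter,
        levene_p=levene_p,
        posthoc=pd.DataFrame(rows, columns=cols),
    )


def correlate_with_t1(
    table: pd.DataFrame, index_name: str, t1_name: str = "T1"
) -> tuple[float, float, float, float]:
    """Pearson correlation of an MT index against T1 over pooled ROI points.

    Pairs values by (subject, muscle) and returns
    (pearson_r, p_two_sided, slope, intercept) of the index-on-T1 line.
    """
    idx = _index_values(table, index_name)[["subject", "muscle", "value"]]
    t1 = _index_values(table, t1_name)[["subject", "muscle", "value"]]
    merged = idx.merge(t1, on=["subject", "muscle"], suffixes=("_idx", "_t1"))
    if len(merged) < 3:
        raise ValueError("need at least 3 paired (index, T1) points")
    x = merged["value_t1"].to_numpy(float)
    y = merged["value_idx"].to_numpy(float)
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return float(r), float(p), float(slope), float(intercept)
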