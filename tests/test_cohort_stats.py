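"""ROI extraction and the cohort-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qmtkit.cohort_stats import (
    MissingROIError,
    anova_t1,
    compare_age_groups,
    compare_regions,
    correlate_with_t1,
    extract_roi_values,
    hodges_lehmann,
    normality_gate,
    rank_biserial,
    roi_means,
)

MUSCLES = ["SOL", "MG", "LG", "TA", "TP"]


def _table(young, senior, index="f_so", rng=None):
    """Long cohort table from per-group value arrays (pooled over muscles)."""
    rows = []
    for g, vals in (("young", young), ("senior", senior)):
        for i, v in enumerate(np.atleast_1d(vals)):
            rows.append(
                {
                    "subject": f"{g[0]}{i // len(MUSCLES)}",
                    "group": g,
                    "muscle": MUSCLES[i % len(MUSCLES)],
                    "index": index,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestRoiExtraction:
    def test_map_mean_and_missing_label(self):
        labels = np.zeros((4, 4, 2), dtype=int)
        labels[:2] = 1
        vol = np.ones((4, 4, 2)) * 3.0
        assert roi_means(vol, labels)[1] == pytest.approx(3.0)
        with pytest.raises(MissingROIError):
            roi_means(vol, labels, label_ids=[1, 2])

    def test_modes_agree_on_homogeneous_roi(self, rng):
        """ROI-mean-then-index equals index-then-ROI-mean on uniform tissue."""
        labels = np.zeros((8, 8, 2), dtype=int)
        labels[2:6, 2:6] = 1
        stack = np.zeros((8, 8, 2, 2))
        stack[..., 0] = 50.0 + rng.normal(0, 0.25, (8, 8, 2))  # SNR 200
        stack[..., 1] = 100.0 + rng.normal(0, 0.5, (8, 8, 2))

        def mtr(v):
            return 1.0 - v[0] / v[1]

        roi_first = extract_roi_values(stack, labels, "roi_signal_mean", mtr)[1]
        mtr_map = 1.0 - stack[..., 0] / stack[..., 1]
        map_mean = extract_roi_values(mtr_map, labels, "map_mean")[1]
        assert roi_first == pytest.approx(map_mean, rel=0.005)

    def test_single_voxel_roi_identical(self):
        labels = np.zeros((3, 3, 1), dtype=int)
        labels[1, 1, 0] = 1
        stack = np.arange(18, dtype=float).reshape(3, 3, 1, 2) + 1.0

        def ratio(v):
            return v[0] / v[1]

        a = extract_roi_values(stack, labels, "roi_signal_mean", ratio)[1]
        b = extract_roi_values(stack[..., 0] / stack[..., 1], labels, "map_mean")[1]
        assert a == pytest.approx(b, rel=1e-12)

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError):
            roi_means(np.ones((4, 4, 2)), np.ones((5, 5, 2), dtype=int))


class TestNormalityGate:
    def test_gaussian_sample_passes(self, rng):
        assert normality_gate(rng.normal(0, 1, 500)) == "normal"

    def test_exponential_sample_rejected(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            if normality_gate(r.exponential(1.0, 100)) == "non_normal":
                hits += 1
        assert hits >= 49

    def test_constant_vector_does_not_crash(self):
        assert normality_gate(np.full(20, 1.3)) == "non_normal"

    def test_too_few(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestHodgesLehmann:
    def test_worked_example(self):
        # pairwise young-senior differences {1,0,2,1,3,2} -> median 1.5
        assert hodges_lehmann([1, 2, 3], [0, 1]) == pytest.approx(1.5)

    def test_brute_force_oracle(self, rng):
        """HL equals the brute-force pairwise-difference median on random data."""
        for _ in range(100):
            m, n = rng.integers(2, 25, 2)
            x, y = rng.normal(0, 1, m), rng.normal(0.3, 1.2, n)
            brute = np.median([xi - yj for xi in x for yj in y])
            assert hodges_lehmann(x, y) == pytest.approx(brute, rel=1e-12, abs=1e-12)

    def test_label_swap_negates(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.2, 1, 9)
        assert hodges_lehmann(x, y) == pytest.approx(-hodges_lehmann(y, x), rel=1e-12)


class TestRankBiserial:
    def test_identity_with_u(self, rng):
        """r = 1 - 2U/(n1 n2) identically, U the senior-win count."""
        for _ in range(50):
            x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 8)
            u_x = sps.mannwhitneyu(x, y).statistic
            u_y = 12 * 8 - u_x
            assert rank_biserial(x, y) == pytest.approx(1 - 2 * u_y / 96, rel=1e-12)

    def test_complete_separation(self):
        assert rank_biserial([4, 5, 6], [1, 2, 3]) == pytest.approx(1.0)
        assert rank_biserial([1, 2, 3], [4, 5, 6]) == pytest.approx(-1.0)

    def test_label_swap_negates(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        assert rank_biserial(x, y) == pytest.approx(-rank_biserial(y, x), rel=1e-12)


class TestCompareAgeGroups:
    def test_identical_groups(self, rng):
        vals = rng.normal(0, 1, 75)
        res = compare_age_groups(_table(vals, vals), "f_so")
        assert res.hl_estimate == pytest.approx(0.0, abs=1e-12)
        assert res.rank_biserial_r == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided > 0.9

    def test_ci_brackets_estimate_and_magnitude_labels(self, rng):
        young = rng.normal(0.075, 0.004, 75)
        senior = rng.normal(0.069, 0.004, 45)
        res = compare_age_groups(_table(young, senior), "f_so")
        assert res.ci_low <= res.hl_estimate <= res.ci_high
        assert res.direction == "Y > O"
        assert res.magnitude in {"small", "medium", "large"}

    def test_magnitude_thresholds(self):
        from qmtkit.cohort_stats import _magnitude

        assert _magnitude(0.16) == "small"
        assert _magnitude(0.38) == "medium"
        assert _magnitude(0.49) == "medium"
        assert _magnitude(0.6) == "large"

    def test_exact_ci_coverage(self, rng):
        """The exact rank-based 95% CI covers the true shift ~95% of the time."""
        cover = 0
        n_rep = 300
        for _ in range(n_rep):
            young = rng.normal(0.5, 1.0, 15)
            senior = rng.normal(0.0, 1.0, 9)
            res = compare_age_groups(_table(young, senior), "f_so")
            cover += res.ci_low <= 0.5 <= res.ci_high
        assert cover / n_rep == pytest.approx(0.95, abs=0.04)


class TestCompareRegions:
    def test_null_no_posthoc_usually(self, rng):
        vals = rng.normal(0, 1, 120)
        res = compare_regions(_table(vals[:75], vals[75:]), "f_so")
        assert res.kw_p > 0.0
        if res.kw_p >= 0.05:
            assert res.posthoc.empty

    def test_shifted_muscle_detected(self, rng):
        """A muscle shifted by 3 IQRs survives the Bonferroni post hocs."""
        df = _table(rng.normal(0, 1, 75), rng.normal(0, 1, 45), "f_so")
        iqr = np.subtract(*np.percentile(df["value"], [75, 25]))
        df.loc[df["muscle"] == "TA", "value"] += 3 * iqr
        res = compare_regions(df, "f_so")
        assert res.kw_p < 0.05
        ta_rows = res.posthoc[
            (res.posthoc["muscle_a"] == "TA") | (res.posthoc["muscle_b"] == "TA")
        ]
        assert (ta_rows["p_adj"] < 0.05).all()
        # Bonferroni factor is the number of pairs (10 for five muscles)
        assert len(res.posthoc) == 10

    def test_two_muscles_single_pair(self, rng):
        df = _table(rng.normal(0, 1, 75), rng.normal(3, 1, 45), "f_so")
        df = df[df["muscle"].isin(["TA", "TP"])].copy()
        df.loc[df["muscle"] == "TA", "value"] += 10.0
        res = compare_regions(df, "f_so")
        assert len(res.posthoc) == 1
        assert res.posthoc["p_adj"].iloc[0] == pytest.approx(res.posthoc["p_raw"].iloc[0])

    def test_single_muscle_error(self, rng):
        df = _table(rng.normal(0, 1, 75), rng.normal(0, 1, 45), "f_so")
        with pytest.raises(ValueError):
            compare_regions(df[df["muscle"] == "TA"], "f_so")


class TestAnovaT1:
    def _t1_table(self, rng, age_shift=0.07, region_shift=0.0):
        rows = []
        for g, n, shift in (("young", 15, 0.0), ("senior", 9, age_shift)):
            for s in range(n):
                subj_eff = rng.normal(0, 0.03)
                for k, m in enumerate(MUSCLES):
                    rows.append(
                        {
                            "subject": f"{g[0]}{s}",
                            "group": g,
                            "muscle": m,
                            "index": "T1",
                            "value": 1.40
                            + shift
                            + subj_eff
                            + region_shift * k
                            + rng.normal(0, 0.02),
                        }
                    )
        return pd.DataFrame(rows)

    def test_age_effect_detected_no_region_effect(self, rng):
        hits_age, false_region = 0, 0
        n_rep = 20
        for _ in range(n_rep):
            rep = anova_t1(self._t1_table(rng))
            hits_age += rep.p_age < 0.05
            false_region += rep.p_region < 0.05
        assert hits_age >= 0.9 * n_rep
        assert false_region <= 0.25 * n_rep

    def test_region_effect_triggers_posthoc(self, rng):
        rep = anova_t1(self._t1_table(rng, age_shift=0.0, region_shift=0.05))
        assert rep.p_region < 0.05
        assert len(rep.posthoc) == 10

    def test_levene_attached(self, rng):
        rep = anova_t1(self._t1_table(rng))
        assert 0.0 <= rep.levene_p <= 1.0

    def test_single_subject_cell_error(self, rng):
        df = self._t1_table(rng)
        df = df[(df["group"] == "senior") | (df["subject"] == "y0")]
        with pytest.raises(ValueError):
            anova_t1(df)


class TestCorrelation:
    def test_exact_linear(self):
        t1 = np.linspace(1.3, 1.6, 30)
        idx = 0.2 - 0.1 * t1
        df = pd.concat(
            [
                _table(t1[:20], t1[20:], "T1"),
                _table(idx[:20], idx[20:], "MT_sat"),
            ]
        )
        r, p, slope, intercept = correlate_with_t1(df, "MT_sat")
        assert r == pytest.approx(-1.0, abs=1e-9)
        assert slope == pytest.approx(-0.1, rel=1e-9)
        assert intercept == pytest.approx(0.2, rel=1e-6)

    def test_independent_data_weak(self, rng):
        ps = []
        for _ in range(50):
            t1 = rng.normal(1.4, 0.05, 40)
            idx = rng.normal(3.0, 0.3, 40)
            df = pd.concat([_table(t1[:25], t1[25:], "T1"), _table(idx[:25], idx[25:], "f_so")])
            ps.append(correlate_with_t1(df, "f_so")[1])
        # null p-values roughly uniform: about half above 0.5
        assert 0.3 < np.mean(np.array(ps) > 0.5) < 0.7

    def test_too_few_pairs(self):
        df = pd.concat([_table([1.4], [1.5], "T1"), _table([3.0], [2.9], "f_so")])
        with pytest.raises(ValueError):
            correlate_with_t1(df, "f_so")


def test_mann_whitney_type_i_error_at_study_n(rng):
    """Null rejection rate ~5% at the study's 15/9 group sizes."""
    n_rep = 2000
    hits = 0
    for _ in range(n_rep):
        x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 9)
        hits += sps.mannwhitneyu(x, y, alternative="two-sided").pvalue < 0.05
    assert hits / n_rep == pytest.approx(0.05, abs=0.015)
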