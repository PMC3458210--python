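"""ICC, Bland-Altman, subgroup filter and sample-size planning.

The two-way mixed ICC implementation is checked against an independent
brute-force ANOVA oracle (explicit Python-loop summation of squares) and
cross-checked against pingouin's intraclass_corr.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mibgplanar import (
    ObserverMeasurementTable,
    bland_altman,
    classify_icc,
    filter_low_delayed_hm,
    icc_two_way_mixed,
    required_sample_size,
)


# ---------------------------------------------------------------------------
# independent oracle: explicit summation of squares, loops only
# ---------------------------------------------------------------------------

def icc_oracle(x, measures, definition):
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if definition == "consistency":
        if measures == "single":
            return (msr - mse) / (msr + (k - 1) * mse)
        return (msr - mse) / msr
    if measures == "single":
        return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICCEstimates:
    def test_perfect_agreement_table(self):
        t = ObserverMeasurementTable([[1, 1], [2, 2], [3, 3]])
        assert icc_two_way_mixed(t, "single", "consistency").icc == 1.0
        assert icc_two_way_mixed(t, "single", "absolute").icc == 1.0

    def test_constant_rater_offset_perfect_consistency_imperfect_absolute(self):
        t = ObserverMeasurementTable([[1, 2], [2, 3], [3, 4]])
        assert icc_two_way_mixed(t, "single", "consistency").icc == 1.0
        assert icc_two_way_mixed(t, "single", "absolute").icc < 1.0

    def test_fixture_table_matches_summation_oracle(self):
        x = np.array(
            [
                [1.52, 1.58],
                [1.21, 1.19],
                [1.88, 1.79],
                [1.40, 1.45],
                [1.66, 1.71],
                [1.33, 1.28],
            ]
        )
        t = ObserverMeasurementTable(x)
        for measures in ("single", "average"):
            for definition in ("consistency", "absolute"):
                mine = icc_two_way_mixed(t, measures, definition).icc
                assert mine == pytest.approx(icc_oracle(x, measures, definition), abs=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_random_tables_match_oracle_to_1e10(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(3, 21)), int(rng.integers(2, 5))
        x = rng.normal(size=(n, k)) + 2 * rng.normal(size=(n, 1)) + 0.5 * rng.normal(size=(1, k))
        t = ObserverMeasurementTable(x)
        for measures in ("single", "average"):
            for definition in ("consistency", "absolute"):
                mine = icc_two_way_mixed(t, measures, definition).icc
                assert mine == pytest.approx(icc_oracle(x, measures, definition), abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        x = rng.normal(size=(10, 3)) + 2 * rng.normal(size=(10, 1))
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y").set_index("Type")
        t = ObserverMeasurementTable(x)
        for typ, measures, definition in [
            ("ICC(C,1)", "single", "consistency"),
            ("ICC(C,k)", "average", "consistency"),
            ("ICC(A,1)", "single", "absolute"),
            ("ICC(A,k)", "average", "absolute"),
        ]:
            mine = icc_two_way_mixed(t, measures, definition)
            assert mine.icc == pytest.approx(ref.loc[typ, "ICC"], abs=1e-10)
            lo, hi = ref.loc[typ, "CI95"]
            assert mine.ci_low == pytest.approx(lo, abs=6e-3)  # pingouin prints 2 dp
            assert mine.ci_high == pytest.approx(hi, abs=6e-3)

    def test_consistency_invariant_to_per_rater_offsets(self, rng):
        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        t0 = icc_two_way_mixed(ObserverMeasurementTable(x), "single", "consistency")
        shifted = x + np.array([[0.0, 0.7, -1.3]])
        t1 = icc_two_way_mixed(ObserverMeasurementTable(shifted), "single", "consistency")
        t1_abs = icc_two_way_mixed(ObserverMeasurementTable(shifted), "single", "absolute")
        assert t1.icc == pytest.approx(t0.icc, abs=1e-12)
        assert t1_abs.icc != pytest.approx(t0.icc, abs=1e-6)

    def test_degenerate_tables(self):
        with pytest.warns(UserWarning, match="identical"):
            r = icc_two_way_mixed(ObserverMeasurementTable([[2, 2], [2, 2]]))
        assert r.icc == 1.0
        with pytest.warns(UserWarning, match="between-subject"):
            r = icc_two_way_mixed(ObserverMeasurementTable([[1, 2], [2, 1], [1.5, 1.5]]))
        assert r.icc == 0.0

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=(15, 2)) + 2 * rng.normal(size=(15, 1))
        for measures in ("single", "average"):
            for definition in ("consistency", "absolute"):
                r = icc_two_way_mixed(ObserverMeasurementTable(x), measures, definition)
                assert r.ci_low <= r.icc <= r.ci_high

    def test_table_validation(self):
        with pytest.raises(ValueError, match="2 subjects"):
            ObserverMeasurementTable([[1, 2]])
        with pytest.raises(ValueError, match="missing"):
            ObserverMeasurementTable([[1, 2], [np.nan, 3]])

    def test_parameter_recovery_two_way_model(self):
        """Mean ICC over simulated two-way tables recovers the true reliability."""
        rho = 0.75
        var_s, var_e = 3.0, 1.0
        rng = np.random.default_rng(0)
        est = []
        for _ in range(300):
            s = rng.normal(0, np.sqrt(var_s), size=(70, 1))
            e = rng.normal(0, np.sqrt(var_e), size=(70, 2))
            est.append(icc_two_way_mixed(ObserverMeasurementTable(s + e)).icc)
        est = np.asarray(est)
        sem = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - rho) <= 3 * sem


class TestClassifyICC:
    @pytest.mark.parametrize(
        "icc, expected",
        [
            (0.98, "excellent"),
            (0.75, "excellent"),
            (0.74, "good"),
            (0.60, "good"),
            (0.59, "fair"),
            (0.49, "fair"),
            (0.48, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_bins(self, icc, expected):
        assert classify_icc(icc) == expected

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.01)


class TestBlandAltman:
    def test_identical_vectors_give_zero_limits(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff == 0 and r.loa_low == 0 and r.loa_high == 0

    def test_fixture_vectors_match_direct_arithmetic(self):
        x = np.array([1.50, 1.40, 1.30])
        y = np.array([1.52, 1.38, 1.34])
        d = x - y
        r = bland_altman(x, y)
        assert r.mean_diff == pytest.approx(d.mean())
        assert r.sd_diff == pytest.approx(d.std(ddof=1))
        assert r.mean_diff == pytest.approx(-0.01333, abs=1e-4)
        assert r.loa_low == pytest.approx(-0.0732, abs=2e-4)
        assert r.loa_high == pytest.approx(0.0465, abs=2e-4)

    @settings(max_examples=40, derandomize=True)
    @given(c=st.floats(-10, 10), seed=st.integers(0, 1000))
    def test_translation_shifts_mean_and_limits_not_sd(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r0 = bland_altman(x, y)
        r1 = bland_altman(x + c, y)
        assert r1.sd_diff == pytest.approx(r0.sd_diff)
        assert r1.mean_diff == pytest.approx(r0.mean_diff + c)
        assert r1.loa_low == pytest.approx(r0.loa_low + c)
        assert r1.loa_high == pytest.approx(r0.loa_high + c)

    def test_limits_cover_about_95pct_of_normal_differences(self, rng):
        x = rng.normal(10, 1, size=4000)
        y = x + rng.normal(0, 0.3, size=4000)
        r = bland_altman(x, y)
        frac = np.mean((r.differences >= r.loa_low) & (r.differences <= r.loa_high))
        assert 0.93 < frac < 0.97

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestSubgroupFilter:
    def test_boundary_value_included(self):
        df = pd.DataFrame({"subject": [0, 1], "hm_delayed_ref": [1.40, 1.41]})
        kept = filter_low_delayed_hm(df)
        assert kept.subject.tolist() == [0]

    def test_all_above_threshold_gives_empty_subgroup(self):
        df = pd.DataFrame({"subject": [0, 1], "hm_delayed_ref": [1.5, 1.6]})
        kept = filter_low_delayed_hm(df)
        assert kept.empty
        with pytest.raises(ValueError):
            ObserverMeasurementTable(np.empty((0, 2)))

    def test_missing_reference_rejected(self):
        df = pd.DataFrame({"subject": [0, 1], "hm_delayed_ref": [1.2, np.nan]})
        with pytest.raises(ValueError, match="missing reference"):
            filter_low_delayed_hm(df)
        with pytest.raises(KeyError):
            filter_low_delayed_hm(pd.DataFrame({"subject": [0]}))


class TestRequiredSampleSize:
    def test_huge_ci_width_gives_minimum_n(self):
        assert required_sample_size(0.5, ci_width=100.0, k=2) == 2

    def test_near_perfect_reliability_gives_minimum_n(self):
        assert required_sample_size(0.999999, ci_width=0.2, k=2) == 2

    def test_matches_root_finding_oracle_on_planning_case(self):
        """n for (icc0=0.75, width=0.20, k=2) equals the variance-formula inversion."""
        icc0, width, k = 0.75, 0.20, 2
        z = sps.norm.ppf(0.975)

        def ci_width(n):
            var = 2 * (1 - icc0) ** 2 * (1 + (k - 1) * icc0) ** 2 / (k * (k - 1) * (n - 1))
            return 2 * z * np.sqrt(var)

        n = required_sample_size(icc0, width, k)
        assert ci_width(n) <= width < ci_width(n - 1)
        # the planning regime: tens of subjects for two raters, same order of
        # magnitude as a typical reliability study of ~70 patients
        assert 50 < n < 100

    def test_invalid_inputs_rejected(self):
        for bad in [dict(icc0=0.0), dict(icc0=1.0), dict(ci_width=0.0), dict(k=1)]:
            kwargs = dict(icc0=0.75, ci_width=0.2, k=2)
            kwargs.update(bad)
            with pytest.raises(ValueError):
                required_sample_size(**kwargs)
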