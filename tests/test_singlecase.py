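"""Single-case inferential tests: worked examples, oracles, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circleslines.singlecase import (
    CaseScores,
    NormativeSummary,
    case_comparison,
    deficit_test,
    p_from_t,
    rsdt,
    udt,
)


class TestRsdt:
    def test_published_behavioral_example(self, behavioral_norm):
        # printed T = 4.5, p = 0.001; inputs are rounded, hence +/-0.2
        res = rsdt(CaseScores(x=10.4, y=11.5), behavioral_norm)
        assert res.statistic == pytest.approx(4.5, abs=0.2)
        assert res.df == 11
        assert res.p_two_tailed == pytest.approx(0.001, abs=0.001)

    def test_published_roi_example(self):
        # left PPC betas: printed T = 4.14, p = 0.002
        norm = NormativeSummary(0.36, 0.4, 0.91, 0.66, 0.82, 12)
        res = rsdt(CaseScores(x=1.59, y=0.91), norm)
        assert res.statistic == pytest.approx(4.14, abs=0.2)
        assert res.p_two_tailed == pytest.approx(0.002, abs=0.002)

    def test_case_at_control_means_is_null(self, behavioral_norm):
        res = rsdt(CaseScores(x=5.5, y=13.4), behavioral_norm)
        assert res.statistic == 0.0
        assert res.p_two_tailed == 1.0

    def test_statistic_increases_with_discrepancy(self, behavioral_norm):
        stats = [
            abs(rsdt(CaseScores(x=5.5 + d, y=13.4), behavioral_norm).statistic)
            for d in np.linspace(0.5, 10, 8)
        ]
        assert all(a < b for a, b in zip(stats, stats[1:]))

    def test_large_n_limit_matches_asymptotic_form(self):
        n, r = 100_000, 0.8
        norm = NormativeSummary(0.0, 1.0, 0.0, 1.0, r, n)
        case = CaseScores(x=2.0, y=-1.0)
        asym = 3.0 / math.sqrt(2 - 2 * r) * math.sqrt(n / (n + 1))
        got = rsdt(case, norm).statistic
        assert abs(got - asym) / asym < 1e-3

    def test_agrees_with_udt_for_equal_sds_in_large_n_limit(self):
        norm = NormativeSummary(0.0, 1.0, 0.0, 1.0, 0.5, 1_000_000)
        case = CaseScores(x=1.7, y=-0.4)
        assert rsdt(case, norm).statistic == pytest.approx(
            udt(case, norm).statistic, rel=1e-4
        )

    def test_type_one_error_is_calibrated(self, behavioral_norm):
        # null cases drawn from the same bivariate-normal population as the
        # n = 12 control samples (r = 0.8): rejection at alpha = .05 should
        # sit near the nominal rate.
        rng = np.random.default_rng(12345)
        mean = [behavioral_norm.mean_x, behavioral_norm.mean_y]
        sx, sy, r = behavioral_norm.sd_x, behavioral_norm.sd_y, behavioral_norm.r
        cov = np.array([[sx**2, r * sx * sy], [r * sx * sy, sy**2]])
        n_rej, n_rep = 0, 2000
        for _ in range(n_rep):
            draw = rng.multivariate_normal(mean, cov, size=13, method="cholesky")
            ctrl, case = draw[:12], draw[12]
            norm = NormativeSummary(
                ctrl[:, 0].mean(),
                ctrl[:, 0].std(ddof=1),
                ctrl[:, 1].mean(),
                ctrl[:, 1].std(ddof=1),
                float(np.corrcoef(ctrl[:, 0], ctrl[:, 1])[0, 1]),
                12,
            )
            if rsdt(CaseScores(*case), norm).p_two_tailed < 0.05:
                n_rej += 1
        assert 0.03 <= n_rej / n_rep <= 0.07

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sd_x": 0.0},
            {"sd_y": -1.0},
            {"r": 1.0},
            {"r": -1.0},
            {"n": 1},
        ],
    )
    def test_invalid_normative_summary_rejected(self, kwargs):
        base = dict(mean_x=0.0, sd_x=1.0, mean_y=0.0, sd_y=1.0, r=0.5, n=12)
        with pytest.raises(ValueError):
            NormativeSummary(**{**base, **kwargs})


class TestUdt:
    def test_closed_form_oracle(self, behavioral_norm):
        # direct evaluation of the formula on the published inputs
        case = CaseScores(x=10.4, y=11.5)
        sd_d = math.sqrt(1.5**2 + 8.4**2 - 2 * 0.8 * 1.5 * 8.4)
        expected = ((10.4 - 11.5) - (5.5 - 13.4)) / (sd_d * math.sqrt(1 + 1 / 12))
        res = udt(case, behavioral_norm)
        assert res.statistic == pytest.approx(expected, abs=1e-9)
        assert res.statistic == pytest.approx(0.90, abs=0.01)
        assert res.p_two_tailed == pytest.approx(p_from_t(expected, 11), abs=1e-12)

    def test_null_discrepancy(self, behavioral_norm):
        res = udt(CaseScores(x=3.0, y=3.0 + 7.9), behavioral_norm)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_correlated_equal_sds_rejected(self):
        with pytest.raises(ValueError):
            udt(
                CaseScores(1.0, 2.0),
                NormativeSummary(0.0, 1.0, 0.0, 1.0, 1.0, 12),
            )


class TestCaseComparison:
    def test_published_behavioral_example(self):
        # CL-LL OI differences: MN+ 1.1 vs MN- 24.4, control SD 6.8
        res = case_comparison(1.1, 24.4, 6.8, 12)
        assert res.statistic == pytest.approx(-2.4, abs=0.05)
        assert res.df == 11
        assert res.p_two_tailed == pytest.approx(0.03, abs=0.005)

    def test_published_roi_example(self):
        res = case_comparison(-0.01, 0.53, 0.32, 12)
        assert abs(res.statistic) == pytest.approx(1.19, abs=0.05)
        assert res.p_two_tailed == pytest.approx(0.26, abs=0.01)

    def test_identical_cases(self):
        res = case_comparison(5.0, 5.0, 2.0, 12)
        assert res.statistic == 0.0
        assert res.p_two_tailed == 1.0

    @given(
        d1=st.floats(-100, 100),
        d2=st.floats(-100, 100),
        sd=st.floats(0.1, 50),
        n=st.integers(2, 100),
    )
    def test_antisymmetric_in_the_two_cases(self, d1, d2, sd, n):
        a = case_comparison(d1, d2, sd, n)
        b = case_comparison(d2, d1, sd, n)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed, abs=1e-12)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            case_comparison(1.0, 2.0, 0.0, 12)


class TestDeficitTest:
    def test_closed_form(self):
        res = deficit_test(10.4, 5.5, 1.5, 12)
        assert res.statistic == pytest.approx(3.138, abs=0.001)

    def test_case_at_mean_is_null(self):
        res = deficit_test(5.5, 5.5, 1.5, 12)
        assert res.statistic == 0.0 and res.p_two_tailed == 1.0

    def test_large_n_limit(self):
        res = deficit_test(2.0, 0.0, 1.0, 10**9)
        assert res.statistic == pytest.approx(2.0, rel=1e-6)


class TestPFromT:
    def test_zero_statistic(self):
        assert p_from_t(0.0, 11) == 1.0

    def test_matches_printed_pairing(self):
        assert p_from_t(2.42, 11) == pytest.approx(0.034, abs=0.002)

    @given(t=st.floats(-50, 50), df=st.integers(1, 200))
    def test_symmetry_and_range(self, t, df):
        p = p_from_t(t, df)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(p_from_t(-t, df), abs=1e-15)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)
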