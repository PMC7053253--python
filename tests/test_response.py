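import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shapekit.response import (GrowthPhaseModel, PressureSensitivityModel,
                               crossover_qc, fit_regression,
                               hysteresis_delta, max_sensitivity,
                               segment_phases)


def ols_oracle(x, y):
    """Closed-form normal-equations regression with t-test p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sse = np.sum(resid**2)
    syy = np.sum((y - y.mean()) ** 2)
    r2 = 1 - sse / syy if syy > 0 else 0.0
    se = np.sqrt(sse / (n - 2) / sxx)
    t = slope / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p, np.mean(np.abs(resid))


def frame(pressures, sha, output=121.0):
    return pd.DataFrame({"pressure_mmHg": pressures, "sha_dB": sha,
                         "p_neg_kPa": output})


class TestRegression:
    def test_exact_line_at_study_sensitivity(self):
        """A perfect 0.15-dB/mmHg line fits with r2=1 and zero error."""
        p = [0.0, 25.0, 50.0, 75.0]
        y = [10.0, 13.75, 17.5, 21.25]
        fit = fit_regression(frame(p, y), (0.0, 75.0))
        assert fit.slope == pytest.approx(0.15, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.mean_error == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_has_zero_slope(self):
        fit = fit_regression(frame([0, 25, 50, 75], [5.0] * 4), (0, 75))
        assert fit.slope == 0.0
        assert fit.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(0, 200, 5)
            p[0], p[1] = 0.0, 200.0  # guarantee spread
            y = rng.normal(0, 3, 5)
            fit = fit_regression(frame(p, y), (0, 200))
            slope, intercept, r2, pval, merr = ols_oracle(p, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)
            assert fit.p_value == pytest.approx(pval, abs=1e-10)
            assert fit.mean_error == pytest.approx(merr, abs=1e-10)

    def test_too_few_pressures_rejected(self):
        with pytest.raises(ValueError):
            fit_regression(frame([0, 25], [1, 2]), (0, 75))

    def test_summary_mentions_key_quantities(self):
        fit = fit_regression(frame([0, 25, 50, 75], [10, 13.7, 17.6, 21.2]),
                             (0, 75))
        text = fit.summary()
        assert "dB/mmHg" in text and "r^2" in text


class TestMaxSensitivity:
    def test_selects_programmed_growth_output(self):
        """The steepest significant slope wins."""
        rows = []
        rng = np.random.default_rng(1)
        for a, slope in ((60.0, 0.05), (121.0, 0.15), (240.0, 0.02)):
            for p in (0.0, 25.0, 50.0, 75.0):
                for _ in range(3):
                    rows.append({"pressure_mmHg": p, "p_neg_kPa": a,
                                 "sha_dB": slope * p + rng.normal(0, 0.1)})
        best = max_sensitivity(pd.DataFrame(rows), (0, 75))
        assert best.output_kpa == 121.0
        assert best.significant

    def test_single_output_returned(self):
        df = frame([0, 25, 50, 75], [0, 3.75, 7.5, 11.25], output=100.0)
        best = max_sensitivity(df, (0, 75))
        assert best.output_kpa == 100.0

    def test_pure_noise_flagged_non_significant(self):
        rng = np.random.default_rng(5)
        df = frame(np.tile([0, 25, 50, 75], 2), rng.normal(0, 1, 8))
        with pytest.warns(UserWarning, match="non-significant"):
            best = max_sensitivity(df, (0, 75))
        assert not best.significant

    def test_tie_breaks_toward_lower_output(self):
        rows = []
        for a in (200.0, 100.0):
            for p in (0.0, 25.0, 50.0, 75.0):
                rows.append({"pressure_mmHg": p, "p_neg_kPa": a,
                             "sha_dB": 0.15 * p})
        best = max_sensitivity(pd.DataFrame(rows), (0, 75))
        assert best.output_kpa == 100.0


class TestSegmentation:
    @staticmethod
    def three_segment_curve(grid, lo=50.0, hi=250.0, occ=-45.0, sat=-15.0):
        slope = (sat - occ) / np.log10(hi / lo)
        x = np.log10(np.clip(grid, lo, hi) / lo)
        return occ + slope * x

    def test_noiseless_breaks_recovered_exactly(self):
        grid = np.geomspace(30, 330, 20)
        grid[np.argmin(abs(grid - 50))] = 50.0
        grid[np.argmin(abs(grid - 250))] = 250.0
        seg = segment_phases(grid, self.three_segment_curve(grid))
        assert seg.break_lo_kpa == 50.0
        assert seg.break_hi_kpa == 250.0
        assert seg.slopes[1] > max(seg.slopes[0], seg.slopes[2])

    def test_straight_line_has_no_growth_phase(self):
        grid = np.geomspace(30, 330, 12)
        with pytest.raises(ValueError, match="no growth phase"):
            segment_phases(grid, 10 * np.log10(grid))

    def test_noisy_breaks_within_one_grid_step(self):
        rng = np.random.default_rng(11)
        grid = np.geomspace(30, 330, 30)
        y = self.three_segment_curve(grid) + rng.normal(0, 0.3, grid.size)
        seg = segment_phases(grid, y)
        steps = np.log10(grid[1] / grid[0])
        assert abs(np.log10(seg.break_lo_kpa / 50.0)) <= 1.5 * steps
        assert abs(np.log10(seg.break_hi_kpa / 250.0)) <= 1.5 * steps

    def test_invariant_to_db_offset(self):
        grid = np.geomspace(30, 330, 20)
        y = self.three_segment_curve(grid)
        a = segment_phases(grid, y)
        b = segment_phases(grid, y + 17.3)
        assert (a.break_lo_kpa, a.break_hi_kpa) == (b.break_lo_kpa,
                                                    b.break_hi_kpa)
        assert a.slopes == pytest.approx(b.slopes, abs=1e-9)

    def test_equivariant_under_axis_rescale(self):
        grid = np.geomspace(30, 330, 20)
        y = self.three_segment_curve(grid)
        a = segment_phases(grid, y)
        b = segment_phases(grid * 10.0, y)
        assert b.break_lo_kpa == pytest.approx(10 * a.break_lo_kpa)
        assert b.break_hi_kpa == pytest.approx(10 * a.break_hi_kpa)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            GrowthPhaseModel(np.geomspace(30, 330, 5), np.zeros(5))


def curve_frame(outputs, sha):
    return pd.DataFrame({"p_neg_kPa": outputs, "sha_dB": sha})


class TestCrossoverQC:
    def test_sign_change_passes(self):
        a = curve_frame([60, 120, 240], [1.0, 2.0, 1.0])
        b = curve_frame([60, 120, 240], [2.0, 1.0, 2.0])
        passed, report = crossover_qc(a, b)
        assert passed and report["passed"]

    def test_one_sided_pair_fails(self):
        a = curve_frame([60, 120, 240], [3.0, 3.0, 3.0])
        b = curve_frame([60, 120, 240], [2.0, 2.0, 2.0])
        passed, report = crossover_qc(a, b)
        assert not passed
        assert "third replicate" in report["recommendation"]

    def test_mismatched_grids_rejected(self):
        a = curve_frame([60, 120], [1, 2])
        b = curve_frame([60, 150], [1, 2])
        with pytest.raises(ValueError):
            crossover_qc(a, b)

    def test_generator_replicates_cross_frequently(self, model):
        """Two noisy replicates of the same truth usually cross."""
        rng = np.random.default_rng(2)
        outputs = np.geomspace(60, 240, 8)
        truth = model.acoustic_level(outputs)
        passes = 0
        for _ in range(100):
            a = curve_frame(outputs, truth + rng.normal(0, 0.3, 8))
            b = curve_frame(outputs, truth + rng.normal(0, 0.3, 8))
            passes += crossover_qc(a, b)[0]
        assert passes > 90


class TestHysteresisDelta:
    def test_identical_arms_give_zero(self):
        base = curve_frame([60, 121, 181], [-30.0, -25.0, -20.0])
        with pytest.warns(UserWarning):
            res = hysteresis_delta(base, base.copy(), 200.0)
        assert res.max_decrease_db == 0.0

    def test_programmed_dip_recovered(self):
        outputs = [60.0, 121.0, 181.0, 240.0]
        base = curve_frame(outputs, [-30.0, -25.0, -20.0, -18.0])
        post = curve_frame(outputs, [-30.0, -25.5, -23.2, -18.4])
        res = hysteresis_delta(base, post, 200.0)
        assert res.max_decrease_db == pytest.approx(3.2)
        assert res.at_output_kpa == 181.0

    def test_post_louder_everywhere_warns(self):
        base = curve_frame([60, 121], [-30.0, -25.0])
        post = curve_frame([60, 121], [-29.0, -24.0])
        with pytest.warns(UserWarning):
            res = hysteresis_delta(base, post, 200.0)
        assert res.max_decrease_db <= 0

    def test_tie_breaks_toward_lower_output(self):
        base = curve_frame([60.0, 121.0], [-30.0, -25.0])
        post = curve_frame([60.0, 121.0], [-32.0, -27.0])
        res = hysteresis_delta(base, post, 200.0)
        assert res.at_output_kpa == 60.0
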