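"""Tests for the validation battery and the target-exclusion heuristic."""

import numpy as np
import pytest

import respondsim as rs
from conftest import make_outputs_batch


class TestOtherDeathRatio:
    def test_mid_interval_ratio_passes(self):
        out = make_outputs_batch(other_deaths=np.full((1, 3), 3200.0),
                                 fatal_overdoses=np.full((1, 3), 1000.0))
        table = rs.other_death_ratio_check(out)
        assert np.allclose(table.median_ratio, 3.2)
        assert table.in_range.all()

    def test_low_ratio_fails(self):
        out = make_outputs_batch(other_deaths=np.full((1, 3), 1000.0),
                                 fatal_overdoses=np.full((1, 3), 1000.0))
        table = rs.other_death_ratio_check(out)
        assert not table.in_range.any()

    def test_zero_fatal_reported_as_undefined(self):
        out = make_outputs_batch(fatal_overdoses=np.zeros((1, 3)))
        table = rs.other_death_ratio_check(out)
        assert (table.n_undefined == 1).all()
        assert table.median_ratio.isna().all()


class TestUnderreportCheck:
    def test_directions(self):
        out = make_outputs_batch(all_overdoses=np.array(
            [[12000.0, 10000.0, 10000.0]]))
        obs = {2013: 10000.0, 2014: 10000.0, 2015: 12000.0}
        table = rs.overdose_underreport_check(out, obs)
        assert list(table.direction) == ["above", "equal", "below"]
        assert table["diff"].iloc[0] == pytest.approx(2000.0)

    def test_missing_year_raises(self):
        out = make_outputs_batch()
        with pytest.raises(rs.ConfigError):
            rs.overdose_underreport_check(out, {2013: 1.0})


class TestActivePercentages:
    def test_all_non_active_and_all_active(self):
        zero = make_outputs_batch(active_pct=np.zeros((1, 3)),
                                  active_pct_group=np.zeros((1, 3, 3)))
        table = rs.active_percentage_summary(zero)
        assert (table["median"] == 0).all()
        full = make_outputs_batch(active_pct=np.full((1, 3), 100.0),
                                  active_pct_group=np.full((1, 3, 3), 100.0))
        assert (rs.active_percentage_summary(full)["median"] == 100).all()

    def test_ordering_flag(self):
        group = np.tile(np.array([70.0, 25.0, 80.0]), (1, 3, 1))
        table = rs.active_percentage_summary(
            make_outputs_batch(active_pct_group=group))
        assert table.ordering_ok.all()
        bad = np.tile(np.array([70.0, 85.0, 80.0]), (1, 3, 1))
        table = rs.active_percentage_summary(
            make_outputs_batch(active_pct_group=bad))
        assert not table.ordering_ok.any()


class TestSeparationMeasures:
    def test_overlap_identical_and_disjoint(self):
        x = np.linspace(0, 1, 300)
        assert rs.overlap_coefficient(x, x) > 0.95
        assert rs.overlap_coefficient(x, x + 5.0) == 0.0

    def test_interval_overlap(self):
        x = np.linspace(0, 1, 100)
        assert rs.interval_overlap(x, x) == pytest.approx(1.0, abs=1e-6)
        assert rs.interval_overlap(x, x + 10) == 0.0

    def test_marginal_comparison_columns(self):
        import pandas as pd
        a = pd.DataFrame({"p": np.linspace(0, 1, 50)})
        b = pd.DataFrame({"p": np.linspace(2, 3, 50)})
        table = rs.marginal_comparison(a, b)
        row = table.iloc[0]
        assert row.overlap == 0.0 and row.ks == 1.0


class TestStageSplitComparison:
    def test_requires_trace(self, bundle):
        res = rs.run_calibration(bundle.space, bundle.fixed, bundle.targets,
                                 n=16, seed=1)
        with pytest.raises(rs.ConfigError):
            rs.stage_split_comparison(res, "total_oud")

    def test_split_on_wide_run(self, wide_window_run):
        table = rs.stage_split_comparison(wide_window_run, "total_oud",
                                          ["m_n", "arrivals.2015"])
        assert set(table.parameter) == {"m_n", "arrivals.2015"}
        assert table.overlap.between(0, 1).all()


class TestBackwardExclusion:
    def test_steps_structure_and_growing_acceptance(self, bundle):
        steps = rs.backward_target_exclusion(
            bundle.space, bundle.fixed, bundle.targets, n=400, seed=17,
            window_scale=4.0, strict_trend=False)
        assert [s.removed for s in steps] == [(), ("fatal",),
                                              ("detox", "fatal")]
        # removing targets can only enlarge the accepted set (same design)
        counts = [s.result.n_accepted for s in steps]
        assert counts[0] <= counts[1] <= counts[2]
        baseline = rs.run_calibration(bundle.space, bundle.fixed,
                                      bundle.targets, n=400, seed=17,
                                      window_scale=4.0, strict_trend=False)
        assert steps[0].result.n_accepted == baseline.n_accepted

    def test_needs_two_families(self, bundle):
        only_fatal = [t for t in bundle.targets if t.family == "fatal"]
        with pytest.raises(rs.ConfigError):
            rs.backward_target_exclusion(bundle.space, bundle.fixed,
                                         only_fatal, n=10, seed=1)


class TestReportAssembly:
    def test_report_roundtrip(self):
        out = make_outputs_batch(n=4)
        report = rs.build_validation_report(out, {2013: 1.0, 2014: 1.0,
                                                  2015: 1.0})
        d = report.to_dict()
        back = rs.ValidationReport.from_dict(d)
        assert back.other_death_ratios.equals(report.other_death_ratios)
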