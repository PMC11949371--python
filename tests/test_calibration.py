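"""Tests for target windows, the sequential filter and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import respondsim as rs
from conftest import make_outputs_batch


class TestWindows:
    def test_pct10_window_arithmetic(self, targets):
        windows = rs.make_windows(targets)
        w = windows["fatal:2015"]
        assert w.lo == pytest.approx(1405.8)
        assert w.hi == pytest.approx(1718.2)

    def test_ci_window_verbatim(self, targets):
        w = rs.make_windows(targets)["total_oud:2015"]
        assert (w.lo, w.hi) == (272707.0, 277402.0)

    def test_trend_only_targets_carry_no_window(self, targets):
        windows = rs.make_windows(targets)
        assert "total_oud:2013" not in windows
        assert "total_oud:2014" not in windows

    def test_degenerate_window_flagged(self):
        t = rs.TargetSpec("zero", "fatal", 2013, 0.0, "pct10")
        with pytest.warns(UserWarning, match="degenerate"):
            windows = rs.make_windows([t])
        assert windows["zero"].degenerate
        assert windows["zero"].lo == windows["zero"].hi == 0.0


def _outputs(total=(230000, 250000, 275000), detox=(39635, 41229, 38329),
             fatal=(900, 1294, 1562)):
    total = np.asarray(total, dtype=float)
    fatal = np.asarray(fatal, dtype=float)
    other = np.full(3, 3000.0)
    return make_outputs_batch(
        alive=(total - fatal - other)[None], fatal_overdoses=fatal[None],
        other_deaths=other[None], detox_admissions=np.asarray(detox, float)[None],
    ).item(0)


class TestSequentialFilter:
    def test_all_pass(self, targets):
        rec = rs.sequential_filter(_outputs(), rs.make_windows(targets), targets)
        assert rec.accepted
        assert all(v is True for v in rec.stages.values())

    def test_failure_short_circuits(self, targets):
        out = _outputs(detox=(39635 * 1.25, 41229, 38329))
        rec = rs.sequential_filter(out, rs.make_windows(targets), targets)
        assert not rec.accepted
        assert rec.stages["total_oud"] is True
        assert rec.stages["detox"] is False
        assert rec.stages["fatal"] is None  # never reached
        assert rec.stages["trend"] is None

    def test_trend_violation_rejected_last(self, targets):
        out = _outputs(total=(250000, 240000, 275000))
        rec = rs.sequential_filter(out, rs.make_windows(targets), targets)
        assert not rec.accepted
        assert rec.stages["fatal"] is True
        assert rec.stages["trend"] is False

    def test_missing_year_raises(self, targets):
        out = make_outputs_batch(years=(2013, 2014)).item(0)
        with pytest.raises(rs.ConfigError):
            rs.sequential_filter(out, rs.make_windows(targets), targets)


class TestRunCalibration:
    def test_everything_accepted_with_infinite_windows(self, bundle):
        wide = [rs.TargetSpec(t.name, t.family, t.year, t.point, "ci",
                              -1e18, 1e18) if t.window_rule != "trend_only"
                else t for t in bundle.targets]
        res = rs.run_calibration(bundle.space, bundle.fixed, wide, n=64,
                                 seed=2, trend_filter=False)
        assert res.acceptance_rate == 1.0

    def test_monotone_attrition_and_chained_counts(self, wide_window_run):
        res = wide_window_run
        assert all(a >= b for a, b in zip(res.counts_passing,
                                          res.counts_passing[1:]))
        for i in range(1, len(res.stage_names)):
            assert res.counts_entering[i] == res.counts_passing[i - 1]
        assert res.counts_passing[-1] == res.n_accepted

    def test_filter_invariant_to_batch_partitioning(self, bundle):
        kw = dict(n=400, seed=13, window_scale=4.0, strict_trend=False)
        a = rs.run_calibration(bundle.space, bundle.fixed, bundle.targets,
                               batch_size=97, **kw)
        b = rs.run_calibration(bundle.space, bundle.fixed, bundle.targets,
                               batch_size=400, **kw)
        assert np.array_equal(a.fail_stage, b.fail_stage)
        assert np.array_equal(a.accepted_index, b.accepted_index)

    def test_accepted_marginals_inside_prior_support(self, wide_window_run):
        frame = wide_window_run.accepted_frame
        for m in wide_window_run.space.marginals:
            x = frame[m.name]
            assert x.min() >= m.lo and x.max() <= m.hi

    def test_acceptance_idempotence(self, bundle, wide_window_run):
        res = wide_window_run
        out = rs.run_simulation_batch(bundle.fixed, res.accepted_params)
        for t in bundle.targets:
            if t.window_rule == "trend_only":
                continue
            w = res.windows[t.name]
            measure = {"total_oud": "total_oud", "detox": "detox_admissions",
                       "fatal": "fatal_overdoses"}[t.family]
            vals = out.year_col(measure, t.year)
            assert np.all(w.contains(vals))

    def test_zero_acceptances_reports_histogram(self, bundle):
        impossible = [rs.TargetSpec("total_oud:2015", "total_oud", 2015,
                                    275070.0, "ci", 0.0, 1.0)]
        res = rs.run_calibration(bundle.space, bundle.fixed, impossible,
                                 n=32, seed=3)
        assert res.n_accepted == 0
        hist = res.failure_histogram()
        assert hist.loc[hist.stage == "total_oud", "count"].item() == 32

    def test_iterated_batches_use_distinct_streams(self, bundle):
        results = rs.iterate_calibration(
            bundle.space, bundle.fixed, bundle.targets, [50, 50], seed=21,
            window_scale=4.0, strict_trend=False)
        assert len(results) == 2
        assert results[0].seed != results[1].seed


class TestBoundaryDiagnostic:
    SPACE = rs.ParameterSpace([rs.MarginalSpec("x", "uniform", 0.0, 1.0)])

    def test_uniform_sample_not_flagged(self):
        frame = pd.DataFrame({"x": np.linspace(0.01, 0.99, 100)})
        diag = rs.boundary_diagnostic(frame, self.SPACE)
        assert not diag.flagged.item()

    def test_edge_concentration_flagged_with_expansion(self):
        frame = pd.DataFrame({"x": np.linspace(0.96, 0.995, 50)})
        diag = rs.boundary_diagnostic(frame, self.SPACE)
        assert diag.flagged.item()
        assert diag.suggested_hi.item() > 1.0

    def test_bimodal_at_both_edges_flagged(self):
        x = np.concatenate([np.linspace(0, 0.05, 30), np.linspace(0.95, 1, 30)])
        diag = rs.boundary_diagnostic(pd.DataFrame({"x": x}), self.SPACE)
        assert diag.flagged.item()
        assert diag.suggested_lo.item() < 0.0
        assert diag.suggested_hi.item() > 1.0


class TestStabilityCheck:
    def test_full_subsample_has_zero_distance(self, bundle, wide_window_run):
        res = wide_window_run
        table = rs.stability_check(res, bundle.fixed, [res.n_accepted], seed=1)
        assert np.allclose(table.ks, 0.0)

    def test_single_draw_is_maximally_unstable(self, bundle, wide_window_run):
        table = rs.stability_check(wide_window_run, bundle.fixed, [1], seed=1)
        assert table.ks.max() >= 0.4

    def test_subsample_larger_than_accepted_raises(self, bundle, wide_window_run):
        with pytest.raises(rs.ConfigError):
            rs.stability_check(wide_window_run, bundle.fixed,
                               [wide_window_run.n_accepted + 1], seed=1)
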