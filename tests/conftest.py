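import numpy as np
import pytest

import respondsim as rs


@pytest.fixture(scope="session")
def bundle():
    return rs.build_default_bundle(seed=0)


@pytest.fixture(scope="session")
def fixed(bundle):
    return bundle.fixed


@pytest.fixture(scope="session")
def space(bundle):
    return bundle.space


@pytest.fixture(scope="session")
def targets(bundle):
    return bundle.targets


@pytest.fixture(scope="session")
def midpoint(bundle):
    return rs.midpoint_inputs(bundle.space, bundle.fixed.strata)


@pytest.fixture(scope="session")
def midpoint_outputs(bundle, midpoint):
    return rs.run_simulation(bundle.fixed, midpoint)


@pytest.fixture(scope="session")
def wide_window_run(bundle):
    """Calibration with every window widened 4x and the trend relaxed:
    a high-acceptance run used by diagnostics that need many accepted sets."""
    return rs.run_calibration(bundle.space, bundle.fixed, bundle.targets,
                              n=6000, seed=5, window_scale=4.0,
                              strict_trend=False, keep_trace=True)


@pytest.fixture(scope="session")
def calibration_run(bundle):
    """The scaled-down study-condition calibration: 1e5 LHS candidates."""
    return rs.run_calibration(bundle.space, bundle.fixed, bundle.targets,
                              n=100_000, seed=42)


@pytest.fixture(scope="session")
def microsim_comparison():
    """Cohort expectations vs the agent-based oracle on a one-stratum toy."""
    import _microsim
    fixed, calib = _microsim.toy_inputs()
    n_weeks = 52
    expected = _microsim.cohort_expectations(fixed, calib, n_weeks)
    observed = _microsim.run_microsim(fixed, calib, n_weeks, seed=1234)
    return expected, observed


def make_outputs_batch(years=(2013, 2014, 2015), **overrides):
    """Fabricate an AnnualOutputsBatch with controllable columns."""
    ny = len(years)
    n = overrides.pop("n", 1)
    defaults = {
        "alive": np.full((n, ny), 1e5), "fatal_overdoses": np.full((n, ny), 1e3),
        "other_deaths": np.full((n, ny), 3e3),
        "detox_admissions": np.full((n, ny), 4e4),
        "all_overdoses": np.full((n, ny), 1.2e4),
        "active_pct": np.full((n, ny), 70.0),
        "active_pct_group": np.full((n, ny, 3), 70.0),
    }
    for k, v in overrides.items():
        defaults[k] = np.asarray(v, dtype=float)
    return rs.AnnualOutputsBatch(tuple(years), **defaults)
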