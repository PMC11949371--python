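"""External and face-validity checks of the calibrated model.

Covers: the other-cause-deaths / fatal-overdoses ratio (literature puts it
at 2.4-4.1x), the direction of simulated vs observed all-overdose counts
(observed counts are under-reported, so the model is expected to sit above
them), active-use percentage summaries with their expected ordering across
health-state groups, and the backward target-exclusion heuristic that
re-runs calibration with target families removed from the last filter
stage backwards to expose parameters a target was pinning down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .calibration import (
    CalibrationResult,
    TargetSpec,
    TARGET_FAMILIES,
    run_calibration,
)
from .core import AnnualOutputsBatch
from .errors import ConfigError
from .inputs import FixedInputs
from .space import ParameterSpace
from .strata import HEALTH_GROUPS

OTHER_DEATH_RATIO_RANGE = (2.4, 4.1)


def other_death_ratio_check(outputs: AnnualOutputsBatch,
                            lo: float = OTHER_DEATH_RATIO_RANGE[0],
                            hi: float = OTHER_DEATH_RATIO_RANGE[1]
                            ) -> pd.DataFrame:
    """Per-year other-cause-deaths / fatal-overdoses ratio across sets.

    The central (median) estimate is flagged against the literature range.
    Sets with zero fatal overdoses have an undefined ratio and are counted
    separately rather than silently dropped into the quantiles.
    """
    rows = []
    for yi, year in enumerate(outputs.years):
        fatal = outputs.fatal_overdoses[:, yi]
        other = outputs.other_deaths[:, yi]
        defined = fatal > 0
        ratios = other[defined] / fatal[defined]
        if ratios.size:
            med = float(np.median(ratios))
            q = np.percentile(ratios, [2.5, 97.5])
            row = {"year": year, "median_ratio": med, "lo": float(q[0]),
                   "hi": float(q[1]), "in_range": bool(lo <= med <= hi)}
        else:
            row = {"year": year, "median_ratio": np.nan, "lo": np.nan,
                   "hi": np.nan, "in_range": False}
        row["n_undefined"] = int((~defined).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def overdose_underreport_check(outputs: AnnualOutputsBatch,
                               observed: Dict[int, float]) -> pd.DataFrame:
    """Simulated minus observed all-overdose counts per year.

    Observed counts are under-reported, so the expected direction is
    simulated above observed; the check reports the direction rather than
    enforcing it (the model can genuinely sit below for some years).
    """
    rows = []
    for yi, year in enumerate(outputs.years):
        if year not in observed:
            raise ConfigError(f"no observed overdose count for year {year}")
        sim = outputs.all_overdoses[:, yi]
        med = float(np.median(sim))
        diff = med - observed[year]
        direction = "above" if diff > 0 else ("below" if diff < 0 else "equal")
        rows.append({"year": year, "observed": float(observed[year]),
                     "simulated_median": med, "diff": diff,
                     "direction": direction,
                     "expected_direction": direction == "above"})
    return pd.DataFrame(rows)


def active_percentage_summary(outputs: AnnualOutputsBatch) -> pd.DataFrame:
    """Year-end active-use percentages: overall and per health-state group.

    Medians and 2.5/97.5 percentile intervals across accepted sets, plus
    face-validity flags for the expected ordering
    (treatment < no-treatment < post-treatment).
    """
    if outputs.size < 1:
        raise ConfigError("need at least one accepted set")
    rows = []
    for yi, year in enumerate(outputs.years):
        series = {"overall": outputs.active_pct[:, yi]}
        for gi, g in enumerate(HEALTH_GROUPS):
            series[g] = outputs.active_pct_group[:, yi, gi]
        med = {k: float(np.median(v)) for k, v in series.items()}
        ordering_ok = (med["treatment"] < med["no_treatment"]
                       < med["post_treatment"])
        for k, v in series.items():
            q = np.percentile(v, [2.5, 97.5])
            rows.append({"year": year, "group": k, "median": med[k],
                         "lo": float(q[0]), "hi": float(q[1]),
                         "ordering_ok": ordering_ok})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distribution-separation measures and the exclusion heuristic
# ---------------------------------------------------------------------------


def overlap_coefficient(x: np.ndarray, y: np.ndarray, bins: int = 30) -> float:
    """Histogram overlap coefficient (integrated min of the two normalized
    histograms over shared bins); 1 for identical samples, 0 for disjoint."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    px, _ = np.histogram(x, bins=edges)
    py, _ = np.histogram(y, bins=edges)
    return float(np.minimum(px / px.sum(), py / py.sum()).sum())


def interval_overlap(x: np.ndarray, y: np.ndarray,
                     q: tuple = (2.5, 97.5)) -> float:
    """Overlap of the two samples' central quantile intervals, as a fraction
    of the shorter interval (0 = disjoint ranges)."""
    ax, bx = np.percentile(x, q)
    ay, by = np.percentile(y, q)
    inter = max(0.0, min(bx, by) - max(ax, ay))
    shorter = min(bx - ax, by - ay)
    if shorter <= 0:
        return 1.0 if inter > 0 else 0.0
    return float(inter / shorter)


def marginal_comparison(frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                        parameters: Optional[Sequence[str]] = None
                        ) -> pd.DataFrame:
    """Per-parameter separation between two sets of parameter vectors:
    histogram overlap, central-interval overlap and KS distance."""
    parameters = list(parameters or frame_a.columns)
    rows = []
    for p in parameters:
        x = frame_a[p].to_numpy()
        y = frame_b[p].to_numpy()
        rows.append({
            "parameter": p,
            "overlap": overlap_coefficient(x, y),
            "interval_overlap": interval_overlap(x, y),
            "ks": float(ks_2samp(x, y).statistic) if x.size and y.size else np.nan,
        })
    return pd.DataFrame(rows)


def stage_split_comparison(result: CalibrationResult, stage: str,
                           parameters: Optional[Sequence[str]] = None
                           ) -> pd.DataFrame:
    """Compare parameter marginals of candidates *accepted* overall against
    candidates *rejected at* the named filter stage.

    Requires a calibration run with ``keep_trace=True`` so the full design
    matrix and per-candidate failure stages are available.
    """
    if result.trace is None:
        raise ConfigError("stage comparison needs a calibration run with "
                          "keep_trace=True")
    try:
        s = result.stage_names.index(stage)
    except ValueError as exc:
        raise ConfigError(f"unknown stage {stage!r}") from exc
    accepted = result.fail_stage < 0
    rejected_here = result.fail_stage == s
    if not accepted.any() or not rejected_here.any():
        raise ConfigError("need both accepted candidates and candidates "
                          f"rejected at stage {stage!r}")
    return marginal_comparison(result.trace[accepted],
                               result.trace[rejected_here], parameters)


@dataclass
class ExclusionStep:
    removed: tuple
    result: CalibrationResult
    comparison: Optional[pd.DataFrame]  # None for the baseline step


@dataclass
class ValidationReport:
    other_death_ratios: pd.DataFrame
    overdose_comparison: pd.DataFrame
    active_percentages: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "other_death_ratios": self.other_death_ratios.to_dict("records"),
            "overdose_comparison": self.overdose_comparison.to_dict("records"),
            "active_percentages": self.active_percentages.to_dict("records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(pd.DataFrame(d["other_death_ratios"]),
                   pd.DataFrame(d["overdose_comparison"]),
                   pd.DataFrame(d["active_percentages"]))


def build_validation_report(outputs: AnnualOutputsBatch,
                            observed: Dict[int, float]) -> ValidationReport:
    """The full validation battery on a set of accepted-run outputs."""
    return ValidationReport(
        other_death_ratio_check(outputs),
        overdose_underreport_check(outputs, observed),
        active_percentage_summary(outputs))


def backward_target_exclusion(space: ParameterSpace, fixed: FixedInputs,
                              targets: Sequence[TargetSpec], n: int, seed: int,
                              **calib_kwargs) -> List[ExclusionStep]:
    """Backward target-exclusion heuristic.

    Re-runs the calibration with windowed target families removed
    cumulatively, starting from the last filter stage (fatal, then detox).
    Every run reuses the same seed, hence the identical LHS design, so a
    step's newly accepted candidates are exactly candidates the previous
    step rejected. Each step's comparison table contrasts the previous
    step's accepted sets against the newly accepted ones (equivalently:
    accepted vs rejected-by-the-removed-target), per parameter.
    """
    fams_present = [f for f in TARGET_FAMILIES
                    if any(t.family == f and t.window_rule != "trend_only"
                           for t in targets)]
    if len(fams_present) < 2:
        raise ConfigError("exclusion heuristic needs at least two windowed "
                          "target families")
    steps: List[ExclusionStep] = []
    removed: tuple = ()
    prev: Optional[CalibrationResult] = None
    for k in range(len(fams_present)):
        removed = tuple(fams_present[len(fams_present) - k:])
        keep = [t for t in targets if t.family not in removed]
        res = run_calibration(space, fixed, keep, n, seed,
                              keep_trace=True, **calib_kwargs)
        comparison = None
        if prev is not None and prev.n_accepted and res.n_accepted:
            prev_acc = prev.fail_stage < 0
            newly = (res.fail_stage < 0) & ~prev_acc
            if newly.any():
                comparison = marginal_comparison(res.trace[prev_acc],
                                                 res.trace[newly])
        steps.append(ExclusionStep(removed, res, comparison))
        prev = res
    return steps
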