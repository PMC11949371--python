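"""Empirical rejection calibration against target uncertainty windows.

The algorithm: draw N candidate parameter sets by Latin hypercube sampling
of the prior space, simulate each, and accept a candidate only if its
outputs fall inside every target window, evaluated as a sequential filter
in a fixed order -- 2015 total OUD count, then detox admissions (all
years), then fatal overdoses (all years), then a strictly increasing total
OUD trend. Windows are published 95% CIs where available and +/-10% of the
observed count otherwise. Diagnostics cover boundary concentration of
accepted marginals (suggesting range shifts) and the stability of output
distributions under accepted-set subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .core import AnnualOutputs, AnnualOutputsBatch, run_simulation_batch
from .errors import ConfigError
from .inputs import CalibratedBatch, FixedInputs
from .space import (
    DesignMatrix,
    ParameterSpace,
    batch_to_frame,
    design_to_batch,
    lhs_sample,
)
from .strata import StrataConfig

TARGET_FAMILIES = ("total_oud", "detox", "fatal")
TREND_STAGE = "trend"


@dataclass(frozen=True)
class TargetSpec:
    """One calibration target.

    ``window_rule`` is ``"ci"`` (explicit interval), ``"pct10"``
    (+/-10% of the point value) or ``"trend_only"`` (participates in the
    trend constraint but carries no acceptance window).
    """

    name: str
    family: str
    year: int
    point: float
    window_rule: str
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self):
        if self.family not in TARGET_FAMILIES:
            raise ConfigError(f"unknown target family {self.family!r}")
        if self.window_rule not in ("ci", "pct10", "trend_only"):
            raise ConfigError(f"unknown window rule {self.window_rule!r}")
        if self.window_rule == "ci":
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ConfigError(f"{self.name}: CI window needs lo < hi")

    def to_dict(self) -> dict:
        return {"name": self.name, "family": self.family, "year": self.year,
                "point": float(self.point), "window_rule": self.window_rule,
                "lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "TargetSpec":
        lo = d.get("lo")
        hi = d.get("hi")
        return cls(d["name"], d["family"], int(d["year"]), float(d["point"]),
                   d["window_rule"],
                   None if lo is None else float(lo),
                   None if hi is None else float(hi))


@dataclass(frozen=True)
class Window:
    lo: float
    hi: float
    degenerate: bool = False

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.lo) & (x <= self.hi)


def make_windows(targets: Sequence[TargetSpec]) -> Dict[str, Window]:
    """Evaluate each windowed target's acceptance interval."""
    out: Dict[str, Window] = {}
    for t in targets:
        if t.window_rule == "trend_only":
            continue
        if t.window_rule == "ci":
            out[t.name] = Window(float(t.lo), float(t.hi))
        else:  # pct10
            lo, hi = 0.9 * t.point, 1.1 * t.point
            degenerate = lo == hi
            if degenerate:
                warnings.warn(f"target {t.name}: degenerate +/-10% window at "
                              f"point {t.point}")
            out[t.name] = Window(lo, hi, degenerate)
    return out


@dataclass
class AcceptanceRecord:
    """Per-candidate trace of the sequential filter.

    ``stages`` maps stage name to True/False, or None when the stage was
    never reached (evaluation short-circuits at the first failure).
    """

    candidate: int
    stages: Dict[str, Optional[bool]]
    accepted: bool


def _stage_plan(targets: Sequence[TargetSpec], strict_trend: bool = True,
                arrivals_trend: bool = False, trend_filter: bool = True
                ) -> List[str]:
    """Filter stage order: windowed total OUD, detox, fatal, then trend."""
    fams = []
    for fam in TARGET_FAMILIES:
        if any(t.family == fam and t.window_rule != "trend_only" for t in targets):
            fams.append(fam)
    plan = [f"{fam}" for fam in fams]
    if trend_filter:
        plan.append(TREND_STAGE)
    if arrivals_trend:
        plan.append("arrivals_trend")
    return plan


def _family_targets(targets, fam):
    return [t for t in targets if t.family == fam and t.window_rule != "trend_only"]


def _stage_pass_masks(outputs: AnnualOutputsBatch, targets: Sequence[TargetSpec],
                      windows: Dict[str, Window], plan: List[str],
                      strict_trend: bool,
                      batch: CalibratedBatch | None = None) -> np.ndarray:
    """(B, n_stages) unconditional pass mask per stage (no short-circuit)."""
    B = outputs.size
    masks = np.ones((B, len(plan)), dtype=bool)
    for si, stage in enumerate(plan):
        if stage == TREND_STAGE:
            tot = outputs.total_oud
            if strict_trend:
                m = np.all(tot[:, 1:] > tot[:, :-1], axis=1)
            else:
                m = np.all(tot[:, 1:] >= tot[:, :-1], axis=1)
        elif stage == "arrivals_trend":
            if batch is None:
                raise ConfigError("arrivals trend filter needs parameter values")
            m = batch.arrivals[:, 1] > batch.arrivals[:, 0]
        else:
            measure = {"total_oud": "total_oud", "detox": "detox_admissions",
                       "fatal": "fatal_overdoses"}[stage]
            m = np.ones(B, dtype=bool)
            for t in _family_targets(targets, stage):
                vals = outputs.year_col(measure, t.year)
                m &= windows[t.name].contains(vals)
        masks[:, si] = m
    return masks


def _sequential(masks: np.ndarray):
    """Apply short-circuit semantics to unconditional stage masks.

    Returns (reached (B, S), accepted (B,), fail_stage (B,) with -1 for
    accepted candidates).
    """
    B, S = masks.shape
    reached = np.ones((B, S), dtype=bool)
    ok = np.ones(B, dtype=bool)
    fail = np.full(B, -1, dtype=np.int16)
    for s in range(S):
        reached[:, s] = ok
        newly_failed = ok & ~masks[:, s]
        fail[newly_failed] = s
        ok &= masks[:, s]
    return reached, ok, fail


def sequential_filter(outputs: AnnualOutputs, windows: Dict[str, Window],
                      targets: Sequence[TargetSpec],
                      strict_trend: bool = True,
                      candidate: int = 0) -> AcceptanceRecord:
    """Run one candidate's outputs through the ordered filter.

    Stages are evaluated in the fixed order and evaluation stops at the
    first failure; unreached stages are recorded as None.
    """
    for t in targets:
        if t.year not in outputs.years:
            raise ConfigError(f"outputs do not cover target year {t.year}")
    plan = _stage_plan(targets, strict_trend)
    b = AnnualOutputsBatch(outputs.years, outputs.alive[None],
                           outputs.fatal_overdoses[None],
                           outputs.other_deaths[None],
                           outputs.detox_admissions[None],
                           outputs.all_overdoses[None],
                           outputs.active_pct[None],
                           outputs.active_pct_group[None])
    masks = _stage_pass_masks(b, targets, windows, plan, strict_trend)
    reached, ok, _ = _sequential(masks)
    stages = {stage: (bool(masks[0, s]) if reached[0, s] else None)
              for s, stage in enumerate(plan)}
    return AcceptanceRecord(candidate, stages, bool(ok[0]))


@dataclass
class CalibrationResult:
    """Accepted parameter sets plus the stagewise attrition trace."""

    space: ParameterSpace
    strata: StrataConfig
    years: tuple
    seed: int
    n: int
    stage_names: List[str]
    counts_entering: List[int]
    counts_passing: List[int]
    accepted_index: np.ndarray
    accepted_params: Optional[CalibratedBatch]
    accepted_outputs: Optional[AnnualOutputsBatch]
    windows: Dict[str, Window]
    fail_stage: np.ndarray  # (n,) first failed stage index, -1 if accepted
    trace: Optional[pd.DataFrame] = None  # full design values if kept

    @property
    def n_accepted(self) -> int:
        return int(len(self.accepted_index))

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n

    @property
    def accepted_frame(self) -> pd.DataFrame:
        if self.accepted_params is None or self.n_accepted == 0:
            return pd.DataFrame(columns=self.space.names)
        return batch_to_frame(self.accepted_params, self.strata, self.years)

    def failure_histogram(self) -> pd.DataFrame:
        names = list(self.stage_names) + ["accepted"]
        idx = np.where(self.fail_stage < 0, len(self.stage_names),
                       self.fail_stage)
        counts = np.bincount(idx, minlength=len(names))
        return pd.DataFrame({"stage": names, "count": counts})

    def manifest(self) -> dict:
        return {
            "seed": int(self.seed), "n": int(self.n),
            "n_accepted": self.n_accepted,
            "acceptance_rate": self.acceptance_rate,
            "stage_names": list(self.stage_names),
            "counts_entering": [int(c) for c in self.counts_entering],
            "counts_passing": [int(c) for c in self.counts_passing],
        }


def run_calibration(space: ParameterSpace, fixed: FixedInputs,
                    targets: Sequence[TargetSpec], n: int, seed: int,
                    batch_size: int = 4000, n_weeks: int = 156,
                    strict_trend: bool = True, arrivals_trend: bool = False,
                    trend_filter: bool = True, keep_trace: bool = False,
                    window_scale: float = 1.0) -> CalibrationResult:
    """Simulate N LHS candidates and filter them through the target windows.

    Candidates are advanced through the weekly cycle many at a time
    (vectorized batches of ``batch_size``); the filter outcome is
    independent of the batching. ``window_scale`` widens (or narrows) every
    window about its midpoint, for diagnostics; the default 1.0 is the
    calibration protocol proper.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    design = lhs_sample(space, n, seed)
    cb = design_to_batch(design, fixed.strata, fixed.years)
    targets = list(targets)
    windows = make_windows(targets)
    if window_scale != 1.0:
        windows = {k: Window(0.5 * (w.lo + w.hi) - 0.5 * (w.hi - w.lo) * window_scale,
                             0.5 * (w.lo + w.hi) + 0.5 * (w.hi - w.lo) * window_scale,
                             w.degenerate)
                   for k, w in windows.items()}
    plan = _stage_plan(targets, strict_trend, arrivals_trend, trend_filter)

    fail_stage = np.empty(n, dtype=np.int16)
    accepted_masks = []
    outputs_chunks: List[AnnualOutputsBatch] = []
    reached_counts = np.zeros(len(plan), dtype=np.int64)
    passed_counts = np.zeros(len(plan), dtype=np.int64)

    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        sub = cb.select(slice(start, stop))
        out = run_simulation_batch(fixed, sub, n_weeks, check=False)
        masks = _stage_pass_masks(out, targets, windows, plan, strict_trend, sub)
        reached, ok, fail = _sequential(masks)
        reached_counts += reached.sum(axis=0)
        passed_counts += (reached & masks).sum(axis=0)
        fail_stage[start:stop] = fail
        accepted_masks.append(ok)
        if ok.any():
            outputs_chunks.append(out.select(ok))

    accepted = np.concatenate(accepted_masks)
    accepted_index = np.flatnonzero(accepted)
    if accepted_index.size:
        accepted_params = cb.select(accepted_index)
        acc_out = outputs_chunks[0]
        if len(outputs_chunks) > 1:
            acc_out = AnnualOutputsBatch(
                acc_out.years,
                *[np.concatenate([getattr(o, f) for o in outputs_chunks])
                  for f in ("alive", "fatal_overdoses", "other_deaths",
                            "detox_admissions", "all_overdoses", "active_pct",
                            "active_pct_group")])
    else:
        accepted_params = None
        acc_out = None

    result = CalibrationResult(
        space=space, strata=fixed.strata, years=tuple(fixed.years), seed=seed,
        n=n, stage_names=plan,
        counts_entering=[int(c) for c in reached_counts],
        counts_passing=[int(c) for c in passed_counts],
        accepted_index=accepted_index, accepted_params=accepted_params,
        accepted_outputs=acc_out, windows=windows, fail_stage=fail_stage,
        trace=design.to_frame() if keep_trace else None)
    return result


def iterate_calibration(space: ParameterSpace, fixed: FixedInputs,
                        targets: Sequence[TargetSpec],
                        batch_sizes: Sequence[int], seed: int,
                        **kwargs) -> List[CalibrationResult]:
    """Resumable growing-N protocol: run successive independent LHS batches
    under a deterministic seed sequence and collect their results.

    Each batch draws fresh samples with its own derived seed, so random
    streams are never reused; merge accepted sets across the returned
    results to emulate "increase N and repeat".
    """
    children = np.random.SeedSequence(seed).spawn(len(batch_sizes))
    results = []
    for bn, child in zip(batch_sizes, children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        results.append(run_calibration(space, fixed, targets, bn, sub_seed,
                                       **kwargs))
    return results


def boundary_diagnostic(result: CalibrationResult, space: ParameterSpace,
                        edge_frac: float = 0.10,
                        mass_threshold: float = 0.30) -> pd.DataFrame:
    """Flag parameters whose accepted values pile up at the prior edges.

    A parameter is flagged when more than ``mass_threshold`` of accepted
    mass falls in the outer ``edge_frac`` of its prior range on either
    side; a shifted/expanded range is suggested for flagged parameters.
    """
    if isinstance(result, pd.DataFrame):
        frame = result
    else:
        if result.n_accepted == 0:
            raise ConfigError("boundary diagnostic needs at least one accepted set")
        frame = result.accepted_frame
    if len(frame) == 0:
        raise ConfigError("boundary diagnostic needs at least one accepted set")
    rows = []
    for m in space.marginals:
        x = frame[m.name].to_numpy()
        width = m.hi - m.lo
        low = float(np.mean(x < m.lo + edge_frac * width))
        high = float(np.mean(x > m.hi - edge_frac * width))
        flagged = (low > mass_threshold) or (high > mass_threshold)
        lo_new, hi_new = m.lo, m.hi
        if low > mass_threshold:
            lo_new = m.lo - 0.5 * width
        if high > mass_threshold:
            hi_new = m.hi + 0.5 * width
        rows.append({"name": m.name, "frac_lower_edge": low,
                     "frac_upper_edge": high, "flagged": flagged,
                     "suggested_lo": lo_new, "suggested_hi": hi_new})
    return pd.DataFrame(rows)


_STAB_MEASURES = ("total_oud", "detox_admissions", "fatal_overdoses")


def stability_check(result: CalibrationResult, fixed: FixedInputs,
                    subsample_sizes: Sequence[int], seed: int,
                    n_weeks: int = 156) -> pd.DataFrame:
    """Distributional stability of outputs under accepted-set subsampling.

    For each subsample size, re-simulates a random accepted subset and
    reports the Kolmogorov-Smirnov distance of each annual output against
    the full accepted set. Distances are expected to shrink (trend) as the
    subsample grows; stability above some size indicates the accepted
    sample is large enough.
    """
    if result.n_accepted == 0:
        raise ConfigError("stability check needs accepted sets")
    sizes = sorted(int(s) for s in subsample_sizes)
    if sizes[-1] > result.n_accepted:
        raise ConfigError("largest subsample exceeds the accepted count")
    rng = np.random.default_rng(seed)
    full = result.accepted_outputs
    rows = []
    for size in sizes:
        idx = rng.choice(result.n_accepted, size=size, replace=False)
        sub_out = run_simulation_batch(fixed, result.accepted_params.select(idx),
                                       n_weeks, check=False)
        for measure in _STAB_MEASURES:
            for yi, year in enumerate(full.years):
                a = getattr(full, measure) if measure != "total_oud" else full.total_oud
                b = (getattr(sub_out, measure) if measure != "total_oud"
                     else sub_out.total_oud)
                d = float(ks_2samp(a[:, yi], b[:, yi]).statistic)
                rows.append({"size": size, "measure": measure, "year": year,
                             "ks": d})
    return pd.DataFrame(rows)
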