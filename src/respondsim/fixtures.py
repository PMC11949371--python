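"""Synthetic default inputs (fixtures).

The model's real fixed inputs derive from non-public linked administrative
data (state health data warehouse, national survey, census, clinical-trial
toxicology). This module generates structurally faithful *synthetic*
stand-ins -- correct stratification, plausible magnitudes -- so the whole
pipeline builds, runs and tests without any download. Only the calibration
target values and the prior bounds reproduce published numbers; everything
else is a labelled synthetic fixture.

Magnitude constants below were fixed once so that, at the midpoints of the
calibrated-parameter priors, the simulated 2015 total OUD count, yearly
detox admissions and yearly fatal overdoses land near their targets --
otherwise the priors could not reach the target windows and the end-to-end
calibration demo would accept nothing. The constants are frozen and
recorded in the bundle manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .calibration import TargetSpec
from .errors import ConfigError
from .inputs import CalibratedInputs, FixedInputs
from .space import MarginalSpec, ParameterSpace, canonical_names
from .strata import MOUDS, StrataConfig, TRANSITION_LABELS

YEARS = (2013, 2014, 2015)

# -- published target values (calibration targets table) ----------------------

TOTAL_OUD_POINTS = {2013: 226861.0, 2014: 233184.0, 2015: 275070.0}
TOTAL_OUD_CI = {2013: (222242.0, 231285.0), 2014: (228680.0, 237514.0),
                2015: (272707.0, 277402.0)}
FATAL_POINTS = {2013: 900.0, 2014: 1294.0, 2015: 1562.0}
DETOX_POINTS = {2013: 39635.0, 2014: 41229.0, 2015: 38329.0}

# -- published prior bounds (calibration parameters table) --------------------

ARRIVAL_BOUNDS = {2013: (6.0, 406.0), 2014: (7.0, 307.0), 2015: (356.0, 1356.0)}
ETA_BOUNDS = {2013: (1.0, 2.0), 2014: (1.25, 2.5), 2015: (1.0, 2.0)}
M_N_BOUNDS = (0.75, 1.75)
M_P_BOUNDS = (1.0, 4.0)
GAMMA_P_BOUNDS = (0.0, 1.0)

# -- frozen synthetic magnitudes (tuned once; see module docstring) -----------

#: total alive population at the start of 2013
INIT_TOTAL = 223460.0
#: share of the initial population in treatment (rest in no-treatment)
INIT_T_SHARE = 0.05
#: split of initial treatment occupancy across bup/ntx/met/detox
INIT_T_SPLIT = (0.30, 0.08, 0.55, 0.07)
#: population-mean baseline weekly overall overdose rate o(t), per year
OD_SCALE = (0.00088179, 0.00084208, 0.00078422)
#: population-mean baseline weekly detox entry rate (before eta)
LAMBDA_ND_SCALE = 0.00214553
#: population-mean weekly other-cause death rate (before group factors)
BETA_SCALE = 0.00040455
#: mean active->non-active ("a"/"e") and relapse ("c"/"g") weekly
#: probabilities in no-treatment; relapse carries an age gradient
RHO_N_EXIT_MEAN = 0.013
RHO_N_RELAPSE_MEAN = 0.040787
#: post-treatment relapse mean; the relapse edges run much faster than in
#: no-treatment (rapid relapse after treatment dropout)
RHO_P_EXIT_MEAN = 0.020
RHO_P_RELAPSE_MEAN = 0.504339
#: cross-route edge means (b, d, f, h) in both no- and post-treatment
RHO_CROSS_MEAN = 0.004
#: prior Beta effective sample sizes (a+b): transition priors pooled from
#: published weekly-transition estimates; f(t) priors from an observed
#: overdose count of ~13k/yr treated as a binomial proportion estimate
RHO_ESS = 2000.0
F_ESS = 13000.0
#: prior means of the yearly fatal overdose proportion f(t)
F_MEANS = (0.070, 0.100, 0.115)
#: treatment overdose multiplier priors (weakly informative stand-ins)
M_T_SHAPES = {"bup": (8.0, 16.0), "ntx": (12.0, 12.0), "met": (6.0, 18.0)}

#: age gradients sampled at band midpoints (piecewise-linear controls)
_AGE_CTRL = (20.0, 30.0, 45.0, 77.5)
_PROFILES = {
    "init_age": (0.25, 0.35, 0.28, 0.12),
    "arrival_age": (0.35, 0.34, 0.23, 0.08),
    "od_age": (1.10, 1.40, 0.90, 0.45),
    "entry_age": (1.20, 1.30, 0.90, 0.50),
    "beta_age": (0.28, 0.52, 1.06, 3.80),
    "relapse_age": (1.15, 1.05, 0.95, 0.85),
}
_SEX_FACTORS = {
    "init": (0.62, 0.38), "arrival": (0.62, 0.38),
    "od": (1.25, 0.75), "entry": (1.10, 0.90), "beta": (1.15, 0.85),
}

#: other fixed structural choices
ARRIVAL_INJ_SHARE = 0.30
INJ_OD_RATIO = 2.0
LAMBDA_MOUD_BASE = (0.0009, 0.0002, 0.0008)  # bup, ntx, met weekly entry
LAMBDA_TP = (0.050, 0.080, 0.025, 0.60)      # bup, ntx, met, detox exits
LAMBDA_PN = float(-np.log(1 - 0.25))         # ~0.29
GAMMA_T = (0.30, 0.25)                       # keep-state prob: noninj, inj
BETA_GROUP = (1.05, 0.65, 1.00)              # N, T, P factors
#: weekly OUD transition probabilities a..h inside each medication
RHO_T = {
    "bup": (0.060, 0.003, 0.020, 0.003, 0.060, 0.003, 0.020, 0.003),
    "ntx": (0.050, 0.003, 0.025, 0.003, 0.050, 0.003, 0.025, 0.003),
    "met": (0.070, 0.003, 0.015, 0.003, 0.070, 0.003, 0.015, 0.003),
}
#: OUD-state split of initial occupancy
INIT_OUD_SPLIT_N = (0.543, 0.157, 0.233, 0.067)
INIT_OUD_SPLIT_T = (0.175, 0.525, 0.075, 0.225)
INIT_OUD_SPLIT_DETOX = (0.0, 0.70, 0.0, 0.30)

#: synthetic observed all-overdose counts standing in for the (non-public)
#: administrative series used by the under-reporting face-validity check
OBSERVED_OVERDOSES = {2013: 11500.0, 2014: 14200.0, 2015: 15100.0}


def _age_profile(strata: StrataConfig, key: str) -> np.ndarray:
    return np.interp(strata.age_midpoints, _AGE_CTRL, _PROFILES[key])


def _sex_profile(strata: StrataConfig, key: str) -> np.ndarray:
    f = _SEX_FACTORS[key]
    return np.array([f[k % len(f)] for k in range(strata.n_sex)], dtype=float)


def _dist(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Outer-product distribution normalized to sum 1, shape (J, K)."""
    g = np.outer(age, sex)
    return g / g.sum()


def _rate_field(strata: StrataConfig, mean: float, age_key: str, sex_key: str,
                weights: np.ndarray) -> np.ndarray:
    """Stratified rate with population-weighted mean equal to ``mean``."""
    g = np.outer(_age_profile(strata, age_key), _sex_profile(strata, sex_key))
    return mean * g / float((g * weights).sum())


def default_strata() -> StrataConfig:
    return StrataConfig()


def default_fixed_inputs(strata: StrataConfig | None = None,
                         seed: int = 0) -> FixedInputs:
    """Deterministic synthetic fixed inputs for the given stratification.

    The same seed always yields the same bundle (the defaults are in fact
    seed-independent constants; the seed is recorded for provenance).
    """
    strata = strata or default_strata()
    J, K = strata.shape
    init_dist = _dist(_age_profile(strata, "init_age"), _sex_profile(strata, "init"))
    arr_dist = _dist(_age_profile(strata, "arrival_age"), _sex_profile(strata, "arrival"))

    n_total = INIT_TOTAL * (1 - INIT_T_SHARE)
    t_total = INIT_TOTAL * INIT_T_SHARE
    n0 = n_total * np.asarray(INIT_OUD_SPLIT_N)[:, None, None] * init_dist[None]
    t0 = np.empty((4, 4, J, K))
    for d, share in enumerate(INIT_T_SPLIT):
        split = INIT_OUD_SPLIT_DETOX if d == 3 else INIT_OUD_SPLIT_T
        t0[d] = t_total * share * np.asarray(split)[:, None, None] * init_dist[None]
    p0 = np.zeros_like(t0)

    demo = np.broadcast_to(arr_dist, (len(YEARS), J, K)).copy()
    lambda_moud = np.stack([
        _rate_field(strata, base, "entry_age", "entry", init_dist)
        for base in LAMBDA_MOUD_BASE])
    lambda_detox = _rate_field(strata, LAMBDA_ND_SCALE, "entry_age", "entry",
                               init_dist)
    baseline_od = np.stack([
        _rate_field(strata, s, "od_age", "od", init_dist) for s in OD_SCALE])
    beta_base = _rate_field(strata, BETA_SCALE, "beta_age", "beta", init_dist)

    split = np.array([1 - ARRIVAL_INJ_SHARE, 0.0, ARRIVAL_INJ_SHARE, 0.0])
    return FixedInputs(
        strata=strata, years=YEARS, n0=n0, t0=t0, p0=p0, demo_props=demo,
        arrival_oud_split=split, lambda_moud=lambda_moud,
        lambda_detox_base=lambda_detox, lambda_tp=np.asarray(LAMBDA_TP),
        lambda_pn=LAMBDA_PN, gamma_t=np.asarray(GAMMA_T),
        rho_t=np.array([RHO_T[m] for m in MOUDS]), baseline_od=baseline_od,
        inj_od_ratio=INJ_OD_RATIO, beta_n=BETA_GROUP[0] * beta_base,
        beta_t=BETA_GROUP[1] * beta_base, beta_p=BETA_GROUP[2] * beta_base)


def _beta_shapes(mean: float, ess: float) -> tuple:
    return mean * ess, (1 - mean) * ess


def _rho_marginals(which: str, strata: StrataConfig) -> List[MarginalSpec]:
    exit_mean = RHO_N_EXIT_MEAN if which == "rho_n" else RHO_P_EXIT_MEAN
    relapse_mean = RHO_N_RELAPSE_MEAN if which == "rho_n" else RHO_P_RELAPSE_MEAN
    grad = _age_profile(strata, "relapse_age")
    out = []
    for lab in TRANSITION_LABELS:
        for j in range(strata.n_age):
            if lab in ("a", "e"):
                mean = exit_mean
            elif lab in ("c", "g"):
                mean = relapse_mean * grad[j]
            else:
                mean = RHO_CROSS_MEAN
            a, b = _beta_shapes(mean, RHO_ESS)
            out.append(MarginalSpec(f"{which}.{lab}.age{j}", "beta", 0.0, 1.0,
                                    a, b))
    return out


def default_parameter_space(strata: StrataConfig | None = None) -> ParameterSpace:
    """Prior marginals of every calibrated scalar (published uniform bounds;
    documented stand-in Beta shapes where the published shapes are not)."""
    strata = strata or default_strata()
    ms: List[MarginalSpec] = []
    for y in YEARS:
        lo, hi = ARRIVAL_BOUNDS[y]
        ms.append(MarginalSpec(f"arrivals.{y}", "uniform", lo, hi))
    for y in YEARS:
        lo, hi = ETA_BOUNDS[y]
        ms.append(MarginalSpec(f"eta.{y}", "uniform", lo, hi))
    for route in ("noninj", "inj"):
        ms.append(MarginalSpec(f"gamma_p.{route}", "uniform", *GAMMA_P_BOUNDS))
    ms.append(MarginalSpec("m_n", "uniform", *M_N_BOUNDS))
    for m in MOUDS:
        a, b = M_T_SHAPES[m]
        ms.append(MarginalSpec(f"m_t.{m}", "beta", 0.0, 1.0, a, b))
    ms.append(MarginalSpec("m_p", "uniform", *M_P_BOUNDS))
    for y, mean in zip(YEARS, F_MEANS):
        a, b = _beta_shapes(mean, F_ESS)
        ms.append(MarginalSpec(f"f.{y}", "beta", 0.0, 1.0, a, b))
    ms += _rho_marginals("rho_n", strata)
    ms += _rho_marginals("rho_p", strata)
    space = ParameterSpace(ms)
    # order to the canonical layout
    order = canonical_names(strata, YEARS)
    by_name = {m.name: m for m in space.marginals}
    return ParameterSpace([by_name[n] for n in order])


def default_targets() -> List[TargetSpec]:
    """The nine published target values with their window rules: the 2015
    total OUD count uses its 95% CI; detox and fatal counts use +/-10%
    windows; the 2013-14 total OUD counts enter only the trend constraint."""
    out = []
    for y in YEARS:
        rule = "ci" if y == 2015 else "trend_only"
        lo, hi = TOTAL_OUD_CI[y]
        out.append(TargetSpec(f"total_oud:{y}", "total_oud", y,
                              TOTAL_OUD_POINTS[y], rule, lo, hi))
    for y in YEARS:
        out.append(TargetSpec(f"detox:{y}", "detox", y, DETOX_POINTS[y], "pct10"))
    for y in YEARS:
        out.append(TargetSpec(f"fatal:{y}", "fatal", y, FATAL_POINTS[y], "pct10"))
    return out


def midpoint_inputs(space: ParameterSpace, strata: StrataConfig | None = None
                    ) -> CalibratedInputs:
    """CalibratedInputs at every prior's mean (midpoint for uniforms)."""
    strata = strata or default_strata()
    from .space import DesignMatrix, design_to_batch
    values = np.array([[m.mean for m in space.marginals]])
    design = DesignMatrix(values, space.names)
    return design_to_batch(design, strata, YEARS).item(0)


@dataclass
class FixtureBundle:
    """Everything needed to run the pipeline with no external data."""

    fixed: FixedInputs
    space: ParameterSpace
    targets: List[TargetSpec]
    observed_overdoses: Dict[int, float]
    seed: int
    manifest: Dict[str, object] = field(default_factory=dict)


def build_default_bundle(seed: int = 0,
                         strata: StrataConfig | None = None) -> FixtureBundle:
    strata = strata or default_strata()
    manifest = {
        "provenance": {
            "targets": "published calibration-target table",
            "prior_bounds": "published calibration-parameter table",
            "everything_else": "synthetic fixture (structural stand-in)",
        },
        "tuning_constants": {
            "init_total": INIT_TOTAL, "od_scale": list(OD_SCALE),
            "lambda_nd_scale": LAMBDA_ND_SCALE, "beta_scale": BETA_SCALE,
            "f_means": list(F_MEANS), "f_ess": F_ESS, "rho_ess": RHO_ESS,
            "rho_n_relapse_mean": RHO_N_RELAPSE_MEAN,
            "rho_p_relapse_mean": RHO_P_RELAPSE_MEAN,
        },
        "seed": seed,
    }
    return FixtureBundle(
        fixed=default_fixed_inputs(strata, seed),
        space=default_parameter_space(strata),
        targets=default_targets(),
        observed_overdoses=dict(OBSERVED_OVERDOSES),
        seed=seed, manifest=manifest)


def fixture_self_check(bundle: FixtureBundle) -> dict:
    """Midpoint sanity check: at prior means the simulated 2015 total OUD
    count must land within a factor of 2 of the 275070 target (guaranteeing
    the calibration demo is non-degenerate). Returns the midpoint outputs."""
    from .core import run_simulation
    mid = midpoint_inputs(bundle.space, bundle.fixed.strata)
    out = run_simulation(bundle.fixed, mid)
    total_2015 = float(out.total_oud[-1])
    ratio = total_2015 / TOTAL_OUD_POINTS[2015]
    if not 0.5 <= ratio <= 2.0:
        raise ConfigError(
            f"fixture self-check failed: midpoint 2015 total OUD {total_2015:.0f} "
            f"is off the target by more than a factor 2")
    return {
        "total_oud": out.total_oud, "detox_admissions": out.detox_admissions,
        "fatal_overdoses": out.fatal_overdoses,
        "other_deaths": out.other_deaths, "all_overdoses": out.all_overdoses,
        "active_pct": out.active_pct, "active_pct_group": out.active_pct_group,
    }
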