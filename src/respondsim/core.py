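"""Deterministic weekly-cycle cohort simulator.

The model advances expected occupancy counts of an opioid use disorder
(OUD) cohort through a weekly cycle. Each week, in a fixed order:

1. new arrivals enter the no-treatment state;
2. other-cause (non-overdose) mortality removes people at SMR-adjusted
   life-table rates;
3. overdose events occur in active-use states; a yearly fatal proportion
   ``f(t)`` of the pooled overdoses is fatal and removed, allocated to
   states in proportion to each state's overdose contribution; survivors
   remain in place;
4. health-state transitions: no-treatment -> each treatment (rate
   ``lambda_NT``; detox scaled by the calibrated ``eta(t)``), treatment ->
   post-treatment (``lambda_TP``), post-treatment -> no-treatment
   (``lambda_PN``), with initiation effects applied to entrants;
5. within-state OUD transitions via the 4x4 weekly matrices.

All rates are converted to probabilities with ``p = 1 - exp(-r t)``
(Poisson assumption); competing exits from one state are renormalized
multinomially, ``p_i = (r_i / R)(1 - exp(-R t))``.

The engine is vectorized over a batch of candidate calibrated-parameter
sets (leading axis ``B``), which is what makes rejection calibration with
1e5+ Latin hypercube samples tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .inputs import CalibratedBatch, CalibratedInputs, FixedInputs, as_batch
from .strata import (
    ACTIVE,
    AI,
    ANI,
    HEALTH_GROUPS,
    IDX_N,
    IDX_T_DETOX,
    N_HEALTH,
    N_OUD,
    N_TREAT,
    NAI,
    NANI,
    build_oud_matrix,
    detox_oud_matrix,
)

CONSERVATION_RTOL = 1e-9

# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def rate_to_prob(rate, dt: float = 1.0):
    """Convert a constant event rate to an event probability over ``dt``.

    Assumes a Poisson process: ``p = 1 - exp(-rate * dt)``.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ConfigError("rate must be nonnegative")
    if not dt > 0:
        raise ConfigError("dt must be positive")
    out = -np.expm1(-rate * dt)
    return float(out) if out.ndim == 0 else out


def prob_to_rate(p, dt: float = 1.0):
    """Inverse of :func:`rate_to_prob`: ``r = -ln(1-p) / dt``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ConfigError("probability must lie in [0, 1)")
    if not dt > 0:
        raise ConfigError("dt must be positive")
    out = -np.log1p(-p) / dt
    return float(out) if out.ndim == 0 else out


def compute_arrivals(a_t: float, demo_props: np.ndarray,
                     arrival_oud_split: np.ndarray) -> np.ndarray:
    """Stratify one week's total arrivals ``A(t)`` into ``(oud, age, sex)``
    counts entering the no-treatment state: ``alpha_jk = A(t) * p_jk``."""
    if a_t < 0:
        raise ConfigError("arrivals must be nonnegative")
    demo = np.asarray(demo_props, dtype=float)
    split = np.asarray(arrival_oud_split, dtype=float)
    if abs(demo.sum() - 1.0) > 1e-9 or abs(split.sum() - 1.0) > 1e-9:
        raise ConfigError("arrival proportions must sum to 1")
    return a_t * split[:, None, None] * demo[None, :, :]


def detox_entry_rate(lambda_bar_nd: np.ndarray, eta_t: float) -> np.ndarray:
    """Detox entry rate ``lambda_ND(t) = lambda_bar_ND * eta(t)``."""
    if not eta_t > 0:
        raise ConfigError("eta must be positive")
    return np.asarray(lambda_bar_nd, dtype=float) * eta_t


def overdose_rates(baseline_od: np.ndarray, m_n: float, m_t: np.ndarray,
                   m_p: float, inj_od_ratio: float = 2.0) -> np.ndarray:
    """Per-health-state, per-OUD-state weekly overdose rates.

    ``nu_N = o(t) * m_N``; ``nu_T = nu_N * m_T`` per medication; detox has
    rate zero; ``nu_P = nu_N * m_P``. Rates apply only to active states,
    with active-injection risk ``inj_od_ratio`` times active-non-injection.
    Returns an array of shape ``(9, 4, n_age, n_sex)``.
    """
    m_t = np.asarray(m_t, dtype=float)
    if not m_n > 0:
        raise ConfigError("m_n must be positive")
    if np.any((m_t < 0) | (m_t > 1)):
        raise ConfigError("m_t must lie in [0, 1]")
    if not m_p >= 1:
        raise ConfigError("m_p must be > 1 (boundary value 1 allowed for checks)")
    base = np.asarray(baseline_od, dtype=float)
    mult = np.concatenate([[m_n], m_n * m_t, [0.0], m_n * m_p * np.ones(4)])
    act = np.array([1.0, 0.0, inj_od_ratio, 0.0])
    return mult[:, None, None, None] * act[None, :, None, None] * base[None, None]


def split_fatal(overdoses: np.ndarray, f_t: float):
    """Split pooled overdoses into fatal and surviving.

    The yearly fatal proportion applies to the *pooled* overdose count; the
    fatal total is allocated back to the contributing states proportionally
    to each state's contribution (which is equivalent to scaling every
    state's count by ``f_t``). Returns ``(fatal_total, fatal_by_state)``.
    """
    if not 0 <= f_t <= 1:
        raise ConfigError("fatal proportion must lie in [0, 1]")
    od = np.asarray(overdoses, dtype=float)
    fatal = od * f_t
    return float(od.sum() * f_t), fatal


def apply_initiation_effect(flow: np.ndarray, gamma, detox: bool = False) -> np.ndarray:
    """Redistribute entrants at treatment (or post-treatment) initiation.

    Active entrants keep their active state with probability ``gamma`` for
    their route (noninj, inj), else drop to the matching non-active state.
    Non-active entrants are unchanged. Detox entry forces everyone
    non-active regardless of ``gamma``. ``flow`` has the OUD axis first.
    """
    flow = np.asarray(flow, dtype=float)
    out = flow.copy()
    if detox:
        out[NANI] = flow[NANI] + flow[ANI]
        out[NAI] = flow[NAI] + flow[AI]
        out[ANI] = 0.0
        out[AI] = 0.0
        return out
    g = np.asarray(gamma, dtype=float)
    if g.shape != (2,) or np.any((g < 0) | (g > 1)):
        raise ConfigError("gamma must be two probabilities (noninj, inj)")
    out[ANI] = flow[ANI] * g[0]
    out[NANI] = flow[NANI] + flow[ANI] * (1 - g[0])
    out[AI] = flow[AI] * g[1]
    out[NAI] = flow[NAI] + flow[AI] * (1 - g[1])
    return out


def _initiation_batch(flow: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Batched initiation effect; flow (B, S, J, K), gamma (B, 2) or (2,)."""
    g = np.asarray(gamma, dtype=float)
    if g.ndim == 1:
        g = np.broadcast_to(g, (flow.shape[0], 2))
    g_ni = g[:, 0][:, None, None]
    g_in = g[:, 1][:, None, None]
    out = np.empty_like(flow)
    out[:, ANI] = flow[:, ANI] * g_ni
    out[:, NANI] = flow[:, NANI] + flow[:, ANI] * (1 - g_ni)
    out[:, AI] = flow[:, AI] * g_in
    out[:, NAI] = flow[:, NAI] + flow[:, AI] * (1 - g_in)
    return out


def _initiation_detox_batch(flow: np.ndarray) -> np.ndarray:
    out = np.zeros_like(flow)
    out[:, NANI] = flow[:, NANI] + flow[:, ANI]
    out[:, NAI] = flow[:, NAI] + flow[:, AI]
    return out


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class _Precomputed:
    """Week-invariant arrays derived from FixedInputs."""

    def __init__(self, fx: FixedInputs):
        J, K = fx.strata.shape
        ny = fx.n_years
        p_beta = np.empty((N_HEALTH, 1, J, K))
        p_beta[0, 0] = rate_to_prob(fx.beta_n)
        p_beta[1:5, 0] = rate_to_prob(fx.beta_t)[None]
        p_beta[5:9, 0] = rate_to_prob(fx.beta_p)[None]
        self.p_beta = p_beta  # (H, 1, J, K), broadcasts over OUD axis
        self.surv_beta = 1.0 - p_beta

        act = np.array([1.0, 0.0, fx.inj_od_ratio, 0.0])
        # (Y, S, J, K): baseline overdose rate by activity
        self.base_act = act[None, :, None, None] * fx.baseline_od[:, None, :, :]
        # (Y, S, J, K): arrival pattern; multiplied by A(t) per candidate
        self.arrival_pattern = (fx.arrival_oud_split[None, :, None, None]
                                * fx.demo_props[:, None, :, :])
        self.m_detox = detox_oud_matrix()
        self.m_t = build_oud_matrix(fx.rho_t)  # (3, 4, 4)
        self.p_tp = rate_to_prob(fx.lambda_tp)  # (4,)
        self.p_pn = rate_to_prob(fx.lambda_pn)


class _BatchPre:
    """Week-invariant arrays derived from one candidate batch."""

    def __init__(self, fx: FixedInputs, cb: CalibratedBatch, pre: _Precomputed):
        B = cb.size
        self.m_n_mat = build_oud_matrix(cb.rho_n)  # (B, J, 4, 4)
        self.m_p_mat = build_oud_matrix(cb.rho_p)
        m_state = np.zeros((B, N_HEALTH))
        m_state[:, 0] = cb.m_n
        m_state[:, 1:4] = cb.m_n[:, None] * cb.m_t
        m_state[:, 4] = 0.0  # no overdoses in detox
        m_state[:, 5:9] = (cb.m_n * cb.m_p)[:, None]
        # (Y, B, H, 2, J, K): weekly overdose probability in the two active
        # OUD states (ANI, AI); non-active states carry no overdose risk
        base_active = pre.base_act[:, ::2]  # (Y, 2, J, K)
        self.p_od = -np.expm1(
            -base_active[:, None, None] * m_state[None, :, :, None, None, None])


def initial_cohort(fx: FixedInputs, batch_size: int = 1) -> np.ndarray:
    """Starting occupancy tensor, shape (B, health, oud, age, sex)."""
    J, K = fx.strata.shape
    cohort = np.zeros((batch_size, N_HEALTH, N_OUD, J, K))
    cohort[:, 0] = fx.n0[None]
    cohort[:, 1:5] = fx.t0[None]
    cohort[:, 5:9] = fx.p0[None]
    return cohort


def _competing_exit_probs(rates: np.ndarray, axis: int = 1) -> np.ndarray:
    """Multinomial renormalization of competing exit rates over ``axis``:
    ``p_i = (r_i / R)(1 - exp(-R))`` with the R -> 0 limit ``p_i = r_i``."""
    total = rates.sum(axis=axis, keepdims=True)
    scale = np.ones_like(total)
    nz = total > 0
    scale[nz] = -np.expm1(-total[nz]) / total[nz]
    return rates * scale


def step_week_batch(cohort: np.ndarray, fx: FixedInputs, cb: CalibratedBatch,
                    week: int, pre: Optional[_Precomputed] = None,
                    batch_pre: Optional[_BatchPre] = None,
                    check: bool = True):
    """Advance a batch cohort tensor one week in place.

    Returns ``(cohort, ledger)`` where ledger maps measure name to a
    ``(B,)`` array (plus ``overdoses_by_health`` of shape ``(B, 9)``).
    """
    if pre is None:
        pre = _Precomputed(fx)
    if batch_pre is None:
        batch_pre = _BatchPre(fx, cb, pre)
    y = fx.year_index(week)
    B = cohort.shape[0]
    start_total = cohort.sum(axis=(1, 2, 3, 4))

    # 1. arrivals into no-treatment
    arrivals = cb.arrivals[:, y]
    cohort[:, IDX_N] += arrivals[:, None, None, None] * pre.arrival_pattern[y][None]

    # 2. other-cause mortality (death probability has no OUD-state axis)
    occ_h = cohort.sum(axis=2)  # (B, H, J, K)
    other = (occ_h * pre.p_beta[None, :, 0]).sum(axis=(1, 2, 3))
    cohort *= pre.surv_beta[None]

    # 3. overdoses and fatal removals; only active states (ANI, AI) at risk
    active_view = cohort[:, :, ::2]  # (B, H, 2, J, K) view onto ANI/AI
    od = active_view * batch_pre.p_od[y]
    od_by_health = od.sum(axis=(2, 3, 4))  # (B, H)
    od_total = od_by_health.sum(axis=1)
    f_t = cb.f[:, y]
    active_view -= od * f_t[:, None, None, None, None]
    fatal = od_total * f_t

    # 4a. no-treatment -> treatments (competing exits)
    J, K = fx.strata.shape
    r = np.empty((B, N_TREAT, J, K))
    r[:, :3] = fx.lambda_moud[None]
    r[:, 3] = fx.lambda_detox_base[None] * cb.eta[:, y, None, None]
    p_exit = _competing_exit_probs(r, axis=1)  # (B, 4, J, K)
    flows_nt = cohort[:, IDX_N][:, None] * p_exit[:, :, None]  # (B, 4, S, J, K)
    cohort[:, IDX_N] -= flows_nt.sum(axis=1)
    for d in range(3):
        cohort[:, 1 + d] += _initiation_batch(flows_nt[:, d], fx.gamma_t)
    cohort[:, IDX_T_DETOX] += _initiation_detox_batch(flows_nt[:, 3])
    detox_entries = flows_nt[:, 3].sum(axis=(1, 2, 3))

    # 4b. treatments -> post-treatments
    flows_tp = cohort[:, 1:5] * pre.p_tp[None, :, None, None, None]
    cohort[:, 1:5] -= flows_tp
    for d in range(4):
        cohort[:, 5 + d] += _initiation_batch(flows_tp[:, d], cb.gamma_p)

    # 4c. post-treatments -> no-treatment (no initiation effect entering N)
    flows_pn = cohort[:, 5:9] * pre.p_pn
    cohort[:, 5:9] -= flows_pn
    cohort[:, IDX_N] += flows_pn.sum(axis=1)

    # 5. within-state OUD transitions
    cohort[:, 0] = np.einsum("bsjk,bjst->btjk", cohort[:, 0], batch_pre.m_n_mat)
    cohort[:, 1:4] = np.einsum("bdsjk,dst->bdtjk", cohort[:, 1:4], pre.m_t)
    cohort[:, 4] = np.einsum("bsjk,st->btjk", cohort[:, 4], pre.m_detox)
    cohort[:, 5:9] = np.einsum("bdsjk,bjst->bdtjk", cohort[:, 5:9],
                               batch_pre.m_p_mat)

    if check:
        end_total = cohort.sum(axis=(1, 2, 3, 4))
        expected = start_total + arrivals - other - fatal
        scale = np.maximum(np.abs(expected), 1.0)
        if np.any(np.abs(end_total - expected) > CONSERVATION_RTOL * scale * 100):
            raise IntegrityError("population conservation violated in weekly cycle")
        mn = cohort.min()
        if mn < -1e-6:
            raise IntegrityError(f"negative occupancy after update ({mn:g})")
        if mn < 0:
            np.maximum(cohort, 0.0, out=cohort)

    ledger = {
        "arrivals": arrivals.astype(float).copy(),
        "other_deaths": other,
        "overdoses": od_total,
        "fatal_overdoses": fatal,
        "detox_entries": detox_entries,
        "overdoses_by_health": od_by_health,
    }
    return cohort, ledger


def step_week(cohort: np.ndarray, fx: FixedInputs, calib: CalibratedInputs,
              week: int):
    """Single-candidate weekly step.

    ``cohort`` has shape (9, 4, n_age, n_sex). Returns the new cohort and a
    ledger of scalar flow counts for the cycle.
    """
    batch = as_batch(calib)
    c = np.asarray(cohort, dtype=float)[None].copy()
    c, ledger = step_week_batch(c, fx, batch, week)
    scalar = {k: float(v[0]) for k, v in ledger.items() if v.ndim == 1}
    scalar["overdoses_by_health"] = ledger["overdoses_by_health"][0]
    return c[0], scalar


@dataclass
class AnnualOutputsBatch:
    """Annual aggregate outputs for a batch of candidates; arrays (B, Y)."""

    years: tuple
    alive: np.ndarray
    fatal_overdoses: np.ndarray
    other_deaths: np.ndarray
    detox_admissions: np.ndarray
    all_overdoses: np.ndarray
    active_pct: np.ndarray           # year-end overall active-use %, (B, Y)
    active_pct_group: np.ndarray     # (B, Y, 3): no-treatment, treatment, post

    @property
    def total_oud(self) -> np.ndarray:
        """Total OUD count = alive at year end + that year's fatal overdoses
        + that year's other-cause deaths."""
        return self.alive + self.fatal_overdoses + self.other_deaths

    @property
    def size(self) -> int:
        return self.alive.shape[0]

    def select(self, idx) -> "AnnualOutputsBatch":
        return AnnualOutputsBatch(
            self.years, self.alive[idx], self.fatal_overdoses[idx],
            self.other_deaths[idx], self.detox_admissions[idx],
            self.all_overdoses[idx], self.active_pct[idx],
            self.active_pct_group[idx])

    def item(self, i: int) -> "AnnualOutputs":
        return AnnualOutputs(
            self.years, self.alive[i], self.fatal_overdoses[i],
            self.other_deaths[i], self.detox_admissions[i],
            self.all_overdoses[i], self.active_pct[i], self.active_pct_group[i])

    def year_col(self, measure: str, year: int) -> np.ndarray:
        arr = getattr(self, measure) if measure != "total_oud" else self.total_oud
        return arr[:, self.years.index(year)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long DataFrame: candidate, year, measure, value."""
        rows = []
        measures = {
            "alive": self.alive, "fatal_overdoses": self.fatal_overdoses,
            "other_deaths": self.other_deaths,
            "detox_admissions": self.detox_admissions,
            "all_overdoses": self.all_overdoses, "total_oud": self.total_oud,
            "active_pct": self.active_pct,
        }
        for m, arr in measures.items():
            for yi, year in enumerate(self.years):
                rows.append(pd.DataFrame({
                    "candidate": np.arange(arr.shape[0]), "year": year,
                    "measure": m, "group": "all", "value": arr[:, yi]}))
        for gi, g in enumerate(HEALTH_GROUPS):
            for yi, year in enumerate(self.years):
                rows.append(pd.DataFrame({
                    "candidate": np.arange(self.active_pct_group.shape[0]),
                    "year": year, "measure": "active_pct", "group": g,
                    "value": self.active_pct_group[:, yi, gi]}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class AnnualOutputs(AnnualOutputsBatch):
    """Annual outputs for one candidate; arrays (Y,)."""

    def to_frame(self) -> pd.DataFrame:  # pragma: no cover - thin convenience
        batch = AnnualOutputsBatch(
            self.years, self.alive[None], self.fatal_overdoses[None],
            self.other_deaths[None], self.detox_admissions[None],
            self.all_overdoses[None], self.active_pct[None],
            self.active_pct_group[None])
        return batch.to_frame().drop(columns="candidate")


def _active_percentages(cohort: np.ndarray):
    """Year-end active-use percentages, overall and by health-state group."""
    active = cohort[:, :, ACTIVE].sum(axis=(2, 3, 4))  # (B, H)
    total = cohort.sum(axis=(2, 3, 4))                 # (B, H)
    groups = [(0, 1), (1, 5), (5, 9)]
    tot_all = total.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        overall = np.where(tot_all > 0,
                           100.0 * active.sum(axis=1) / tot_all, 0.0)
        by_group = np.stack([
            np.where(total[:, a:b].sum(1) > 0,
                     100.0 * active[:, a:b].sum(1) / total[:, a:b].sum(1), 0.0)
            for a, b in groups], axis=1)
    return overall, by_group


def run_simulation_batch(fx: FixedInputs, calib, n_weeks: int = 156,
                         check: bool = True) -> AnnualOutputsBatch:
    """Run the weekly cycle for a batch of calibrated-parameter sets and
    aggregate weekly ledgers into calendar years."""
    cb = as_batch(calib)
    if n_weeks % 52 != 0:
        raise ConfigError("n_weeks must be a multiple of 52")
    ny = n_weeks // 52
    if ny > fx.n_years:
        raise ConfigError("horizon exceeds years covered by yearly parameters")
    B = cb.size
    pre = _Precomputed(fx)
    batch_pre = _BatchPre(fx, cb, pre)
    cohort = initial_cohort(fx, B)

    zeros = lambda: np.zeros((B, ny))
    fatal, other, detox, od = zeros(), zeros(), zeros(), zeros()
    alive = zeros()
    active = zeros()
    active_group = np.zeros((B, ny, 3))

    for week in range(n_weeks):
        y = week // 52
        cohort, ledger = step_week_batch(cohort, fx, cb, week, pre, batch_pre,
                                         check=check)
        fatal[:, y] += ledger["fatal_overdoses"]
        other[:, y] += ledger["other_deaths"]
        detox[:, y] += ledger["detox_entries"]
        od[:, y] += ledger["overdoses"]
        if week % 52 == 51:
            alive[:, y] = cohort.sum(axis=(1, 2, 3, 4))
            active[:, y], active_group[:, y] = _active_percentages(cohort)

    years = tuple(fx.years[:ny])
    return AnnualOutputsBatch(years, alive, fatal, other, detox, od,
                              active, active_group)


def run_simulation(fx: FixedInputs, calib: CalibratedInputs,
                   n_weeks: int = 156) -> AnnualOutputs:
    """Single-candidate convenience wrapper around the batch engine."""
    out = run_simulation_batch(fx, as_batch(calib), n_weeks)
    return out.item(0)
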