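"""Independent individual-level Monte-Carlo oracle.

Simulates every person as an agent with Bernoulli/categorical draws, using
the same event order as the cohort engine but none of its code paths. On a
one-stratum toy the cohort model's deterministic outputs are expectations
of this process, so the two must agree within Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np

import respondsim as rs
from respondsim.strata import ANI, NANI, AI, NAI, StrataConfig, build_oud_matrix, detox_oud_matrix

NONACTIVE = {ANI: NANI, AI: NAI}


def toy_inputs(n0: float = 100000.0, arrivals: float = 30.0):
    """One-stratum toy with magnitudes in the fixture's plausible ranges."""
    strata = StrataConfig(age_band_edges=(15, 100), sexes=("all",))
    one = np.ones((1, 1))
    rho_row = (0.013, 0.004, 0.041, 0.004, 0.013, 0.004, 0.041, 0.004)
    fixed = rs.FixedInputs(
        strata=strata, years=(2013, 2014, 2015),
        n0=np.array([0.55, 0.15, 0.23, 0.07])[:, None, None] * n0 * one[None],
        t0=np.zeros((4, 4, 1, 1)), p0=np.zeros((4, 4, 1, 1)),
        demo_props=np.ones((3, 1, 1)),
        arrival_oud_split=np.array([0.7, 0.0, 0.3, 0.0]),
        lambda_moud=np.array([0.0009, 0.0002, 0.0008])[:, None, None] * one[None],
        lambda_detox_base=0.0021 * one,
        lambda_tp=np.array([0.05, 0.08, 0.025, 0.6]),
        lambda_pn=float(-np.log(0.75)),
        gamma_t=np.array([0.30, 0.25]),
        rho_t=np.array([
            (0.060, 0.003, 0.020, 0.003, 0.060, 0.003, 0.020, 0.003),
            (0.050, 0.003, 0.025, 0.003, 0.050, 0.003, 0.025, 0.003),
            (0.070, 0.003, 0.015, 0.003, 0.070, 0.003, 0.015, 0.003)]),
        baseline_od=0.0009 * np.ones((3, 1, 1)),
        inj_od_ratio=2.0,
        beta_n=0.00042 * one, beta_t=0.00028 * one, beta_p=0.00040 * one)
    calib = rs.CalibratedInputs(
        arrivals=np.full(3, arrivals), eta=np.array([1.5, 1.8, 1.5]),
        gamma_p=np.array([0.5, 0.4]),
        rho_n=np.array([rho_row]),
        rho_p=np.array([(0.020, 0.004, 0.50, 0.004, 0.020, 0.004, 0.50, 0.004)]),
        m_n=1.25, m_t=np.array([0.33, 0.5, 0.25]), m_p=2.5,
        f=np.array([0.07, 0.10, 0.115]))
    return fixed, calib


def run_microsim(fixed, calib, n_weeks: int, seed: int):
    """Agent-based run; returns aggregate tallies and final occupancy."""
    rng = np.random.default_rng(seed)
    n0_counts = np.round(fixed.n0[:, 0, 0]).astype(int)
    arrivals_per_week = int(round(float(calib.arrivals[0])))
    n_max = int(n0_counts.sum() + arrivals_per_week * n_weeks + 10)

    health = np.zeros(n_max, dtype=np.int8)   # all start in no-treatment
    oud = np.empty(n_max, dtype=np.int8)
    alive = np.zeros(n_max, dtype=bool)
    pos = 0
    for s, c in enumerate(n0_counts):
        oud[pos:pos + c] = s
        alive[pos:pos + c] = True
        pos += c

    # transition machinery mirroring the model's definitions, rebuilt
    # independently from the inputs
    m_all = np.empty((9, 4, 4))
    m_all[0] = build_oud_matrix(calib.rho_n[0])
    for d in range(3):
        m_all[1 + d] = build_oud_matrix(fixed.rho_t[d])
    m_all[4] = detox_oud_matrix()
    m_all[5:9] = build_oud_matrix(calib.rho_p[0])[None]

    p_beta = 1 - np.exp(-np.array(
        [fixed.beta_n[0, 0]] + [fixed.beta_t[0, 0]] * 4 + [fixed.beta_p[0, 0]] * 4))
    od_mult = np.array([calib.m_n, *(calib.m_n * calib.m_t), 0.0,
                        *(calib.m_n * calib.m_p * np.ones(4))])
    p_tp = 1 - np.exp(-fixed.lambda_tp)
    p_pn = 1 - np.exp(-fixed.lambda_pn)
    split_cum = np.cumsum(fixed.arrival_oud_split)

    tallies = {k: 0.0 for k in ("fatal", "other", "detox_entries", "overdoses")}

    def initiation(idx, gamma_ni, gamma_in, detox):
        o = oud[idx]
        if detox:
            oud[idx] = np.where(o == ANI, NANI, np.where(o == AI, NAI, o))
            return
        u = rng.random(idx.size)
        drop_ani = (o == ANI) & (u >= gamma_ni)
        drop_ai = (o == AI) & (u >= gamma_in)
        oud[idx[drop_ani]] = NANI
        oud[idx[drop_ai]] = NAI

    for week in range(n_weeks):
        y = week // 52
        # arrivals
        new = slice(pos, pos + arrivals_per_week)
        alive[new] = True
        health[new] = 0
        oud[new] = np.searchsorted(split_cum, rng.random(arrivals_per_week),
                                   side="right")
        pos += arrivals_per_week

        idx = np.flatnonzero(alive)
        # other-cause mortality
        die = rng.random(idx.size) < p_beta[health[idx]]
        alive[idx[die]] = False
        tallies["other"] += die.sum()

        idx = np.flatnonzero(alive)
        # overdoses in active states
        base = fixed.baseline_od[y, 0, 0]
        act = np.where(oud[idx] == ANI, 1.0,
                       np.where(oud[idx] == AI, fixed.inj_od_ratio, 0.0))
        p_od = 1 - np.exp(-base * od_mult[health[idx]] * act)
        od_event = rng.random(idx.size) < p_od
        tallies["overdoses"] += od_event.sum()
        fatal = od_event & (rng.random(idx.size) < calib.f[y])
        alive[idx[fatal]] = False
        tallies["fatal"] += fatal.sum()

        idx = np.flatnonzero(alive)
        # health-state transitions
        in_n = idx[health[idx] == 0]
        rates = np.array([*fixed.lambda_moud[:, 0, 0],
                          fixed.lambda_detox_base[0, 0] * calib.eta[y]])
        total = rates.sum()
        p_exit = rates / total * (1 - np.exp(-total))
        cum = np.cumsum(p_exit)
        u = rng.random(in_n.size)
        dest = np.searchsorted(cum, u, side="right")  # 4 = stay
        for d in range(4):
            movers = in_n[dest == d]
            if movers.size == 0:
                continue
            health[movers] = 1 + d
            if d == 3:
                tallies["detox_entries"] += movers.size
                initiation(movers, None, None, detox=True)
            else:
                initiation(movers, fixed.gamma_t[0], fixed.gamma_t[1], False)
        for d in range(4):
            in_t = idx[health[idx] == 1 + d]
            move = in_t[rng.random(in_t.size) < p_tp[d]]
            health[move] = 5 + d
            initiation(move, calib.gamma_p[0], calib.gamma_p[1], False)
        in_p = idx[(health[idx] >= 5)]
        move = in_p[rng.random(in_p.size) < p_pn]
        health[move] = 0

        # OUD-state transitions
        idx = np.flatnonzero(alive)
        rows = m_all[health[idx], oud[idx]]  # (n, 4) categorical rows
        u = rng.random(idx.size)
        oud[idx] = (u[:, None] >= np.cumsum(rows, axis=1)[:, :3]).sum(axis=1)

    idx = np.flatnonzero(alive)
    occ_health = np.bincount(health[idx], minlength=9).astype(float)
    occ_group = np.array([occ_health[0], occ_health[1:5].sum(),
                          occ_health[5:9].sum()])
    n_active = float(np.isin(oud[idx], (ANI, AI)).sum())
    return {
        "alive": float(idx.size), "n_active": n_active,
        "occ_group": occ_group, **{k: float(v) for k, v in tallies.items()},
    }


def cohort_expectations(fixed, calib, n_weeks: int):
    """Deterministic cohort-model aggregates over the same horizon."""
    cohort = rs.initial_cohort(fixed, 1)[0]
    tallies = {k: 0.0 for k in ("fatal", "other", "detox_entries", "overdoses")}
    for week in range(n_weeks):
        cohort, ledger = rs.step_week(cohort, fixed, calib, week)
        tallies["fatal"] += ledger["fatal_overdoses"]
        tallies["other"] += ledger["other_deaths"]
        tallies["detox_entries"] += ledger["detox_entries"]
        tallies["overdoses"] += ledger["overdoses"]
    occ_health = cohort.sum(axis=(1, 2, 3))
    occ_group = np.array([occ_health[0], occ_health[1:5].sum(),
                          occ_health[5:9].sum()])
    active = cohort[:, (ANI, AI)].sum()
    return {
        "alive": float(cohort.sum()), "n_active": float(active),
        "occ_group": occ_group, **tallies,
    }
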