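"""Input containers: fixed (non-calibrated) and calibrated model parameters.

``FixedInputs`` collects everything the model treats as known: initial
cohort, demographic arrival proportions, stratified treatment-entry rates,
in-treatment OUD transition probabilities, baseline overdose rates and
SMR-adjusted other-cause death rates. ``CalibratedInputs`` is a single point
of the calibrated-parameter space (arrivals, detox-rate multipliers,
post-treatment initiation effects, no-/post-treatment OUD transitions,
overdose multipliers, fatal overdose proportions). ``CalibratedBatch``
stacks many such points for vectorized simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .strata import (
    MOUDS,
    N_OUD,
    N_TREAT,
    ROUTES,
    StrataConfig,
    TRANSITION_LABELS,
    validate_stratified,
)

PROP_TOL = 1e-9  # tolerance for proportion sums


@dataclass
class FixedInputs:
    """All non-calibrated model parameters.

    Rates are weekly unless noted. Shapes use J = number of age bands,
    K = number of sexes, Y = number of calendar years simulated.

    Attributes
    ----------
    strata : StrataConfig
    years : tuple of int
        Calendar years covered by yearly-varying parameters.
    n0 : (4, J, K) array
        Initial no-treatment occupancy by OUD state.
    t0 : (4, 4, J, K) array
        Initial treatment occupancy by treatment type and OUD state.
    p0 : (4, 4, J, K) array
        Initial post-treatment occupancy; identically zero.
    demo_props : (Y, J, K) array
        Demographic proportions of new arrivals per year; sums to 1 per year.
    arrival_oud_split : (4,) array
        OUD-state distribution of arrivals (sums to 1).
    lambda_moud : (3, J, K) array
        Entry rates from no-treatment into buprenorphine/naltrexone/methadone.
    lambda_detox_base : (J, K) array
        Baseline entry rate into detox; multiplied by the calibrated eta(t).
    lambda_tp : (4,) array
        Exit rate treatment -> post-treatment, per treatment type.
    lambda_pn : float
        Exit rate post-treatment -> no-treatment (~0.29, from a 25% weekly
        exit probability via r = -ln(1-p)).
    gamma_t : (2,) array
        Treatment initiation effect: probability of keeping the current OUD
        state on entering a medication treatment, by route (noninj, inj).
    rho_t : (3, 8) array
        Weekly OUD transition probabilities (edges a..h) inside each
        medication treatment. Detox has a forced all-non-active matrix.
    baseline_od : (Y, J, K) array
        Overall weekly overdose rate o(t) for the whole population.
    inj_od_ratio : float
        Overdose risk of active-injection relative to active-non-injection.
    beta_n, beta_t, beta_p : (J, K) arrays
        SMR-adjusted non-overdose (other-cause) weekly death rates in
        no-treatment, treatment and post-treatment.
    """

    strata: StrataConfig
    years: tuple
    n0: np.ndarray
    t0: np.ndarray
    p0: np.ndarray
    demo_props: np.ndarray
    arrival_oud_split: np.ndarray
    lambda_moud: np.ndarray
    lambda_detox_base: np.ndarray
    lambda_tp: np.ndarray
    lambda_pn: float
    gamma_t: np.ndarray
    rho_t: np.ndarray
    baseline_od: np.ndarray
    inj_od_ratio: float
    beta_n: np.ndarray
    beta_t: np.ndarray
    beta_p: np.ndarray

    def __post_init__(self):
        self.validate()

    @property
    def n_years(self) -> int:
        return len(self.years)

    def validate(self) -> None:
        s = self.strata
        ny = self.n_years
        self.n0 = validate_stratified("n0", self.n0, s, (N_OUD,))
        self.t0 = validate_stratified("t0", self.t0, s, (N_TREAT, N_OUD))
        self.p0 = validate_stratified("p0", self.p0, s, (N_TREAT, N_OUD))
        self.demo_props = validate_stratified("demo_props", self.demo_props, s, (ny,))
        self.lambda_moud = validate_stratified("lambda_moud", self.lambda_moud, s, (3,))
        self.lambda_detox_base = validate_stratified(
            "lambda_detox_base", self.lambda_detox_base, s)
        self.baseline_od = validate_stratified("baseline_od", self.baseline_od, s, (ny,))
        self.beta_n = validate_stratified("beta_n", self.beta_n, s)
        self.beta_t = validate_stratified("beta_t", self.beta_t, s)
        self.beta_p = validate_stratified("beta_p", self.beta_p, s)
        self.arrival_oud_split = np.asarray(self.arrival_oud_split, dtype=float)
        self.lambda_tp = np.asarray(self.lambda_tp, dtype=float)
        self.gamma_t = np.asarray(self.gamma_t, dtype=float)
        self.rho_t = np.asarray(self.rho_t, dtype=float)

        if np.any(self.p0 != 0):
            raise ConfigError("initial post-treatment occupancy must be zero")
        for name in ("n0", "t0", "lambda_moud", "lambda_detox_base", "baseline_od",
                     "beta_n", "beta_t", "beta_p", "lambda_tp"):
            if np.any(getattr(self, name) < 0):
                raise ConfigError(f"{name}: negative values not allowed")
        if self.lambda_pn < 0:
            raise ConfigError("lambda_pn must be nonnegative")
        if self.inj_od_ratio < 0:
            raise ConfigError("inj_od_ratio must be nonnegative")
        sums = self.demo_props.sum(axis=(1, 2))
        if np.any(np.abs(sums - 1.0) > PROP_TOL):
            raise ConfigError("demo_props must sum to 1 per year")
        if abs(self.arrival_oud_split.sum() - 1.0) > PROP_TOL:
            raise ConfigError("arrival_oud_split must sum to 1")
        if self.arrival_oud_split.shape != (N_OUD,) or np.any(self.arrival_oud_split < 0):
            raise ConfigError("arrival_oud_split must be a length-4 distribution")
        if self.gamma_t.shape != (2,) or np.any((self.gamma_t < 0) | (self.gamma_t > 1)):
            raise ConfigError("gamma_t must be two probabilities (noninj, inj)")
        if self.rho_t.shape != (3, 8) or np.any((self.rho_t < 0) | (self.rho_t > 1)):
            raise ConfigError("rho_t must be (3, 8) probabilities")
        if self.lambda_tp.shape != (N_TREAT,):
            raise ConfigError("lambda_tp must have one rate per treatment type")

    def year_index(self, week: int) -> int:
        y = week // 52
        if y < 0 or y >= self.n_years:
            raise ConfigError(
                f"week {week} outside the {self.n_years}-year parameter horizon")
        return y

    @property
    def total_initial(self) -> float:
        return float(self.n0.sum() + self.t0.sum() + self.p0.sum())


@dataclass
class CalibratedInputs:
    """One point of the calibrated-parameter space.

    Attributes
    ----------
    arrivals : (Y,) array
        Weekly non-stratified total arrivals A(t) per year.
    eta : (Y,) array
        Detox entry-rate multipliers per year (> 0).
    gamma_p : (2,) array
        Post-treatment initiation effect by route (noninj, inj), in [0, 1].
    rho_n, rho_p : (J, 8) arrays
        Age-stratified weekly OUD transition probabilities (edges a..h) in
        no-treatment / post-treatment.
    m_n : float
        No-treatment overdose multiplier (> 0).
    m_t : (3,) array
        Per-medication overdose multipliers, each in [0, 1]; detox has none.
    m_p : float
        Post-treatment overdose multiplier (> 1).
    f : (Y,) array
        Fatal overdose proportion per year, in [0, 1].
    """

    arrivals: np.ndarray
    eta: np.ndarray
    gamma_p: np.ndarray
    rho_n: np.ndarray
    rho_p: np.ndarray
    m_n: float
    m_t: np.ndarray
    m_p: float
    f: np.ndarray

    def __post_init__(self):
        for name in ("arrivals", "eta", "gamma_p", "rho_n", "rho_p", "m_t", "f"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if np.any(self.arrivals < 0):
            raise ConfigError("arrivals must be nonnegative")
        if np.any(self.eta <= 0):
            raise ConfigError("eta must be positive")
        if np.any((self.gamma_p < 0) | (self.gamma_p > 1)):
            raise ConfigError("gamma_p must lie in [0, 1]")
        for name in ("rho_n", "rho_p"):
            r = getattr(self, name)
            if r.ndim != 2 or r.shape[1] != 8 or np.any((r < 0) | (r > 1)):
                raise ConfigError(f"{name} must be (n_age, 8) probabilities")
        if not self.m_n > 0:
            raise ConfigError("m_n must be positive")
        if np.any((self.m_t < 0) | (self.m_t > 1)):
            raise ConfigError("m_t must lie in [0, 1]")
        if not self.m_p > 1:
            raise ConfigError("m_p must exceed 1")
        if np.any((self.f < 0) | (self.f > 1)):
            raise ConfigError("f must lie in [0, 1]")


@dataclass
class CalibratedBatch:
    """Stacked calibrated parameters for B candidates (leading axis B)."""

    arrivals: np.ndarray  # (B, Y)
    eta: np.ndarray       # (B, Y)
    gamma_p: np.ndarray   # (B, 2)
    rho_n: np.ndarray     # (B, J, 8)
    rho_p: np.ndarray     # (B, J, 8)
    m_n: np.ndarray       # (B,)
    m_t: np.ndarray       # (B, 3)
    m_p: np.ndarray       # (B,)
    f: np.ndarray         # (B, Y)

    @property
    def size(self) -> int:
        return self.arrivals.shape[0]

    @classmethod
    def stack(cls, items: Sequence[CalibratedInputs]) -> "CalibratedBatch":
        if len(items) == 0:
            raise ConfigError("cannot stack an empty parameter list")
        return cls(
            arrivals=np.stack([c.arrivals for c in items]),
            eta=np.stack([c.eta for c in items]),
            gamma_p=np.stack([c.gamma_p for c in items]),
            rho_n=np.stack([c.rho_n for c in items]),
            rho_p=np.stack([c.rho_p for c in items]),
            m_n=np.array([c.m_n for c in items], dtype=float),
            m_t=np.stack([c.m_t for c in items]),
            m_p=np.array([c.m_p for c in items], dtype=float),
            f=np.stack([c.f for c in items]),
        )

    def select(self, idx) -> "CalibratedBatch":
        return CalibratedBatch(
            self.arrivals[idx], self.eta[idx], self.gamma_p[idx],
            self.rho_n[idx], self.rho_p[idx], self.m_n[idx],
            self.m_t[idx], self.m_p[idx], self.f[idx])

    def item(self, i: int) -> CalibratedInputs:
        return CalibratedInputs(
            arrivals=self.arrivals[i], eta=self.eta[i], gamma_p=self.gamma_p[i],
            rho_n=self.rho_n[i], rho_p=self.rho_p[i], m_n=float(self.m_n[i]),
            m_t=self.m_t[i], m_p=float(self.m_p[i]), f=self.f[i])

    @classmethod
    def from_single(cls, c: CalibratedInputs) -> "CalibratedBatch":
        return cls.stack([c])


def as_batch(calib) -> CalibratedBatch:
    """Coerce a CalibratedInputs, sequence thereof, or CalibratedBatch."""
    if isinstance(calib, CalibratedBatch):
        return calib
    if isinstance(calib, CalibratedInputs):
        return CalibratedBatch.from_single(calib)
    return CalibratedBatch.stack(list(calib))
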