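"""Calibrated-parameter space: declarative marginals and Latin hypercube
sampling.

Each calibrated scalar gets a :class:`MarginalSpec` (uniform or beta,
optionally rescaled to a support interval). A :class:`ParameterSpace`
orders the marginals; :func:`lhs_sample` draws a stratified design
(one draw per equal-probability bin per dimension, columns permuted
independently) and :func:`to_parameter_sets` materializes rows as
:class:`~respondsim.inputs.CalibratedInputs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .errors import ConfigError
from .inputs import CalibratedBatch, CalibratedInputs
from .strata import StrataConfig, TRANSITION_LABELS, MOUDS

FAMILIES = ("uniform", "beta")


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one calibrated scalar.

    ``name`` is a dotted parameter path (e.g. ``arrivals.2014``,
    ``rho_n.c.age1``). For ``uniform``, ``lo``/``hi`` are the bounds; for
    ``beta``, ``a``/``b`` are the shape parameters and ``lo``/``hi`` rescale
    the unit support (defaults 0, 1).
    """

    name: str
    family: str
    lo: float = 0.0
    hi: float = 1.0
    a: float | None = None
    b: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")
        if not self.lo < self.hi:
            raise ConfigError(f"{self.name}: lower bound must be below upper")
        if self.family == "beta":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ConfigError(f"{self.name}: beta shapes must be positive")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of uniform(0,1) draws onto this marginal."""
        u = np.asarray(u, dtype=float)
        if self.family == "uniform":
            return self.lo + u * (self.hi - self.lo)
        return self.lo + (self.hi - self.lo) * stats.beta.ppf(u, self.a, self.b)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo)
        if self.family == "uniform":
            return np.clip(x, 0.0, 1.0)
        return stats.beta.cdf(x, self.a, self.b)

    @property
    def mean(self) -> float:
        if self.family == "uniform":
            return 0.5 * (self.lo + self.hi)
        return self.lo + (self.hi - self.lo) * self.a / (self.a + self.b)

    def to_dict(self) -> dict:
        d = {"name": self.name, "family": self.family,
             "lo": float(self.lo), "hi": float(self.hi)}
        if self.family == "beta":
            d["a"] = float(self.a)
            d["b"] = float(self.b)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalSpec":
        return cls(d["name"], d["family"], float(d.get("lo", 0.0)),
                   float(d.get("hi", 1.0)),
                   d.get("a"), d.get("b"))


@dataclass
class ParameterSpace:
    """Ordered collection of marginals defining the joint sampling space."""

    marginals: List[MarginalSpec]

    def __post_init__(self):
        names = [m.name for m in self.marginals]
        if len(set(names)) != len(names):
            raise ConfigError("marginal names must be unique")

    @property
    def d(self) -> int:
        return len(self.marginals)

    @property
    def names(self) -> List[str]:
        return [m.name for m in self.marginals]

    def __getitem__(self, name: str) -> MarginalSpec:
        for m in self.marginals:
            if m.name == name:
                return m
        raise KeyError(name)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Columnwise quantile transform of an (N, d) uniform matrix."""
        u = np.asarray(u, dtype=float)
        if u.ndim != 2 or u.shape[1] != self.d:
            raise ConfigError("uniform matrix has wrong dimensionality")
        out = np.empty_like(u)
        for j, m in enumerate(self.marginals):
            out[:, j] = m.ppf(u[:, j])
        return out

    def to_records(self) -> list:
        return [m.to_dict() for m in self.marginals]

    @classmethod
    def from_records(cls, recs: Iterable[dict]) -> "ParameterSpace":
        return cls([MarginalSpec.from_dict(r) for r in recs])


@dataclass
class DesignMatrix:
    """An N x d matrix of sampled parameter values."""

    values: np.ndarray
    names: List[str]
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int | None = None) -> "DesignMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns), seed)


def lhs_sample(space: ParameterSpace, n: int, seed, midpoint: bool = False
               ) -> DesignMatrix:
    """Latin hypercube sample of the parameter space.

    Each dimension is cut into ``n`` equal-probability bins and exactly one
    draw falls in each bin; bin order is permuted independently per
    dimension. Within-bin placement is uniform jitter by default, or the
    bin midpoint when ``midpoint=True`` (deterministic given the
    permutations).
    """
    if n < 1:
        raise ConfigError("sample count must be >= 1")
    sampler = qmc.LatinHypercube(d=space.d, scramble=not midpoint,
                                 rng=np.random.default_rng(seed))
    u = sampler.random(n=n)
    return DesignMatrix(space.ppf(u), space.names, seed)


# ---------------------------------------------------------------------------
# naming convention and materialization
# ---------------------------------------------------------------------------


def canonical_names(strata: StrataConfig, years: Sequence[int]) -> List[str]:
    """The canonical ordered scalar names covering CalibratedInputs."""
    names = [f"arrivals.{y}" for y in years]
    names += [f"eta.{y}" for y in years]
    names += ["gamma_p.noninj", "gamma_p.inj"]
    names += ["m_n"] + [f"m_t.{m}" for m in MOUDS] + ["m_p"]
    names += [f"f.{y}" for y in years]
    for which in ("rho_n", "rho_p"):
        for lab in TRANSITION_LABELS:
            for j in range(strata.n_age):
                names.append(f"{which}.{lab}.age{j}")
    return names


def check_space_covers(space: ParameterSpace, strata: StrataConfig,
                       years: Sequence[int]) -> None:
    want = set(canonical_names(strata, years))
    have = set(space.names)
    if want != have:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ConfigError(
            f"parameter space does not cover CalibratedInputs exactly; "
            f"missing={missing[:5]} extra={extra[:5]}")


def design_to_batch(design: DesignMatrix, strata: StrataConfig,
                    years: Sequence[int]) -> CalibratedBatch:
    """Fast path: map design columns onto stacked calibrated parameters."""
    col = design.column
    ny = len(years)
    J = strata.n_age
    n = design.n
    rho = {}
    for which in ("rho_n", "rho_p"):
        arr = np.empty((n, J, 8))
        for li, lab in enumerate(TRANSITION_LABELS):
            for j in range(J):
                arr[:, j, li] = col(f"{which}.{lab}.age{j}")
        rho[which] = arr
    return CalibratedBatch(
        arrivals=np.stack([col(f"arrivals.{y}") for y in years], axis=1),
        eta=np.stack([col(f"eta.{y}") for y in years], axis=1),
        gamma_p=np.stack([col("gamma_p.noninj"), col("gamma_p.inj")], axis=1),
        rho_n=rho["rho_n"], rho_p=rho["rho_p"],
        m_n=col("m_n"),
        m_t=np.stack([col(f"m_t.{m}") for m in MOUDS], axis=1),
        m_p=col("m_p"),
        f=np.stack([col(f"f.{y}") for y in years], axis=1),
    )


def to_parameter_sets(design: DesignMatrix, space: ParameterSpace,
                      strata: StrataConfig, years: Sequence[int]
                      ) -> List[CalibratedInputs]:
    """Materialize every design row as a validated CalibratedInputs.

    Rows violating a type invariant (e.g. an m_p marginal misconfigured to
    dip below 1) are rejected with a diagnostic.
    """
    if design.names != space.names:
        raise ConfigError("design columns do not match the parameter space")
    check_space_covers(space, strata, years)
    batch = design_to_batch(design, strata, years)
    out = []
    for i in range(design.n):
        try:
            out.append(batch.item(i))
        except ConfigError as exc:
            raise ConfigError(f"design row {i} violates an invariant: {exc}") from exc
    return out


def batch_to_frame(cb: CalibratedBatch, strata: StrataConfig,
                   years: Sequence[int]) -> pd.DataFrame:
    """Flatten a CalibratedBatch back to a design-style DataFrame."""
    names = canonical_names(strata, years)
    data = {}
    ny = len(years)
    for yi, y in enumerate(years):
        data[f"arrivals.{y}"] = cb.arrivals[:, yi]
        data[f"eta.{y}"] = cb.eta[:, yi]
        data[f"f.{y}"] = cb.f[:, yi]
    data["gamma_p.noninj"] = cb.gamma_p[:, 0]
    data["gamma_p.inj"] = cb.gamma_p[:, 1]
    data["m_n"] = cb.m_n
    for mi, m in enumerate(MOUDS):
        data[f"m_t.{m}"] = cb.m_t[:, mi]
    data["m_p"] = cb.m_p
    for which, arr in (("rho_n", cb.rho_n), ("rho_p", cb.rho_p)):
        for li, lab in enumerate(TRANSITION_LABELS):
            for j in range(strata.n_age):
                data[f"{which}.{lab}.age{j}"] = arr[:, j, li]
    return pd.DataFrame({n: data[n] for n in names})
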