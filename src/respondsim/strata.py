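"""State space and demographic stratification of the cohort model.

The model tracks an opioid use disorder (OUD) population over three axes
besides demography:

* **health states** -- one no-treatment state ``N``, four treatment states
  (buprenorphine, naltrexone, methadone, detox) and four paired
  post-treatment states;
* **OUD states** -- the 2x2 cross of use activity and route of
  administration: active non-injection (ANI), non-active after
  non-injection (NANI), active injection (AI), non-active after
  injection (NAI);
* **demography** -- age band x sex.

Arrays throughout the package are indexed ``[health, oud, age, sex]`` in
the orders defined here (batched variants carry a leading candidate axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError

# -- OUD (substance use) states ------------------------------------------------

OUD_STATES = ("ANI", "NANI", "AI", "NAI")
N_OUD = 4
#: boolean mask over OUD_STATES: currently using actively
ACTIVE = np.array([True, False, True, False])
#: boolean mask over OUD_STATES: injection route
INJECTION = np.array([False, False, True, True])
#: index of the matching non-active state for each OUD state
NONACTIVE_OF = np.array([1, 1, 3, 3])

ANI, NANI, AI, NAI = range(4)

# -- health states -------------------------------------------------------------

TREATMENTS = ("bup", "ntx", "met", "detox")
MOUDS = ("bup", "ntx", "met")  # medication treatments; detox is an acute service
N_TREAT = 4

HEALTH_STATES = (
    "N",
    "T_bup",
    "T_ntx",
    "T_met",
    "T_detox",
    "P_bup",
    "P_ntx",
    "P_met",
    "P_detox",
)
N_HEALTH = 9
IDX_N = 0
IDX_T = slice(1, 5)  # T_bup..T_detox
IDX_P = slice(5, 9)  # P_bup..P_detox
IDX_T_DETOX = 4
IDX_P_DETOX = 8

#: health-state group labels used in reports
HEALTH_GROUPS = ("no_treatment", "treatment", "post_treatment")

#: the eight core OUD transition labels (a..h) and the (from, to) pair each moves
TRANSITION_LABELS = ("a", "b", "c", "d", "e", "f", "g", "h")
TRANSITION_EDGES = {
    "a": (ANI, NANI),
    "b": (ANI, AI),
    "c": (NANI, ANI),
    "d": (NANI, NAI),
    "e": (AI, NAI),
    "f": (AI, ANI),
    "g": (NAI, AI),
    "h": (NAI, NANI),
}

ROUTES = ("noninj", "inj")  # route-of-administration strata for initiation effects


@dataclass(frozen=True)
class StrataConfig:
    """Demographic stratification: age bands and sexes.

    Parameters
    ----------
    age_band_edges
        Strictly increasing year boundaries; band ``j`` spans
        ``[edges[j], edges[j+1])``.
    sexes
        Sex labels (default two).
    """

    age_band_edges: tuple = (15, 25, 35, 55, 100)
    sexes: tuple = ("male", "female")

    def __post_init__(self):
        edges = tuple(float(e) for e in self.age_band_edges)
        if len(edges) < 2:
            raise ConfigError("need at least one age band (two edges)")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError("age band edges must be strictly increasing")
        if len(self.sexes) < 1:
            raise ConfigError("need at least one sex stratum")
        object.__setattr__(self, "age_band_edges", edges)
        object.__setattr__(self, "sexes", tuple(self.sexes))

    @property
    def n_age(self) -> int:
        return len(self.age_band_edges) - 1

    @property
    def n_sex(self) -> int:
        return len(self.sexes)

    @property
    def age_midpoints(self) -> np.ndarray:
        e = np.asarray(self.age_band_edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def age_labels(self) -> tuple:
        e = self.age_band_edges
        return tuple(f"{int(a)}-{int(b)}" for a, b in zip(e, e[1:]))

    @property
    def shape(self) -> tuple:
        """(n_age, n_sex)"""
        return (self.n_age, self.n_sex)

    def to_dict(self) -> dict:
        return {"age_band_edges": list(self.age_band_edges), "sexes": list(self.sexes)}

    @classmethod
    def from_dict(cls, d: dict) -> "StrataConfig":
        return cls(tuple(d["age_band_edges"]), tuple(d["sexes"]))


def build_oud_matrix(probs: np.ndarray, edge_map: dict | None = None) -> np.ndarray:
    """Assemble 4x4 weekly OUD transition matrices from the eight edge
    probabilities a..h.

    ``probs`` has shape ``(..., 8)`` in TRANSITION_LABELS order; the result has
    shape ``(..., 4, 4)``. The diagonal holds the stay probability
    ``1 - row sum``. Rows whose off-diagonal sum exceeds 1 raise ConfigError.
    """
    edge_map = edge_map or TRANSITION_EDGES
    probs = np.asarray(probs, dtype=float)
    if probs.shape[-1] != 8:
        raise ConfigError("expected 8 transition probabilities (a..h)")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ConfigError("OUD transition probabilities must lie in [0, 1]")
    out = np.zeros(probs.shape[:-1] + (N_OUD, N_OUD), dtype=float)
    for i, lab in enumerate(TRANSITION_LABELS):
        s, t = edge_map[lab]
        out[..., s, t] += probs[..., i]
    rowsum = out.sum(axis=-1)
    if np.any(rowsum > 1.0 + 1e-12):
        raise ConfigError("OUD transition row sums exceed 1")
    idx = np.arange(N_OUD)
    out[..., idx, idx] = 1.0 - np.clip(rowsum, 0.0, 1.0)
    return out


def detox_oud_matrix() -> np.ndarray:
    """Forced matrix for detox: everyone becomes (or stays) non-active."""
    m = np.zeros((N_OUD, N_OUD))
    for s in range(N_OUD):
        m[s, NONACTIVE_OF[s]] = 1.0
    m[NANI, NANI] = 1.0
    m[NAI, NAI] = 1.0
    m[NANI, ANI] = 0.0
    m[NAI, AI] = 0.0
    # rows ANI and AI map fully to their non-active partners; rows NANI/NAI stay
    m[ANI] = 0.0
    m[ANI, NANI] = 1.0
    m[AI] = 0.0
    m[AI, NAI] = 1.0
    return m


def validate_stratified(name: str, arr: np.ndarray, strata: StrataConfig,
                        lead: Sequence[int] = ()) -> np.ndarray:
    """Check that ``arr`` has shape ``(*lead, n_age, n_sex)`` and return it as
    float array."""
    arr = np.asarray(arr, dtype=float)
    want = tuple(lead) + strata.shape
    if arr.shape != want:
        raise ConfigError(f"{name}: expected shape {want}, got {arr.shape}")
    return arr
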