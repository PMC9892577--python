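"""State statistics, thermodynamic and kinetic estimators.

* van't Hoff: R ln K_T = -dH/T + dS, with the equilibrium constant of
  the free -> bound transformation taken as the occupancy ratio
  K_T = p(free)/p(bound) (a configurable convention switch exposes the
  conventional bound/free ratio, which flips the sign of dH and dS).
* Arrhenius: ln k = ln A - Ea/(R T) with k = 1/tau1, the hydrolysis
  rate constant.
* Kinetic isotope effect: KIE = kH/kD; values above 2 indicate a
  primary isotope effect (bond to the transferred H broken in the
  rate-limiting step).
* Debye screening length of the electrolyte, which sets the FET's
  sensing range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants, stats
from sklearn.base import BaseEstimator

from .models import R_GAS


def state_statistics(events: pd.DataFrame, by: list[str] | None = None
                     ) -> pd.DataFrame:
    """Per-state mean dwell and occurrence proportions.

    Two proportion conventions are reported: ``occurrence_proportion``
    is each state's share of event counts; ``time_proportion`` is its
    share of total occupied time.  For a strictly alternating two-state
    trace the count shares are identically 1/2, so occupancy-based
    analyses (the van't Hoff fit) use ``time_proportion``.
    """
    if events.empty:
        raise ValueError("empty event list")
    group_cols = (by or []) + ["state"]
    g = events.groupby(group_cols, observed=True)
    out = g.agg(n_events=("dwell_s", "size"),
                mean_dwell=("dwell_s", "mean"),
                total_time=("dwell_s", "sum"),
                mean_current=("mean_current_nA", "mean")).reset_index()
    norm_cols = by or None
    if norm_cols:
        denom_n = out.groupby(norm_cols)["n_events"].transform("sum")
        denom_t = out.groupby(norm_cols)["total_time"].transform("sum")
    else:
        denom_n, denom_t = out["n_events"].sum(), out["total_time"].sum()
    out["occurrence_proportion"] = out["n_events"] / denom_n
    out["time_proportion"] = out["total_time"] / denom_t
    if out["state"].nunique() == 1:
        warnings.warn("single-state input: proportions are degenerate")
    return out


@dataclass
class ThermoFit:
    dH: float                  # J/mol
    dS: float                  # J/K/mol
    K_by_T: dict
    r_squared: float


class VantHoffFit(BaseEstimator):
    """Linear van't Hoff fit of R ln K_T against 1000/T.

    ``fit(T, p_bound)`` takes temperatures (K) and bound-state occupancy
    proportions; K_T = p_free/p_bound under the default convention.
    dH = -slope * 1000 and dS = intercept (exact closed-form linear
    regression, machine precision on noise-free inputs).
    """

    def __init__(self, convention: str = "free_over_bound"):
        self.convention = convention

    def fit(self, T, p_bound, y=None):
        T = np.asarray(T, dtype=float)
        p = np.asarray(p_bound, dtype=float)
        if T.size < 3 or np.unique(T).size < 3:
            raise ValueError("van't Hoff fit needs >= 3 distinct temperatures")
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("occupancies must lie in (0, 1)")
        K = (1.0 - p) / p
        if self.convention == "bound_over_free":
            K = 1.0 / K
        elif self.convention != "free_over_bound":
            raise ValueError(f"unknown convention {self.convention!r}")
        x = 1000.0 / T
        yv = R_GAS * np.log(K)
        res = stats.linregress(x, yv)
        self.dH_ = -res.slope * 1000.0
        self.dS_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue ** 2)
        self.K_by_T_ = dict(zip(T.tolist(), K.tolist()))
        return self

    def result(self) -> ThermoFit:
        return ThermoFit(self.dH_, self.dS_, self.K_by_T_, self.r_squared_)


def vant_hoff_fit(temperatures, p_bound,
                  convention: str = "free_over_bound") -> ThermoFit:
    return VantHoffFit(convention).fit(temperatures, p_bound).result()


@dataclass
class ArrheniusResult:
    Ea: float                  # J/mol
    lnA: float
    k_by_T: dict
    r_squared: float


class ArrheniusFit(BaseEstimator):
    """Arrhenius fit of ln k vs 1/(R T) with k = 1/tau1."""

    def fit(self, T, tau1, y=None):
        T = np.asarray(T, dtype=float)
        tau1 = np.asarray(tau1, dtype=float)
        if T.size < 3 or np.unique(T).size < 3:
            raise ValueError("Arrhenius fit needs >= 3 distinct temperatures")
        if np.any(tau1 <= 0):
            raise ValueError("tau1 values must be positive")
        k = 1.0 / tau1
        res = stats.linregress(1.0 / (R_GAS * T), np.log(k))
        self.Ea_ = -float(res.slope)
        self.lnA_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue ** 2)
        self.k_by_T_ = dict(zip(T.tolist(), k.tolist()))
        return self

    def result(self) -> ArrheniusResult:
        return ArrheniusResult(self.Ea_, self.lnA_, self.k_by_T_,
                               self.r_squared_)


def arrhenius_fit(temperatures, tau1_by_T) -> ArrheniusResult:
    return ArrheniusFit().fit(temperatures, tau1_by_T).result()


@dataclass
class KIEResult:
    kH: float
    kD: float
    kie: float
    primary: bool              # KIE > 2: primary isotope effect


def compute_kie(kH: float, kD: float) -> KIEResult:
    """Kinetic isotope effect kH/kD from the paired rate constants."""
    if kH <= 0 or kD <= 0:
        raise ValueError("rate constants must be positive")
    ratio = kH / kD
    return KIEResult(kH, kD, ratio, ratio > 2.0)


def debye_length(ionic_strength: float, T: float = 298.15,
                 epsilon_r: float = 78.5) -> float:
    """Debye screening length of a 1:1 aqueous electrolyte, in nm.

    lambda_D = sqrt(eps_r eps0 kB T / (2 NA e^2 I)), with the ionic
    strength I in mol/L; for water at 25 C this reduces to
    ~0.304/sqrt(I) nm.  Halving I multiplies lambda_D by sqrt(2).
    """
    if ionic_strength <= 0 or T <= 0 or epsilon_r <= 0:
        raise ValueError("inputs must be positive")
    c_m3 = ionic_strength * 1000.0 * constants.Avogadro
    lam = np.sqrt(epsilon_r * constants.epsilon_0 * constants.k * T
                  / (2.0 * constants.e ** 2 * c_m3))
    return float(lam * 1e9)
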