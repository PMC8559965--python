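"""Derived quantities: equilibrium dose-response curves, phase-plane region
classification, apoptosis persistence, efficacy scores and arm contrasts.

The apoptosis switch partitions the (X, B) phase plane into an apoptotic
region Ta (X > th_X, B < th_B), an anti-apoptotic region Tt (X < th_X,
B > th_B), and a remaining 'neither' region.  Treatment efficacy is scored
reciprocally: anti-tumor efficacy E_T = f_T / C(t) and anti-CRCC efficacy
E_c = f_c / L(t), combined as E_total = omega_1 E_T + omega_2 E_c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import apoptosis_indicator, intracellular_equilibrium
from .parameters import ParameterSet
from .simulate import SimulationResult
from .therapy import HOURS_PER_DAY

__all__ = [
    "DoseResponseCurve", "EfficacyResult", "dose_response_curve",
    "classify_region", "apoptosis_persistence", "efficacy_metrics",
    "percent_change",
]


@dataclass
class DoseResponseCurve:
    """Equilibrium levels of the intracellular cascade along a TZB grid."""

    T_grid: np.ndarray
    L_star: np.ndarray
    F_star: np.ndarray
    B_star: np.ndarray
    X_star: np.ndarray
    S_fixed: float
    A_fixed: float
    crossing_dose: Optional[float]   # smallest dose entering Ta, or None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.T_grid, "L_star": self.L_star, "F_star": self.F_star,
            "B_star": self.B_star, "X_star": self.X_star,
        })


@dataclass(frozen=True)
class EfficacyResult:
    """Reciprocal efficacy scores evaluated at one time point."""

    E_T: float
    E_c: float
    E_total: float
    t_eval: float


def dose_response_curve(params: ParameterSet, T_grid: Sequence[float],
                        S_fixed: float = 0.25, A_fixed: float = 0.0,
                        refine_tol: float = 1e-4) -> DoseResponseCurve:
    """Closed-form equilibria per dose, plus the smallest apoptotic dose.

    The crossing dose is the smallest grid dose whose equilibrium lies in the
    apoptotic region, refined by bisection between the bracketing grid points
    to ``refine_tol``.
    """
    grid = np.asarray(T_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dose grid must be nonempty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("dose grid must be nonnegative and increasing")

    eqs = [intracellular_equilibrium(params, S=S_fixed, A=A_fixed, T=float(T))
           for T in grid]
    L = np.array([e.L_star for e in eqs])
    F = np.array([e.F_star for e in eqs])
    B = np.array([e.B_star for e in eqs])
    X = np.array([e.X_star for e in eqs])

    def in_ta(T: float) -> bool:
        e = intracellular_equilibrium(params, S=S_fixed, A=A_fixed, T=T)
        return bool(apoptosis_indicator(e.B_star, e.X_star, params))

    apop = np.array([apoptosis_indicator(b, x, params)
                     for b, x in zip(B, X)], dtype=bool)
    crossing: Optional[float] = None
    if apop.any():
        j = int(np.argmax(apop))
        if j == 0:
            crossing = float(grid[0])
        else:
            lo, hi = float(grid[j - 1]), float(grid[j])
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                if in_ta(mid):
                    hi = mid
                else:
                    lo = mid
            crossing = hi
    return DoseResponseCurve(T_grid=grid, L_star=L, F_star=F, B_star=B,
                             X_star=X, S_fixed=S_fixed, A_fixed=A_fixed,
                             crossing_dose=crossing)


def classify_region(B: float, X: float, params: ParameterSet) -> str:
    """'Ta' (apoptotic), 'Tt' (anti-apoptotic) or 'neither'."""
    if B < 0 or X < 0:
        raise ValueError("B and X must be >= 0")
    if X > params.th_X and B < params.th_B:
        return "Ta"
    if X < params.th_X and B > params.th_B:
        return "Tt"
    return "neither"


def region_trajectory(sim: SimulationResult) -> pd.DataFrame:
    """(X, B) trajectory labelled by phase-plane region, for plotting."""
    p = sim.params_used
    labels = [classify_region(b, x, p)
              for b, x in zip(sim.state("B"), sim.state("X"))]
    return pd.DataFrame({"time_h": sim.times, "X": sim.state("X"),
                         "B": sim.state("B"), "region": labels})


def apoptosis_persistence(sim: SimulationResult,
                          params: Optional[ParameterSet] = None) -> float:
    """Total time (days) spent with the apoptosis indicator on.

    Uses the event-resolved switch times, so the measure is exact between
    located crossings.
    """
    total = sum(t1 - t0 for t0, t1, v in sim.apop_segments if v == 1)
    return total / HOURS_PER_DAY


def efficacy_metrics(sim: SimulationResult,
                     params: Optional[ParameterSet] = None,
                     t_eval: float = 30.0 * HOURS_PER_DAY,
                     f_T: Optional[float] = None,
                     f_c: Optional[float] = None) -> EfficacyResult:
    """E_T = f_T/C, E_c = f_c/L and their weighted sum at ``t_eval`` (hours).

    Scale factors default to the values stored in the parameter set; pass
    explicit ``f_T``/``f_c`` to normalize against reference runs (e.g. f_T =
    untreated C(t_eval) so the control scores E_T = 1).
    """
    p = params if params is not None else sim.params_used
    at = sim.at(t_eval)
    C, L = at["C"], at["L"]
    if C <= 0 or L <= 0:
        raise ValueError("efficacy undefined for zero C or L")
    fT = p.f_T if f_T is None else f_T
    fc = p.f_c if f_c is None else f_c
    E_T = fT / C
    E_c = fc / L
    return EfficacyResult(E_T=E_T, E_c=E_c,
                          E_total=p.omega_1 * E_T + p.omega_2 * E_c,
                          t_eval=t_eval)


def percent_change(sim_ref: SimulationResult, sim_alt: SimulationResult,
                   variable: str, t_eval: float) -> float:
    """Percent reduction ``100*(ref - alt)/ref`` of one variable at ``t_eval``
    hours (positive when the alternative arm lowers the readout)."""
    ref = sim_ref.at(t_eval)[variable]
    alt = sim_alt.at(t_eval)[variable]
    if ref == 0:
        raise ValueError(f"reference {variable} is zero at t={t_eval} h")
    return 100.0 * (ref - alt) / ref
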