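"""Right-hand side of the hybrid ODE system, indicator functions, and the
closed-form intracellular equilibrium with its stability classification.

State ordering (see :data:`crccsim.parameters.STATE_NAMES`)::

    y = (F, B, X, C, S, L, A, T)

Governing equations (nondimensional working system, time in hours):

    dF/dt = lambda_F + lambda_2 L - mu_F F
    dB/dt = lambda_B + lambda_3 F + k5 k4^2/(k4^2 + delta T^2) - mu_B B
    dX/dt = lambda_X + k7 k6^2/(k6^2 + gamma B^2) - mu_X X
    dC/dt = r C (1 - C/K) + lambda_1 S - mu_C (alpha/B) C I_apop
    dS/dt = beta T I_s
    dL/dt = lambda_L + k3 S/(k1 + k2 A) - mu_L L
    dA/dt = u_A(t) - mu_A A     (0 when clamped)
    dT/dt = u_T(t) - mu_T T     (0 when clamped)

``I_apop = 1`` iff Bcl-2 is below and BAX above the apoptosis thresholds
(strict inequalities); ``I_s = 1`` only inside the CSC activation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .parameters import ParameterSet, STATE_NAMES
from .therapy import TherapyProtocol, infusion_rate

__all__ = [
    "apoptosis_indicator",
    "csc_indicator",
    "full_rhs",
    "intracellular_equilibrium",
    "EquilibriumResult",
    "DegenerateStateError",
]

_B_FLOOR = 1e-12  # defensive floor on B in the alpha/B kill term


class DegenerateStateError(ValueError):
    """Raised when the killing term alpha/B is evaluated at B = 0."""


def apoptosis_indicator(B: float, X: float, params: ParameterSet) -> int:
    """1 iff B < th_B and X > th_X (strict); 0 otherwise.

    The (X, B) plane has three regions: apoptotic (Ta), anti-apoptotic (Tt),
    and a 'neither' region where the indicator is also 0.
    """
    return int(B < params.th_B and X > params.th_X)


def csc_indicator(t: float, params: ParameterSet) -> int:
    """1 iff t_on < t <= t_off (CSC activation window, hours)."""
    t_on, t_off = params.csc_window
    return int(t_on < t <= t_off)


def _drug_rates(t: float, A: float, T: float, params: ParameterSet,
                protocol: TherapyProtocol) -> Tuple[float, float]:
    if protocol.atv.mode == "clamped":
        dA = 0.0
    else:
        dA = infusion_rate(protocol, "ATV", t) - params.mu_A * A
    if protocol.tzb.mode == "clamped":
        dT = 0.0
    else:
        dT = infusion_rate(protocol, "TZB", t) - params.mu_T * T
    return dA, dT


def full_rhs(state: Sequence[float], t: float, params: ParameterSet,
             protocol: TherapyProtocol, *, validate: bool = True) -> np.ndarray:
    """Time derivatives of all eight state components.

    With ``validate=True`` (the public contract) negative state components
    raise; the integrator path uses ``validate=False`` where transient
    round-off negatives are clipped upstream.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (8,):
        raise ValueError(f"state must have 8 components {STATE_NAMES}")
    if validate and np.any(y < 0):
        bad = [n for n, v in zip(STATE_NAMES, y) if v < 0]
        raise ValueError(f"negative state component(s): {bad}")
    F, B, X, C, S, L, A, T = y
    p = params

    i_apop = apoptosis_indicator(B, X, p)
    i_s = csc_indicator(t, p)

    dF = p.lambda_F + p.lambda_2 * L - p.mu_F * F
    dB = (p.lambda_B + p.lambda_3 * F
          + p.k5 * p.k4 ** 2 / (p.k4 ** 2 + p.delta * T ** 2)
          - p.mu_B * B)
    dX = (p.lambda_X + p.k7 * p.k6 ** 2 / (p.k6 ** 2 + p.gamma * B ** 2)
          - p.mu_X * X)
    if i_apop:
        if B <= 0.0:
            if validate:
                raise DegenerateStateError(
                    "apoptotic killing with B = 0 (alpha/B undefined)")
            warnings.warn("B at floor in kill term alpha/B", RuntimeWarning,
                          stacklevel=2)
        kill = p.mu_C * (p.alpha / max(B, _B_FLOOR)) * C
    else:
        kill = 0.0
    dC = p.r * C * (1.0 - C / p.K) + p.lambda_1 * S - kill
    dS = p.beta * T * i_s
    dL = p.lambda_L + p.k3 * S / (p.k1 + p.k2 * A) - p.mu_L * L
    dA, dT = _drug_rates(t, A, T, p, protocol)
    return np.array([dF, dB, dX, dC, dS, dL, dA, dT])


# ---------------------------------------------------------------------------
# closed-form equilibrium of the (L, F, B, X) cascade


@dataclass(frozen=True)
class EquilibriumResult:
    """Cascade equilibrium of the intracellular subsystem at fixed S, A, T."""

    L_star: float
    F_star: float
    B_star: float
    X_star: float
    stability: str                  # 'stable' | 'unstable' | 'marginal'
    eigenvalues: Tuple[complex, ...]

    def as_dict(self) -> dict:
        return {
            "L_star": self.L_star, "F_star": self.F_star,
            "B_star": self.B_star, "X_star": self.X_star,
            "stability": self.stability,
            "eigenvalues": list(self.eigenvalues),
        }


def intracellular_equilibrium(params: ParameterSet, S: float = 0.25,
                              A: float = 0.0, T: float = 0.0) -> EquilibriumResult:
    """Closed-form equilibrium of the (L, F, B, X) subsystem.

    With S and both drug levels held constant the subsystem is a feed-forward
    cascade, so the equilibrium is obtained by forward substitution:

        L* = (lambda_L + k3 S/(k1 + k2 A)) / mu_L
        F* = (lambda_F + lambda_2 L*) / mu_F
        B* = (lambda_B + lambda_3 F* + k5 k4^2/(k4^2 + delta T^2)) / mu_B
        X* = (lambda_X + k7 k6^2/(k6^2 + gamma B*^2)) / mu_X

    Local stability comes from the eigenvalues of the subsystem Jacobian,
    which is lower-triangular in the cascade ordering.
    """
    if min(S, A, T) < 0:
        raise ValueError("S, A and T must be >= 0")
    p = params
    for name in ("mu_L", "mu_F", "mu_B", "mu_X"):
        if getattr(p, name) <= 0:
            raise ValueError(f"decay rate {name} must be > 0")
    L = (p.lambda_L + p.k3 * S / (p.k1 + p.k2 * A)) / p.mu_L
    F = (p.lambda_F + p.lambda_2 * L) / p.mu_F
    B = (p.lambda_B + p.lambda_3 * F
         + p.k5 * p.k4 ** 2 / (p.k4 ** 2 + p.delta * T ** 2)) / p.mu_B
    X = (p.lambda_X + p.k7 * p.k6 ** 2 / (p.k6 ** 2 + p.gamma * B ** 2)) / p.mu_X

    jac = intracellular_jacobian(params, B)
    eigs = np.linalg.eigvals(jac)
    re = eigs.real
    if np.all(re < 0):
        stability = "stable"
    elif np.any(re > 0):
        stability = "unstable"
    else:
        stability = "marginal"
    return EquilibriumResult(L_star=float(L), F_star=float(F), B_star=float(B),
                             X_star=float(X), stability=stability,
                             eigenvalues=tuple(complex(e) for e in eigs))


def intracellular_jacobian(params: ParameterSet, B_star: float) -> np.ndarray:
    """Jacobian of the (L, F, B, X) subsystem at an equilibrium.

    Only the X row depends on the state (through the Bcl-2 inhibition of
    BAX); the matrix is lower triangular, so the eigenvalues are the negated
    decay rates.
    """
    p = params
    dXdB = -p.k7 * p.k6 ** 2 * 2 * p.gamma * B_star / (
        p.k6 ** 2 + p.gamma * B_star ** 2) ** 2
    return np.array([
        [-p.mu_L, 0.0, 0.0, 0.0],
        [p.lambda_2, -p.mu_F, 0.0, 0.0],
        [0.0, p.lambda_3, -p.mu_B, 0.0],
        [0.0, 0.0, dXdB, -p.mu_X],
    ])
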