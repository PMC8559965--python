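"""Model parameters, unit systems, and config I/O.

The model couples an intracellular apoptosis switch (NF-kB ``F``, Bcl-2 ``B``,
BAX ``X``) to tumor cells ``C``, cancer stem cells ``S``, the cytokine IL-6
``L`` and the two drug concentrations (atorvastatin ``A``, trastuzumab ``T``).

Two unit systems exist:

* ``dimensional`` -- literature values with concentrations in uM or g/mm^3 and
  rates per hour.
* ``nondimensional`` -- the unit-free working system in which all published
  simulation magnitudes are expressed (drug doses T in [0, 6], A in [0, 40],
  apoptosis thresholds at 8, IL-6 around 10-60).  This is the canonical
  internal system; time is kept in hours in both systems.

The nondimensional working set shipped here is calibrated so that the closed
form IL-6 equilibrium ``L* = (lambda_L + k3*S/(k1 + k2*A))/mu_L`` equals 60 at
(S=1, A=0) and 18 at (S=1, A=5), the 30-day four-arm simulations give a 46 %
(ATV vs control) and 69 % (combination vs TZB-alone) IL-6 reduction, and the
equilibrium dose-response with (S=0.25, A=5) crosses into the apoptotic region
at T = 0.25.  See docs/methods.md for the derivation.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping, Tuple, Union

import yaml

__all__ = [
    "ParameterSet",
    "ScaleSet",
    "default_parameters",
    "table_dimensional_parameters",
    "convert_units",
    "load_parameters",
    "dump_parameters",
    "DEFAULT_INITIAL_STATE",
    "STATE_NAMES",
]

#: ordering of the eight state components used throughout the package
STATE_NAMES = ("F", "B", "X", "C", "S", "L", "A", "T")

#: the standard initial condition used in every published run, given in the
#: paper-style tuple order (L, F, B, X, S, C); drugs start at 0 (infused mode)
#: or at their clamped levels.
DEFAULT_INITIAL_STATE: Dict[str, float] = {
    "L": 0.0,
    "F": 0.0,
    "B": 5.0,
    "X": 0.0,
    "S": 0.25,
    "C": 0.01,
}


class ParameterError(ValueError):
    """Raised for invalid or inconsistent parameter values."""


@dataclass(frozen=True)
class ParameterSet:
    """All model constants of the coupled tumor--CRCC system.

    Rates are per hour; concentrations are in the units of the active
    ``unit_system``.  Instances are immutable; use :meth:`replace` to derive
    perturbed sets (e.g. for sensitivity sampling).
    """

    # --- intracellular signalling -------------------------------------
    lambda_F: float = 0.035      # basal NF-kB source
    lambda_B: float = 0.16028116  # basal Bcl-2 source
    lambda_X: float = 0.006      # basal BAX source
    lambda_2: float = 0.05       # NF-kB activation by IL-6
    lambda_3: float = 0.025      # Bcl-2 activation by NF-kB
    k4: float = 1.0              # Bcl-2 inhibition saturation constant
    k5: float = 0.10244565       # Bcl-2 autocatalytic strength
    k6: float = 1.0              # BAX inhibition saturation constant
    k7: float = 0.3136           # BAX autocatalytic strength
    delta: float = 10.0          # Bcl-2 inhibition strength by TZB
    gamma: float = 0.015         # BAX inhibition strength by Bcl-2
    mu_F: float = 0.3            # NF-kB decay
    mu_B: float = 0.0347         # Bcl-2 decay
    mu_X: float = 0.02           # BAX decay

    # --- tumor / CSC / IL-6 -------------------------------------------
    r: float = 0.007             # tumor growth rate
    K: float = 1.0               # tumor carrying capacity
    lambda_1: float = 1e-4       # tumor-cell production by CSC
    beta: float = 0.00560897     # CSC production rate by TZB
    lambda_L: float = 0.85043478  # basal IL-6 supply
    k1: float = 1.0              # IL-6 inhibition scaling parameter
    k2: float = 1.11034483       # IL-6 inhibition strength by ATV
    k3: float = 4.03956522       # IL-6 secretion strength by CSC
    mu_L: float = 0.0815         # IL-6 decay
    mu_C: float = 0.05           # tumor apoptotic kill rate
    alpha: float = 2.0           # scaling of Bcl-2-modulated killing

    # --- drug kinetics ------------------------------------------------
    mu_T: float = 0.005          # TZB decay
    mu_A: float = 0.0495         # ATV decay

    # --- switching / scoring -----------------------------------------
    th_B: float = 8.0            # apoptosis threshold on Bcl-2
    th_X: float = 8.0            # apoptosis threshold on BAX
    csc_window: Tuple[float, float] = (480.0, 600.0)  # (t_on, t_off) hours
    f_T: float = 1.0             # anti-tumor efficacy scale factor
    f_c: float = 1.0             # anti-CRCC efficacy scale factor
    omega_1: float = 0.5         # weight of E_T in E_total
    omega_2: float = 0.5         # weight of E_c in E_total

    unit_system: str = "nondimensional"

    def __post_init__(self) -> None:
        nonneg = (
            "lambda_F", "lambda_B", "lambda_X", "lambda_2", "lambda_3",
            "k1", "k2", "k3", "k4", "k5", "k6", "k7", "delta", "gamma",
            "r", "lambda_1", "beta", "lambda_L", "alpha", "mu_C",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        positive = ("mu_F", "mu_B", "mu_X", "mu_L", "mu_T", "mu_A", "K",
                    "th_B", "th_X")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        w1, w2 = self.omega_1, self.omega_2
        if not (0.0 <= w1 <= 1.0 and 0.0 <= w2 <= 1.0):
            raise ParameterError("efficacy weights must lie in [0, 1]")
        if abs(w1 + w2 - 1.0) > 1e-12:
            raise ParameterError("omega_1 + omega_2 must equal 1")
        t_on, t_off = self.csc_window
        if not t_on < t_off:
            raise ParameterError("csc_window must satisfy t_on < t_off")
        if self.unit_system not in ("dimensional", "nondimensional"):
            raise ParameterError(f"unknown unit system {self.unit_system!r}")

    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["csc_window"] = list(self.csc_window)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        d = dict(data)
        if "csc_window" in d:
            d["csc_window"] = tuple(float(x) for x in d["csc_window"])
        return cls(**d)


def default_parameters() -> ParameterSet:
    """The calibrated nondimensional working parameter set."""
    return ParameterSet()


def table_dimensional_parameters() -> ParameterSet:
    """Dimensional literature values (uM, g/mm^3, per hour).

    Carried as metadata alongside the nondimensional working set.  Threshold,
    scaling and scoring fields without published dimensional counterparts keep
    their nondimensional values; converting this set to useful simulation
    units requires the (unpublished) concentration scales, see
    :func:`convert_units` and docs/methods.md.
    """
    return ParameterSet(
        lambda_F=3.5e-2,
        lambda_B=8.5e-4,
        lambda_X=3.3e-4,
        lambda_2=9.15e8,
        lambda_3=1.38e-2,
        k4=1.0,
        k5=1.25e-1,
        k6=1.0,
        k7=1.0,
        delta=1.44e18,
        gamma=8.0,
        mu_F=3e-1,
        mu_B=3.47e-2,
        mu_X=2e-2,
        r=7e-2,
        K=2.5e-3,
        lambda_1=5e-14,
        beta=3.12e-17,
        lambda_L=1.34e-11,
        k1=1.0,
        k2=5e-2,
        k3=6.56e-17,
        mu_L=8.15e-2,
        mu_C=3e-3,
        alpha=2.0,
        mu_T=5.0e-3,
        mu_A=4.95e-2,
        unit_system="dimensional",
    )


# ---------------------------------------------------------------------------
# unit conversion


@dataclass(frozen=True)
class ScaleSet:
    """Characteristic scales bridging dimensional and nondimensional units.

    ``x_nondim = x_dim / X_scale`` for each state variable; ``t_scale`` is the
    duration (hours) of one nondimensional time unit (1 keeps time in hours).
    """

    F: float = 1.0
    B: float = 1.0
    X: float = 1.0
    C: float = 1.0
    S: float = 1.0
    L: float = 1.0
    A: float = 1.0
    T: float = 1.0
    t: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ParameterError(f"scale {f.name} must be > 0")


def _conversion_factors(s: ScaleSet) -> Dict[str, float]:
    """Multiplicative factor applied to each dimensional parameter to obtain
    its nondimensional counterpart (derived by substituting the scaled
    variables into the governing equations)."""
    return {
        "lambda_F": s.t / s.F,
        "lambda_B": s.t / s.B,
        "lambda_X": s.t / s.X,
        "lambda_2": s.L * s.t / s.F,
        "lambda_3": s.F * s.t / s.B,
        "k4": 1.0,
        "k5": s.t / s.B,
        "k6": 1.0,
        "k7": s.t / s.X,
        "delta": s.T ** 2,
        "gamma": s.B ** 2,
        "mu_F": s.t,
        "mu_B": s.t,
        "mu_X": s.t,
        "r": s.t,
        "K": 1.0 / s.C,
        "lambda_1": s.S * s.t / s.C,
        "beta": s.T * s.t / s.S,
        "lambda_L": s.t / s.L,
        "k1": 1.0,
        "k2": s.A,
        "k3": s.S * s.t / s.L,
        "mu_L": s.t,
        "mu_C": s.t,  # the kill term's B-dependence is carried by alpha
        "alpha": 1.0 / s.B,
        "mu_T": s.t,
        "mu_A": s.t,
        "th_B": 1.0 / s.B,
        "th_X": 1.0 / s.X,
        "f_T": 1.0,
        "f_c": 1.0,
        "omega_1": 1.0,
        "omega_2": 1.0,
    }


def convert_units(params: ParameterSet, scales: ScaleSet) -> ParameterSet:
    """Express ``params`` in the other unit system.

    Round-trips (dimensional -> nondimensional -> dimensional) recover the
    original values to machine precision.
    """
    factors = _conversion_factors(scales)
    to_nondim = params.unit_system == "dimensional"
    out: Dict[str, Any] = {}
    for f in dataclasses.fields(params):
        name = f.name
        if name == "unit_system":
            continue
        value = getattr(params, name)
        if name == "csc_window":
            fac = 1.0 / scales.t
            out[name] = (
                tuple(v * fac for v in value) if to_nondim
                else tuple(v / fac for v in value)
            )
            continue
        if name not in factors:
            raise ParameterError(f"no unit-conversion rule for {name!r}")
        out[name] = value * factors[name] if to_nondim else value / factors[name]
    out["unit_system"] = "nondimensional" if to_nondim else "dimensional"
    return ParameterSet(**out)


# ---------------------------------------------------------------------------
# config I/O


def dump_parameters(params: ParameterSet, stream: Union[io.TextIOBase, None] = None) -> str:
    """Serialize a parameter set to YAML (returns the document)."""
    doc = yaml.safe_dump({"parameters": params.to_dict()}, sort_keys=True)
    if stream is not None:
        stream.write(doc)
    return doc


def load_parameters(source: Union[str, io.TextIOBase]) -> ParameterSet:
    """Load a parameter set from a YAML document or open stream."""
    data = yaml.safe_load(source if isinstance(source, str) else source.read())
    if not isinstance(data, dict) or "parameters" not in data:
        raise ParameterError("config must contain a top-level 'parameters' map")
    return ParameterSet.from_dict(data["parameters"])


def load_scenario(source: Union[str, io.TextIOBase]) -> Dict[str, Any]:
    """Load a full scenario config: parameters plus optional ``initial_state``
    (mapping of state names) and ``horizon_days``."""
    data = yaml.safe_load(source if isinstance(source, str) else source.read())
    if not isinstance(data, dict) or "parameters" not in data:
        raise ParameterError("config must contain a top-level 'parameters' map")
    out: Dict[str, Any] = {
        "parameters": ParameterSet.from_dict(data["parameters"]),
        "initial_state": dict(data.get("initial_state",
                                       DEFAULT_INITIAL_STATE)),
        "horizon_days": float(data.get("horizon_days", 40.0)),
    }
    return out


def packaged_config(name: str = "baseline_nondimensional") -> str:
    """Return the text of a config shipped with the package
    ('baseline_nondimensional' or 'table_dimensional')."""
    from importlib import resources

    ref = resources.files(__package__) / "configs" / f"{name}.yaml"
    try:
        return ref.read_text()
    except FileNotFoundError as err:
        raise ParameterError(f"no packaged config named {name!r}") from err
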