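"""Treatment protocols: clamped drug levels, periodic infusions, and the
six-slot alternating TZB/ATV schemes.

A protocol describes, per agent ("ATV" or "TZB"), either a *clamped* mode in
which the drug concentration is held constant, or an *infused* mode in which
the concentration obeys ``dD/dt = sum_i I * 1[t in [t_i, t_i + h]] - mu * D``.
Infusion windows use closed intervals, so the rate at a window edge includes
the dose.  All times are hours internally; the ``*_days`` keyword helpers
convert at the boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

import yaml

__all__ = [
    "HOURS_PER_DAY",
    "Agent",
    "InfusionWindow",
    "AgentSchedule",
    "TherapyProtocol",
    "ScheduleCode",
    "constant_protocol",
    "periodic_protocol",
    "alternating_protocol",
    "enumerate_codes",
    "infusion_rate",
]

HOURS_PER_DAY = 24.0

Agent = Literal["ATV", "TZB"]
AGENTS: Tuple[Agent, Agent] = ("ATV", "TZB")


class ProtocolError(ValueError):
    """Raised for malformed protocols or schedule codes."""


@dataclass(frozen=True)
class InfusionWindow:
    """One infusion: agent, start time (h), duration (h) and dose rate."""

    agent: Agent
    start: float
    duration: float
    dose: float

    def __post_init__(self) -> None:
        if self.agent not in AGENTS:
            raise ProtocolError(f"unknown agent {self.agent!r}")
        if self.duration <= 0:
            raise ProtocolError("window duration must be > 0")
        if self.dose < 0:
            raise ProtocolError("dose must be >= 0")
        if self.start < 0:
            raise ProtocolError("window start must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class AgentSchedule:
    """Mode of one agent: clamped at ``level`` or driven by ``windows``."""

    mode: Literal["clamped", "infused"]
    level: float = 0.0
    windows: Tuple[InfusionWindow, ...] = ()

    def __post_init__(self) -> None:
        if self.mode == "clamped":
            if self.level < 0:
                raise ProtocolError("clamped level must be >= 0")
        elif self.mode == "infused":
            wins = tuple(sorted(self.windows, key=lambda w: w.start))
            for a, b in zip(wins, wins[1:]):
                if b.start < a.end - 1e-9:
                    raise ProtocolError(
                        f"overlapping infusion windows at t={b.start} h")
            object.__setattr__(self, "windows", wins)
        else:
            raise ProtocolError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class TherapyProtocol:
    """Full treatment description for both agents over ``horizon`` hours."""

    atv: AgentSchedule
    tzb: AgentSchedule
    horizon: float

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ProtocolError("horizon must be > 0")
        for sched in (self.atv, self.tzb):
            if sched.mode == "infused" and sched.windows:
                if sched.windows[-1].end > self.horizon + 1e-9:
                    raise ProtocolError("horizon does not cover all windows")

    def schedule(self, agent: Agent) -> AgentSchedule:
        return self.atv if agent == "ATV" else self.tzb

    def breakpoints(self, agent: Agent) -> List[float]:
        """Window edges (starts and ends) for one agent, unsorted."""
        sched = self.schedule(agent)
        pts: List[float] = []
        for w in sched.windows:
            pts.extend((w.start, w.end))
        return pts

    def to_dict(self) -> Dict[str, object]:
        def enc(s: AgentSchedule) -> Dict[str, object]:
            d: Dict[str, object] = {"mode": s.mode}
            if s.mode == "clamped":
                d["level"] = s.level
            else:
                d["windows"] = [
                    {"start": w.start, "duration": w.duration, "dose": w.dose}
                    for w in s.windows
                ]
            return d

        return {"ATV": enc(self.atv), "TZB": enc(self.tzb),
                "horizon": self.horizon}

    def to_yaml(self) -> str:
        return yaml.safe_dump({"protocol": self.to_dict()}, sort_keys=False)

    @classmethod
    def from_yaml(cls, doc: str) -> "TherapyProtocol":
        data = yaml.safe_load(doc)["protocol"]

        def dec(agent: Agent, d: Dict[str, object]) -> AgentSchedule:
            if d["mode"] == "clamped":
                return AgentSchedule(mode="clamped", level=float(d["level"]))
            wins = tuple(
                InfusionWindow(agent=agent, start=float(w["start"]),
                               duration=float(w["duration"]),
                               dose=float(w["dose"]))
                for w in d["windows"]
            )
            return AgentSchedule(mode="infused", windows=wins)

        return cls(atv=dec("ATV", data["ATV"]), tzb=dec("TZB", data["TZB"]),
                   horizon=float(data["horizon"]))


@dataclass(frozen=True)
class ScheduleCode:
    """Length-6 alternating-therapy label over {A, T}, three of each."""

    code: str

    def __post_init__(self) -> None:
        c = self.code.upper()
        if len(c) != 6 or set(c) - {"A", "T"}:
            raise ProtocolError(
                f"schedule code must be 6 letters over {{A,T}}, got {self.code!r}")
        if c.count("A") != 3:
            raise ProtocolError(
                f"schedule code needs exactly three 'A' and three 'T': {self.code!r}")
        object.__setattr__(self, "code", c)

    def __str__(self) -> str:
        return self.code


# ---------------------------------------------------------------------------
# constructors


def constant_protocol(T_level: float, A_level: float,
                      horizon_days: float = 40.0) -> TherapyProtocol:
    """Both agents clamped at fixed levels (the TZB+/-ATV+/- study arms)."""
    if T_level < 0 or A_level < 0:
        raise ProtocolError("clamped levels must be >= 0")
    return TherapyProtocol(
        atv=AgentSchedule(mode="clamped", level=A_level),
        tzb=AgentSchedule(mode="clamped", level=T_level),
        horizon=horizon_days * HOURS_PER_DAY,
    )


def periodic_protocol(agent: Agent, dose: float, period_days: float,
                      duration_days: float = 1.0, n_injections: int = 10,
                      start_days: float = 0.0,
                      horizon_days: float = 40.0,
                      other_clamped_level: float = 0.0) -> TherapyProtocol:
    """``n_injections`` windows of one agent at ``start + k*period``.

    The other agent is clamped at ``other_clamped_level`` (default 0), which
    encodes the "periodic ATV over basal TZB" combination runs.
    """
    if dose < 0:
        raise ProtocolError("dose must be >= 0")
    if period_days < duration_days:
        raise ProtocolError("period must be >= window duration "
                            "(overlapping windows are rejected)")
    h = duration_days * HOURS_PER_DAY
    wins = tuple(
        InfusionWindow(agent=agent,
                       start=(start_days + k * period_days) * HOURS_PER_DAY,
                       duration=h, dose=dose)
        for k in range(n_injections)
    )
    infused = AgentSchedule(mode="infused", windows=wins)
    clamped = AgentSchedule(mode="clamped", level=other_clamped_level)
    if agent == "ATV":
        atv, tzb = infused, clamped
    else:
        atv, tzb = clamped, infused
    horizon = max(horizon_days * HOURS_PER_DAY,
                  wins[-1].end if wins else 0.0)
    return TherapyProtocol(atv=atv, tzb=tzb, horizon=horizon)


def continuous_protocol(agent: Agent, rate: float,
                        horizon_days: float = 40.0,
                        other_clamped_level: float = 0.0) -> TherapyProtocol:
    """Continuous infusion at a constant rate (the period -> 0 limit)."""
    horizon = horizon_days * HOURS_PER_DAY
    win = InfusionWindow(agent=agent, start=0.0, duration=horizon, dose=rate)
    infused = AgentSchedule(mode="infused", windows=(win,))
    clamped = AgentSchedule(mode="clamped", level=other_clamped_level)
    if agent == "ATV":
        return TherapyProtocol(atv=infused, tzb=clamped, horizon=horizon)
    return TherapyProtocol(atv=clamped, tzb=infused, horizon=horizon)


def alternating_protocol(code: Union[str, ScheduleCode], I_A: float,
                         I_T: float, slot_spacing_days: float = 7.0,
                         h_A_days: float = 1.0, h_T_days: float = 1.0,
                         horizon_days: float = 40.0) -> TherapyProtocol:
    """Six-slot alternating scheme: slot k (days 0, 7, ..., 35) carries an ATV
    window if ``code[k] == 'A'`` else a TZB window; three rounds per agent."""
    code = ScheduleCode(str(code))
    atv_wins: List[InfusionWindow] = []
    tzb_wins: List[InfusionWindow] = []
    for k, letter in enumerate(code.code):
        start = k * slot_spacing_days * HOURS_PER_DAY
        if letter == "A":
            atv_wins.append(InfusionWindow(
                agent="ATV", start=start,
                duration=h_A_days * HOURS_PER_DAY, dose=I_A))
        else:
            tzb_wins.append(InfusionWindow(
                agent="TZB", start=start,
                duration=h_T_days * HOURS_PER_DAY, dose=I_T))
    return TherapyProtocol(
        atv=AgentSchedule(mode="infused", windows=tuple(atv_wins)),
        tzb=AgentSchedule(mode="infused", windows=tuple(tzb_wins)),
        horizon=horizon_days * HOURS_PER_DAY,
    )


def enumerate_codes() -> List[ScheduleCode]:
    """All C(6,3) = 20 alternating schedule codes, lexicographic order."""
    codes = []
    for positions in itertools.combinations(range(6), 3):
        letters = ["T"] * 6
        for p in positions:
            letters[p] = "A"
        codes.append("".join(letters))
    return [ScheduleCode(c) for c in sorted(codes)]


# ---------------------------------------------------------------------------
# evaluation


def infusion_rate(protocol: TherapyProtocol, agent: Agent, t: float) -> float:
    """Pointwise infusion rate ``sum_i I * 1[t in [t_i, t_i + h]]``.

    Closed window endpoints contribute; clamped agents have no infusion rate.
    """
    sched = protocol.schedule(agent)
    if sched.mode != "infused":
        raise ProtocolError(
            f"agent {agent} is clamped; infusion rate is undefined")
    total = 0.0
    for w in sched.windows:
        if w.start <= t <= w.end:
            total += w.dose
    return total


def total_delivered(protocol: TherapyProtocol, agent: Agent) -> float:
    """Total drug delivered to one agent, ``sum_i dose * duration``."""
    sched = protocol.schedule(agent)
    if sched.mode != "infused":
        raise ProtocolError(f"agent {agent} is clamped")
    return sum(w.dose * w.duration for w in sched.windows)
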