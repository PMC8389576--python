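"""Measurement protocol descriptions.

A :class:`ProtocolSpec` captures the light regime of one PAM experiment:
an ordered list of phases (dark, actinic, dark recovery), the saturating
pulse times inside each phase, and the light intensities involved.  The
defaults mirror a FluorPen-style instrument programme:

* measuring light 0.09 µmol photons m⁻² s⁻¹,
* saturating/super pulses 2400 µmol m⁻² s⁻¹,
* Kautsky actinic light 300 µmol m⁻² s⁻¹ for 60 s with five super pulses
  (first at 7 s, then every 12 s) followed by an 88 s dark recovery with
  three super pulses (first at 11 s, then every 26 s),
* OJIP induction pulse of red light at 3000 µmol m⁻² s⁻¹,
* light curve with actinic steps 10, 20, 50, 100, 300, 500 µmol m⁻² s⁻¹.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .errors import ProtocolError

MEASURING_PPFD = 0.09
SATURATING_PPFD = 2400.0
OJIP_PULSE_PPFD = 3000.0
KC_ACTINIC_PPFD = 300.0
LC_STEPS_PPFD = (10.0, 20.0, 50.0, 100.0, 300.0, 500.0)

#: duration of one saturating-pulse window, seconds
PULSE_WINDOW_S = 0.8


def pulse_schedule(phase_duration_s: float, first_s: float, interval_s: float) -> list[float]:
    """Saturating-pulse times within a phase: ``first, first+interval, ...``
    while they fall inside the phase.

    ``pulse_schedule(60, 7, 12) -> [7, 19, 31, 43, 55]`` and
    ``pulse_schedule(88, 11, 26) -> [11, 37, 63]`` are the Kautsky light and
    dark schedules.
    """
    if phase_duration_s <= 0 or first_s <= 0 or interval_s <= 0:
        raise ProtocolError(
            "pulse_schedule arguments must be positive, got "
            f"({phase_duration_s}, {first_s}, {interval_s})"
        )
    times = []
    t = first_s
    while t <= phase_duration_s:
        times.append(t)
        t += interval_s
    return times


@dataclass(frozen=True)
class Phase:
    """One protocol phase: kind, duration and actinic level, plus the pulse
    times (seconds from phase start)."""

    name: str  # {dark, actinic, dark_recovery}
    duration_s: float
    actinic_ppfd: float
    pulse_times_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in {"dark", "actinic", "dark_recovery"}:
            raise ProtocolError(f"unknown phase name {self.name!r}")
        if self.duration_s <= 0:
            raise ProtocolError(f"phase {self.name!r} duration must be > 0")
        if self.actinic_ppfd < 0:
            raise ProtocolError("actinic_ppfd must be >= 0")
        for t in self.pulse_times_s:
            if not 0 <= t <= self.duration_s:
                raise ProtocolError(
                    f"pulse at {t} s falls outside phase {self.name!r} "
                    f"(duration {self.duration_s} s)"
                )


@dataclass(frozen=True)
class ProtocolSpec:
    protocol_id: str  # {LC, KC, OJIP, YIELD}
    phases: tuple[Phase, ...]
    measuring_ppfd: float = MEASURING_PPFD
    saturating_ppfd: float = SATURATING_PPFD
    ojip_pulse_ppfd: float = OJIP_PULSE_PPFD

    def __post_init__(self) -> None:
        if not self.phases:
            raise ProtocolError("protocol needs at least one phase")

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    def phase_start_s(self, index: int) -> float:
        return sum(p.duration_s for p in self.phases[:index])

    def absolute_pulse_times(self) -> list[tuple[str, float]]:
        """(phase name, absolute pulse time) pairs in chronological order."""
        out = []
        for i, phase in enumerate(self.phases):
            t0 = self.phase_start_s(i)
            for t in phase.pulse_times_s:
                out.append((phase.name, t0 + t))
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ProtocolSpec":
        raw = json.loads(text)
        phases = tuple(Phase(**p) for p in raw.pop("phases"))
        return cls(phases=phases, **raw)


def kautsky_protocol(
    dark_s: float = 5.0,
    dark_pulse_s: float = 2.0,
    actinic_s: float = 60.0,
    recovery_s: float = 88.0,
    actinic_ppfd: float = KC_ACTINIC_PPFD,
) -> ProtocolSpec:
    """The Kautsky induction-and-relaxation programme: an initial dark super
    pulse, 60 s of actinic light with five pulses (7 s then 12 s intervals),
    and 88 s dark recovery with three pulses (11 s then 26 s intervals)."""
    return ProtocolSpec(
        protocol_id="KC",
        phases=(
            Phase("dark", dark_s, 0.0, (dark_pulse_s,)),
            Phase("actinic", actinic_s, actinic_ppfd,
                  tuple(pulse_schedule(actinic_s, 7.0, 12.0))),
            Phase("dark_recovery", recovery_s, 0.0,
                  tuple(pulse_schedule(recovery_s, 11.0, 26.0))),
        ),
    )


def light_curve_protocol(
    steps_ppfd: tuple[float, ...] = LC_STEPS_PPFD,
    dark_s: float = 5.0,
    dark_pulse_s: float = 2.0,
    step_s: float = 20.0,
) -> ProtocolSpec:
    """Rapid-light-curve programme: a dark super pulse, then one actinic phase
    per PPFD step with a saturating pulse near the end of each step."""
    if not steps_ppfd:
        raise ProtocolError("light curve needs at least one PPFD step")
    if any(s < 0 for s in steps_ppfd):
        raise ProtocolError("PPFD steps must be >= 0")
    if any(b < a for a, b in zip(steps_ppfd, steps_ppfd[1:])):
        raise ProtocolError(f"PPFD steps must be non-decreasing, got {steps_ppfd}")
    phases = [Phase("dark", dark_s, 0.0, (dark_pulse_s,))]
    for ppfd in steps_ppfd:
        phases.append(Phase("actinic", step_s, float(ppfd), (step_s - 1.0,)))
    return ProtocolSpec(protocol_id="LC", phases=tuple(phases))


def ojip_protocol(duration_s: float = 2.0) -> ProtocolSpec:
    """Fast-transient programme: one continuous saturating red pulse."""
    return ProtocolSpec(
        protocol_id="OJIP",
        phases=(Phase("actinic", duration_s, OJIP_PULSE_PPFD),),
    )
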