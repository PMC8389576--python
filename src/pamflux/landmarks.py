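"""Landmark extraction: named fluorescence levels from raw traces.

The quenching analysis needs F0 and FM from the dark-adapted state, the
pulse maxima FM′ (light) and FM″ (dark recovery) with their pre-pulse
steady levels F(t), and the dark-recovery minimum F0″.  The fast-transient
analysis needs the O, J, I, P levels plus the 0.3 ms sample that feeds the
initial-slope statistic M0.

Conventions (all configurable):

* FM-type landmarks are the *maximum* within a pulse window — the
  saturating plateau can be short.
* pre-pulse F(t) is the *median* of the 0.5 s before the pulse — robust to
  measuring-light noise.
* F0″ is the *minimum* of measuring-light samples in the dark recovery
  (the recovery drifts downward as quenching relaxes).
* O defaults to 50 µs, the conventional fast-transient origin; instruments
  that report O at 0.5 ms are accommodated by passing ``timepoints_ms``
  starting at 0.5.
* OJIP levels are read by linear interpolation on a log-time axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExtractionError, ValidationError
from .protocols import PULSE_WINDOW_S, ProtocolSpec, pulse_schedule  # noqa: F401
from .trace import FluorescenceTrace

#: conventional origin of the fast transient, milliseconds
DEFAULT_O_TIME_MS = 0.05
#: default O/J/I/P extraction times, milliseconds
DEFAULT_OJIP_TIMEPOINTS_MS = (DEFAULT_O_TIME_MS, 2.0, 30.0, 1000.0)
#: the early-slope sample used by M0, milliseconds
M0_TIME_MS = 0.3


@dataclass(frozen=True)
class PulseLandmark:
    """One saturating pulse: absolute time, pulse maximum, and (where
    defined) the pre-pulse steady fluorescence."""

    time_s: float
    fm: float
    ft: float | None = None


@dataclass(frozen=True)
class KCLandmarks:
    """Named levels of a Kautsky induction/relaxation experiment."""

    F0: float
    FM: float
    light_pulses: tuple[PulseLandmark, ...]  # FM'_i with pre-pulse F(t)_i
    dark_pulses: tuple[PulseLandmark, ...]   # FM''_j
    F0_double_prime: float

    def __post_init__(self) -> None:
        vals = [self.F0, self.FM, self.F0_double_prime]
        vals += [p.fm for p in self.light_pulses + self.dark_pulses]
        vals += [p.ft for p in self.light_pulses if p.ft is not None]
        if any(v <= 0 for v in vals):
            raise ValidationError("all KC landmarks must be > 0")
        if self.FM < self.F0:
            raise ValidationError(f"FM={self.FM} < F0={self.F0}")
        for p in self.light_pulses:
            if p.ft is not None and p.fm < p.ft:
                raise ValidationError(
                    f"pulse at {p.time_s} s: FM'={p.fm} < F(t)={p.ft}")

    @property
    def last_light_pulse(self) -> PulseLandmark:
        return self.light_pulses[-1]

    @property
    def last_dark_pulse(self) -> PulseLandmark:
        return self.dark_pulses[-1]

    def rescaled(self, c: float) -> "KCLandmarks":
        return KCLandmarks(
            self.F0 * c, self.FM * c,
            tuple(PulseLandmark(p.time_s, p.fm * c,
                                None if p.ft is None else p.ft * c)
                  for p in self.light_pulses),
            tuple(PulseLandmark(p.time_s, p.fm * c) for p in self.dark_pulses),
            self.F0_double_prime * c,
        )


@dataclass(frozen=True)
class OJIPLandmarks:
    """O, J, I, P levels of the fast transient plus the 0.3 ms sample."""

    FO: float
    F300: float
    FJ: float
    FI: float
    FP: float
    timepoints_ms: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (self.FO, self.F300, self.FJ, self.FI, self.FP)):
            raise ValidationError("all OJIP landmarks must be > 0")
        if self.FP < self.FO:
            raise ValidationError(f"FP={self.FP} < FO={self.FO}")

    def rescaled(self, c: float) -> "OJIPLandmarks":
        return OJIPLandmarks(self.FO * c, self.F300 * c, self.FJ * c,
                             self.FI * c, self.FP * c, self.timepoints_ms)


@dataclass(frozen=True)
class LCLandmarks:
    """Dark-adapted F0/FM plus one (PPFD, F(t), FM′) triple per actinic step."""

    F0: float
    FM: float
    steps: tuple[tuple[float, PulseLandmark], ...]  # (ppfd, pulse)


# ---------------------------------------------------------------------------
# helpers

def _pulse_window_values(trace: FluorescenceTrace, t_pulse: float,
                         window_s: float = PULSE_WINDOW_S) -> np.ndarray:
    sel = (trace.pulse_flag
           & (trace.time_s >= t_pulse - 1e-9)
           & (trace.time_s < t_pulse + window_s))
    vals = trace.fluorescence[sel]
    if vals.size == 0:
        raise ExtractionError(f"pulse at {t_pulse:g} s not found in trace")
    return vals


def _pre_pulse_steady(trace: FluorescenceTrace, t_pulse: float,
                      window_s: float = 0.5) -> float:
    sel = (~trace.pulse_flag
           & (trace.time_s >= t_pulse - window_s)
           & (trace.time_s < t_pulse))
    vals = trace.fluorescence[sel]
    if vals.size == 0:
        raise ExtractionError(
            f"no measuring-light samples in the {window_s} s before the "
            f"pulse at {t_pulse:g} s")
    return float(np.median(vals))


def extract_kc_landmarks(
    trace: FluorescenceTrace,
    protocol: ProtocolSpec,
    pre_pulse_window_s: float = 0.5,
) -> KCLandmarks:
    """Locate every protocol pulse in the trace and read off the KC levels.

    F0 is the median of dark measuring-light samples before the first pulse;
    FM the maximum of the initial dark super pulse; each light-phase pulse
    yields (F(t)ᵢ, FM′ᵢ); each dark-recovery pulse yields FM″ⱼ; F0″ is the
    minimum measuring-light sample of the dark-recovery phase.
    """
    pulses = protocol.absolute_pulse_times()
    dark = [t for name, t in pulses if name == "dark"]
    light = [t for name, t in pulses if name == "actinic"]
    dark_rec = [t for name, t in pulses if name == "dark_recovery"]
    if len(dark) != 1 or not light or not dark_rec:
        raise ExtractionError(
            "Kautsky protocol must define one dark pulse, >=1 actinic pulse "
            "and >=1 dark-recovery pulse")

    t_first = dark[0]
    sel_dark = ~trace.pulse_flag & (trace.time_s < t_first)
    if not sel_dark.any():
        raise ExtractionError(
            f"no dark measuring-light samples before the first pulse at {t_first:g} s")
    f0 = float(np.median(trace.fluorescence[sel_dark]))
    fm = float(np.max(_pulse_window_values(trace, t_first)))

    light_lm = tuple(
        PulseLandmark(t, float(np.max(_pulse_window_values(trace, t))),
                      _pre_pulse_steady(trace, t, pre_pulse_window_s))
        for t in light)
    dark_lm = tuple(
        PulseLandmark(t, float(np.max(_pulse_window_values(trace, t))))
        for t in dark_rec)

    i_rec = [i for i, p in enumerate(protocol.phases) if p.name == "dark_recovery"][0]
    t0_rec = protocol.phase_start_s(i_rec)
    sel_rec = (~trace.pulse_flag & (trace.time_s >= t0_rec)
               & (trace.time_s < t0_rec + protocol.phases[i_rec].duration_s))
    if not sel_rec.any():
        raise ExtractionError("no measuring-light samples in the dark-recovery phase")
    f0pp = float(np.min(trace.fluorescence[sel_rec]))

    return KCLandmarks(F0=f0, FM=fm, light_pulses=light_lm,
                       dark_pulses=dark_lm, F0_double_prime=f0pp)


def extract_ojip_landmarks(
    trace: FluorescenceTrace,
    timepoints_ms: tuple[float, float, float, float] = DEFAULT_OJIP_TIMEPOINTS_MS,
) -> OJIPLandmarks:
    """Read the O, J, I levels by log-time interpolation; P is the trace
    maximum; the 0.3 ms sample is always extracted for M0."""
    if len(timepoints_ms) != 4:
        raise ValidationError("timepoints_ms must be (O, J, I, P) in ms")
    t_ms = trace.time_s * 1000.0
    needed = [*timepoints_ms[:3], M0_TIME_MS]
    for tp in needed:
        if not (t_ms[0] - 1e-9 <= tp <= t_ms[-1] + 1e-9):
            raise ExtractionError(
                f"requested time {tp} ms outside trace span "
                f"[{t_ms[0]:.4g}, {t_ms[-1]:.4g}] ms")
    if timepoints_ms[3] > t_ms[-1] + 1e-9:
        raise ExtractionError(
            f"requested P time {timepoints_ms[3]} ms beyond trace end {t_ms[-1]:.4g} ms")
    logt = np.log(t_ms)
    interp = lambda tp: float(np.interp(np.log(tp), logt, trace.fluorescence))
    fo, fj, fi = (interp(tp) for tp in timepoints_ms[:3])
    f300 = interp(M0_TIME_MS)
    fp = float(np.max(trace.fluorescence))
    return OJIPLandmarks(FO=fo, F300=f300, FJ=fj, FI=fi, FP=fp,
                         timepoints_ms=tuple(timepoints_ms))


def extract_lc_landmarks(
    trace: FluorescenceTrace,
    protocol: ProtocolSpec,
    pre_pulse_window_s: float = 0.5,
) -> LCLandmarks:
    """Dark F0/FM plus per-step (PPFD, F(t), FM′) from a light-curve trace."""
    pulses = protocol.absolute_pulse_times()
    dark = [t for name, t in pulses if name == "dark"]
    if len(dark) != 1:
        raise ExtractionError("light-curve protocol needs exactly one dark pulse")
    t_first = dark[0]
    sel_dark = ~trace.pulse_flag & (trace.time_s < t_first)
    if not sel_dark.any():
        raise ExtractionError("no dark samples before the initial pulse")
    f0 = float(np.median(trace.fluorescence[sel_dark]))
    fm = float(np.max(_pulse_window_values(trace, t_first)))
    steps = []
    for i, phase in enumerate(protocol.phases):
        if phase.name != "actinic":
            continue
        t0 = protocol.phase_start_s(i)
        for tp in phase.pulse_times_s:
            t_abs = t0 + tp
            steps.append((
                phase.actinic_ppfd,
                PulseLandmark(t_abs,
                              float(np.max(_pulse_window_values(trace, t_abs))),
                              _pre_pulse_steady(trace, t_abs, pre_pulse_window_s)),
            ))
    if not steps:
        raise ExtractionError("light-curve protocol defines no actinic pulses")
    return LCLandmarks(F0=f0, FM=fm, steps=tuple(steps))
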