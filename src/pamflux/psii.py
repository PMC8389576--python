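"""PSII quantum yields, light-curve rETR, and Kautsky quenching coefficients.

Standard PAM conventions:

* ``ϕ_max = (FM − F0)/FM`` (dark-adapted), ``ϕ_PSII = (FM′ − F(t))/FM′``
  (light-adapted).
* ``NPQ = (FM − FM′)/FM′`` (Stern–Volmer); ``qI = (FM − FM″)/FM″`` from the
  last dark-recovery pulse (sustained, photoinhibitory quenching);
  ``qE = NPQ − qI`` so the decomposition NPQ = qE + qI holds exactly.
* ``F0′ = F0 / (FV/FM + F0/FM′)`` — the light-phase minimal-fluorescence
  estimator used when F0′ is not measured directly.
* ``qP = (FM′ − F(t))/(FM′ − F0′)`` (puddle model),
  ``qL = qP·F0′/F(t)`` (lake model).
* ``PQ = 1 − qP`` — the closed-centre fraction; lower values mean more open
  centres, i.e. more efficient photochemical quenching.  The convention is
  recorded in output metadata because instrument vendors differ here.
* ``rETR = etr_factor·ϕ_PSII·PPFD`` with the two-photosystem partition
  factor 0.5 by default and no absorptance term ("relative" ETR).

Negative NPQ/qE values (FM′ > FM, incomplete relaxation) are retained with
a warning rather than clipped — clipping would bias group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DegenerateDataError, ValidationError
from .landmarks import KCLandmarks, LCLandmarks

DEFAULT_ETR_FACTOR = 0.5

#: conventions serialized with every coefficient table
CONVENTIONS = {
    "NPQ": "(FM - FM')/FM'",
    "qI": "(FM - FM'')/FM'' at the last dark-recovery pulse",
    "qE": "NPQ - qI",
    "F0_prime": "F0 / (FV/FM + F0/FM')",
    "qP": "(FM' - F(t))/(FM' - F0')",
    "qL": "qP * F0'/F(t)",
    "PQ": "1 - qP (closed-centre fraction)",
    "rETR": "etr_factor * phi_PSII * PPFD, etr_factor=0.5, no absorptance",
    "steady_state_pulse": "last actinic-phase pulse",
}


@dataclass(frozen=True)
class YieldValue:
    phi: float
    adapted_state: str  # {light, dark}


@dataclass(frozen=True)
class LightCurvePoint:
    ppfd: float
    phi_psii: float
    rETR: float


@dataclass(frozen=True)
class QuenchingCoefficients:
    NPQ: float
    qE: float
    qI: float
    qP: float
    qL: float
    PQ: float
    F0_prime: float

    def as_dict(self) -> dict[str, float]:
        return {"NPQ": self.NPQ, "qE": self.qE, "qI": self.qI,
                "qP": self.qP, "qL": self.qL, "PQ": self.PQ}


@dataclass(frozen=True)
class DailyLightIntegral:
    dli: float  # mol photons m^-2 d^-1
    ppfd: float
    photoperiod_h: float


def phi_psii(ft: float, fmp: float) -> YieldValue:
    """Effective PSII yield of a light-adapted sample, (FM′ − F(t))/FM′."""
    if fmp <= 0:
        raise ValidationError(f"FM' must be > 0, got {fmp}")
    if ft <= 0:
        raise ValidationError(f"F(t) must be > 0, got {ft}")
    if ft > fmp:
        warnings.warn(
            f"F(t)={ft} exceeds FM'={fmp}; negative yield retained",
            stacklevel=2)
    return YieldValue(phi=(fmp - ft) / fmp, adapted_state="light")


def phi_max(f0: float, fm: float) -> YieldValue:
    """Maximum dark-adapted PSII yield, (FM − F0)/FM; requires FM > F0."""
    if f0 <= 0:
        raise ValidationError(f"F0 must be > 0, got {f0}")
    if fm <= f0:
        raise DegenerateDataError(
            f"non-inductive sample: FM={fm} must exceed F0={f0}")
    return YieldValue(phi=(fm - f0) / fm, adapted_state="dark")


def daily_light_integral(ppfd: float, photoperiod_h: float) -> DailyLightIntegral:
    """Mol photons m⁻² d⁻¹ received at constant PPFD over the photoperiod."""
    if ppfd < 0:
        raise ValidationError(f"ppfd must be >= 0, got {ppfd}")
    if not 0 <= photoperiod_h <= 24:
        raise ValidationError(
            f"photoperiod_h must be in [0, 24], got {photoperiod_h}")
    return DailyLightIntegral(
        dli=ppfd * photoperiod_h * 3600.0 * 1e-6,
        ppfd=ppfd, photoperiod_h=photoperiod_h)


def retr(phi: float, ppfd: float, etr_factor: float = DEFAULT_ETR_FACTOR) -> LightCurvePoint:
    """Relative electron transport rate, etr_factor·ϕ·PPFD."""
    if ppfd < 0:
        raise ValidationError(f"ppfd must be >= 0, got {ppfd}")
    if not 0 <= phi <= 1:
        raise ValidationError(f"phi_psii must be in [0, 1], got {phi}")
    if etr_factor <= 0:
        raise ValidationError(f"etr_factor must be > 0, got {etr_factor}")
    return LightCurvePoint(ppfd=ppfd, phi_psii=phi, rETR=etr_factor * phi * ppfd)


def light_curve(
    landmarks: LCLandmarks, etr_factor: float = DEFAULT_ETR_FACTOR
) -> list[LightCurvePoint]:
    """One rETR point per actinic step from the step's (F(t), FM′) pair."""
    points = []
    for ppfd, pulse in landmarks.steps:
        y = phi_psii(pulse.ft, pulse.fm)
        points.append(retr(y.phi, ppfd, etr_factor))
    return points


def npq(fm: float, fmp: float) -> float:
    """Stern–Volmer non-photochemical quenching (FM − FM′)/FM′."""
    if fm <= 0 or fmp <= 0:
        raise ValidationError(f"FM and FM' must be > 0, got {fm}, {fmp}")
    value = (fm - fmp) / fmp
    if value < 0:
        warnings.warn(f"FM'={fmp} exceeds FM={fm}: negative NPQ retained",
                      stacklevel=2)
    return value


def qi(fm: float, fmpp: float) -> float:
    """Photoinhibitory quenching (FM − FM″)/FM″, FM″ from the last
    dark-recovery pulse."""
    if fm <= 0 or fmpp <= 0:
        raise ValidationError(f"FM and FM'' must be > 0, got {fm}, {fmpp}")
    return (fm - fmpp) / fmpp


def qe(npq_value: float, qi_value: float) -> float:
    """Energy-dependent quenching, NPQ − qI (negative values retained with a
    warning: relaxation can overshoot in noisy data)."""
    value = npq_value - qi_value
    if value < 0:
        warnings.warn(f"qE = {value:.4g} < 0 (qI exceeds NPQ); retained",
                      stacklevel=2)
    return value


def f0_prime(f0: float, fm: float, fmp: float) -> float:
    """Estimated minimal fluorescence in light, F0/(FV/FM + F0/FM′)."""
    if not fm > f0 > 0:
        raise ValidationError(f"need FM > F0 > 0, got F0={f0}, FM={fm}")
    if fmp <= 0:
        raise ValidationError(f"FM' must be > 0, got {fmp}")
    denom = (fm - f0) / fm + f0 / fmp
    if denom <= 0:
        raise DegenerateDataError(f"F0' denominator {denom} <= 0")
    return f0 / denom


def qp(ft: float, fmp: float, f0p: float) -> float:
    """Puddle-model photochemical quenching (FM′ − F(t))/(FM′ − F0′)."""
    if fmp <= f0p:
        raise DegenerateDataError(
            f"degenerate landmarks: FM'={fmp} must exceed F0'={f0p}")
    return (fmp - ft) / (fmp - f0p)


def ql(qp_value: float, f0p: float, ft: float) -> float:
    """Lake-model photochemical quenching qP·F0′/F(t)."""
    if ft <= 0:
        raise ValidationError(f"F(t) must be > 0, got {ft}")
    return qp_value * f0p / ft


def pq_coefficient(qp_value: float) -> float:
    """Closed-centre fraction 1 − qP; lower values mean more efficient
    photochemical quenching."""
    return 1.0 - qp_value


def kc_coefficients(
    landmarks: KCLandmarks, pulse_index: int = -1
) -> QuenchingCoefficients:
    """All quenching coefficients of one Kautsky experiment.

    NPQ, qE, qP, qL and PQ refer to the actinic-phase pulse selected by
    ``pulse_index`` (default: the last, closest to steady state); qI comes
    from the last dark-recovery pulse.  NPQ = qE + qI holds exactly by
    construction.
    """
    ss = landmarks.light_pulses[pulse_index]
    npq_value = npq(landmarks.FM, ss.fm)
    qi_value = qi(landmarks.FM, landmarks.last_dark_pulse.fm)
    f0p = f0_prime(landmarks.F0, landmarks.FM, ss.fm)
    qp_value = qp(ss.ft, ss.fm, f0p)
    return QuenchingCoefficients(
        NPQ=npq_value,
        qE=qe(npq_value, qi_value),
        qI=qi_value,
        qP=qp_value,
        qL=ql(qp_value, f0p, ss.ft),
        PQ=pq_coefficient(qp_value),
        F0_prime=f0p,
    )
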