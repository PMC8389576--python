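"""JIP-test specific energy fluxes and the performance index.

From the O/J/P levels of the fast transient (plus the 0.3 ms sample) the
JIP framework derives per-reaction-centre energy fluxes:

* ``phi_P0 = FV/FP`` — maximum trapping yield (TR0/ABS), identical to the
  dark-adapted ϕ_max;
* ``VJ = (FJ − FO)/FV`` — relative variable fluorescence at J;
* ``psi_0 = 1 − VJ`` — probability a trapped exciton moves an electron past
  QA⁻;
* ``M0 = 4·(F300 − FO)/FV`` per ms — initial slope of the normalized rise;
* ``TR0/RC = M0/VJ``, ``ABS/RC = TR0/RC ÷ phi_P0``,
  ``ET0/RC = TR0/RC · psi_0``, ``DI0/RC = ABS/RC − TR0/RC``;
* ``PI_ABS = (phi_P0·VJ/M0) · phi_P0/(1−phi_P0) · psi_0/(1−psi_0)`` — the
  performance index on absorption basis.  (Its first factor is RC/ABS =
  γ/(1−γ) under the standard VJ-based RC estimate.)

All quantities are ratios of fluorescence levels, hence invariant under a
uniform rescaling of the signal.  FI is carried through for completeness
but enters none of the implemented fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .landmarks import DEFAULT_OJIP_TIMEPOINTS_MS, OJIPLandmarks, extract_ojip_landmarks
from .trace import FluorescenceTrace

_EPS = 1e-12


@dataclass(frozen=True)
class JIPCoefficients:
    FV: float
    phi_P0: float
    VJ: float
    psi_0: float
    M0: float  # per ms
    ABS_RC: float
    TR0_RC: float
    ET0_RC: float
    DI0_RC: float
    PI_ABS: float

    def as_dict(self) -> dict[str, float]:
        return {"ABS/RC": self.ABS_RC, "TR0/RC": self.TR0_RC,
                "ET0/RC": self.ET0_RC, "DI0/RC": self.DI0_RC,
                "PI_ABS": self.PI_ABS}


def jip_coefficients(lm: OJIPLandmarks) -> JIPCoefficients:
    """Specific energy fluxes and PI_ABS from one set of OJIP landmarks."""
    if not lm.FP > lm.FO > 0:
        raise ValidationError(f"need FP > FO > 0, got FO={lm.FO}, FP={lm.FP}")
    if not (lm.FO <= lm.F300 <= lm.FP):
        raise ValidationError(
            f"F300={lm.F300} must lie between FO={lm.FO} and FP={lm.FP}")
    fv = lm.FP - lm.FO
    phi_p0 = fv / lm.FP
    vj = (lm.FJ - lm.FO) / fv
    if vj <= _EPS or vj >= 1 - _EPS:
        raise DegenerateDataError(
            f"degenerate transient: VJ={vj:.6g} must lie strictly in (0, 1)")
    if phi_p0 <= _EPS or phi_p0 >= 1 - _EPS:
        raise DegenerateDataError(
            f"degenerate transient: phi_P0={phi_p0:.6g} must lie strictly in (0, 1)")
    psi0 = 1.0 - vj
    m0 = 4.0 * (lm.F300 - lm.FO) / fv
    if m0 <= _EPS:
        raise DegenerateDataError(f"degenerate transient: M0={m0:.6g} <= 0")
    tr0_rc = m0 / vj
    abs_rc = tr0_rc / phi_p0
    et0_rc = tr0_rc * psi0
    di0_rc = abs_rc - tr0_rc
    pi_abs = (phi_p0 * vj / m0) * (phi_p0 / (1.0 - phi_p0)) * (psi0 / (1.0 - psi0))
    return JIPCoefficients(FV=fv, phi_P0=phi_p0, VJ=vj, psi_0=psi0, M0=m0,
                           ABS_RC=abs_rc, TR0_RC=tr0_rc, ET0_RC=et0_rc,
                           DI0_RC=di0_rc, PI_ABS=pi_abs)


@dataclass
class BatchFailure:
    plant_id: str
    error: str


def jip_batch(
    traces: dict[str, FluorescenceTrace],
    groups: dict[str, tuple[str, float]],
    timepoints_ms: tuple[float, float, float, float] = DEFAULT_OJIP_TIMEPOINTS_MS,
) -> tuple[pd.DataFrame, list[BatchFailure]]:
    """Per-plant JIP coefficients for a batch of OJIP traces.

    ``groups`` maps plant_id -> (cytotype, photoperiod_h).  Plants whose
    extraction or flux computation fails are reported by id, never silently
    dropped.  Returns (long coefficient table, failures).
    """
    rows, failures = [], []
    for plant_id, trace in traces.items():
        try:
            lm = extract_ojip_landmarks(trace, timepoints_ms)
            coef = jip_coefficients(lm)
        except Exception as exc:  # noqa: BLE001 - aggregated into the report
            failures.append(BatchFailure(plant_id, f"{type(exc).__name__}: {exc}"))
            continue
        cyto, pp = groups[plant_id]
        for name, value in coef.as_dict().items():
            rows.append((plant_id, cyto, pp, name, value))
    table = pd.DataFrame(
        rows, columns=["plant_id", "cytotype", "photoperiod_h", "coefficient", "value"])
    return table, failures
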