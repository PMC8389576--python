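"""Synthetic PAM-fluorometry study generator.

Generates fluorescence traces for a full factorial design — cytotypes
{2x, 4x, 6x_29, 6x_35} × photoperiods {10 h, 16.5 h} — with known
ground-truth coefficient values, so the whole landmark → coefficient →
statistics pipeline can be validated without instrument data.

Generative models (deliberately the simplest forms that reproduce the
qualitative shapes a fluorometer records):

* **OJIP transient** — a sum of three saturating exponentials,
  ``F(t) = F0 + FV · Σₖ wₖ (1 − exp(−t/τₖ))`` with strictly increasing τₖ
  and weights summing to 1; ``FV = F0·ϕ/(1−ϕ)`` so that the dark-adapted
  maximum yield ``(FM−F0)/FM`` equals the prescribed ``phi_max_true``.
* **Kautsky induction/relaxation** — first-order NPQ kinetics,
  ``NPQ(t) = npq_ss·(1−exp(−t/τ_N))`` in actinic light, relaxing in the dark
  toward the sustained (photoinhibitory) component ``npq_ss·qi_frac`` with
  the same τ_N; ``FM′(t) = FM/(1+NPQ(t))``.  The closed-centre fraction
  c(t) relaxes from 0 toward ``closed_frac_ss`` (τ_c) in light and back to 0
  in darkness.  Measuring-light fluorescence is
  ``F(t) = F0′(t) + (FM′(t) − F0′(t))·c(t)`` with F0′ from the same
  estimator the analysis uses; saturating-pulse windows emit FM′(t).
* **Light curve** — the saturating-exponential response
  ``rETR(I) = retr_max·(1 − exp(−α·I/retr_max))`` with the effective yield
  ``ϕ(I) = rETR(I)/(f·I)``; ``α ≤ ϕ_max·f`` guarantees ϕ(0⁺) ≤ ϕ_max.

Noise is multiplicative log-normal with a prescribed coefficient of
variation (fluorescence is strictly positive, so additive Gaussian noise is
inappropriate).  One RNG stream per plant is derived by stable hashing of
``(seed, plant_id)``, so a plant's traces do not depend on generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .protocols import (
    LC_STEPS_PPFD,
    OJIP_PULSE_PPFD,
    PULSE_WINDOW_S,
    ProtocolSpec,
    kautsky_protocol,
    light_curve_protocol,
    ojip_protocol,
)
from .trace import FluorescenceTrace

CYTOTYPES = ("2x", "4x", "6x_29", "6x_35")
PHOTOPERIODS_H = (10.0, 16.5)


@dataclass(frozen=True, order=True)
class GroupFactor:
    """One cell of the factorial design."""

    cytotype: str
    photoperiod_h: float

    def __post_init__(self) -> None:
        if self.cytotype not in CYTOTYPES:
            raise ValidationError(
                f"cytotype {self.cytotype!r} not in {CYTOTYPES}")
        if self.photoperiod_h not in PHOTOPERIODS_H:
            raise ValidationError(
                f"photoperiod_h {self.photoperiod_h!r} not in {PHOTOPERIODS_H}")

    @property
    def label(self) -> str:
        return f"{self.cytotype}@{self.photoperiod_h:g}h"


@dataclass(frozen=True)
class GroupTruth:
    """True coefficient-generating parameters of one design cell.

    ``alpha_lc = None`` means the maximal admissible initial light-curve
    slope ``phi_max_true · etr_factor`` (yield at vanishing light equals the
    dark-adapted maximum).
    """

    phi_max_true: float = 0.80
    npq_ss: float = 0.8
    qi_frac: float = 0.25
    closed_frac_ss: float = 0.30
    retr_max: float = 40.0
    alpha_lc: float | None = None
    ojip_taus_ms: tuple[float, float, float] = (0.25, 4.0, 120.0)
    ojip_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_max_true < 1.0:
            raise ValidationError(
                f"phi_max_true must be in (0, 1), got {self.phi_max_true}")
        if self.npq_ss < 0 or self.retr_max < 0:
            raise ValidationError("npq_ss and retr_max must be >= 0")
        if not 0.0 <= self.qi_frac <= 1.0:
            raise ValidationError(f"qi_frac must be in [0, 1], got {self.qi_frac}")
        if not 0.0 <= self.closed_frac_ss <= 1.0:
            raise ValidationError(
                f"closed_frac_ss must be in [0, 1], got {self.closed_frac_ss}")
        if self.alpha_lc is not None and self.alpha_lc < 0:
            raise ValidationError("alpha_lc must be >= 0")
        taus = self.ojip_taus_ms
        if len(taus) != 3 or not (taus[0] < taus[1] < taus[2]):
            raise ValidationError(
                f"ojip_taus_ms must be three strictly increasing values, got {taus}")
        w = self.ojip_weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValidationError(
                f"ojip_weights must be non-negative and sum to 1, got {w}")


def default_group_truth() -> dict[GroupFactor, GroupTruth]:
    """Synthetic preset mimicking the study's qualitative pattern — not
    estimates from any measured dataset.

    The 6x_35 clone carries a depressed maximum yield (further lowered by
    photoperiod extension); 4x and 6x_35 quench non-photochemically more
    strongly, and the extended photoperiod raises NPQ in 2x and 6x_29 toward
    them; the closed-centre fraction (the PQ coefficient) is lower in the
    polyploids except 6x_35.
    """
    base = GroupTruth()
    per_cyto = {
        "2x": dict(phi_max_true=0.80, npq_ss=0.60, qi_frac=0.18,
                   closed_frac_ss=0.35, retr_max=40.0),
        "4x": dict(phi_max_true=0.80, npq_ss=1.00, qi_frac=0.28,
                   closed_frac_ss=0.25, retr_max=32.0),
        "6x_29": dict(phi_max_true=0.80, npq_ss=0.55, qi_frac=0.15,
                      closed_frac_ss=0.20, retr_max=40.0),
        "6x_35": dict(phi_max_true=0.74, npq_ss=1.00, qi_frac=0.30,
                      closed_frac_ss=0.35, retr_max=36.0),
    }
    truth: dict[GroupFactor, GroupTruth] = {}
    for cyto, kw in per_cyto.items():
        for pp in PHOTOPERIODS_H:
            cell = dict(kw)
            if pp == 16.5:
                if cyto in ("2x", "6x_29"):
                    cell["npq_ss"] = 0.95  # extension raises NPQ toward 4x level
                if cyto == "6x_35":
                    cell["phi_max_true"] = 0.70
                    cell["closed_frac_ss"] = 0.40
                else:
                    cell["closed_frac_ss"] = max(0.05, cell["closed_frac_ss"] - 0.05)
            truth[GroupFactor(cyto, pp)] = replace(base, **cell)
    return truth


@dataclass
class SimulationParams:
    """Study-level simulation configuration."""

    groups: dict[GroupFactor, GroupTruth] = field(default_factory=default_group_truth)
    f0_base: float = 500.0
    noise_cv: float = 0.04
    n_per_cell: int = 5
    seed: int = 0
    tau_npq_s: float = 10.0
    tau_closed_s: float = 3.0
    etr_factor: float = 0.5
    lc_steps_ppfd: tuple[float, ...] = LC_STEPS_PPFD

    def __post_init__(self) -> None:
        if self.f0_base <= 0:
            raise ValidationError(f"f0_base must be > 0, got {self.f0_base}")
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_per_cell < 1:
            raise ValidationError(f"n_per_cell must be >= 1, got {self.n_per_cell}")
        if self.etr_factor <= 0:
            raise ValidationError("etr_factor must be > 0")
        for g in self.groups:
            if not isinstance(g, GroupFactor):
                raise ValidationError("groups must be keyed by GroupFactor")

    def truth_for(self, group: GroupFactor) -> GroupTruth:
        try:
            return self.groups[group]
        except KeyError:
            raise ValidationError(f"no truth parameters for group {group.label}") from None

    def alpha_for(self, truth: GroupTruth) -> float:
        alpha = (truth.phi_max_true * self.etr_factor
                 if truth.alpha_lc is None else truth.alpha_lc)
        if alpha > truth.phi_max_true * self.etr_factor + 1e-12:
            raise ValidationError(
                f"alpha_lc={alpha} exceeds phi_max_true*etr_factor="
                f"{truth.phi_max_true * self.etr_factor}")
        return alpha


# ---------------------------------------------------------------------------
# RNG plumbing

def plant_rng(seed: int, plant_id: str, stream: str = "") -> np.random.Generator:
    """One reproducible stream per (seed, plant, purpose), insensitive to
    the order in which plants are generated."""
    words = [int(seed) & 0x7FFFFFFF, zlib.crc32(plant_id.encode())]
    if stream:
        words.append(zlib.crc32(stream.encode()))
    return np.random.default_rng(np.random.SeedSequence(words))


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative factors with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


# ---------------------------------------------------------------------------
# Design

def make_design(
    n_per_cell: int | dict = 5, seed: int = 0
) -> list[tuple[str, GroupFactor]]:
    """Enumerate plants for the factorial design.

    ``n_per_cell`` is either one integer for every cell or a mapping
    ``{(cytotype, photoperiod_h): n}`` (GroupFactor keys also accepted),
    emulating the study's unbalanced 3–11 plants per cell.  Deterministic
    given ``seed`` (the seed is recorded but the enumeration itself is
    order-stable).
    """
    cells: dict[GroupFactor, int] = {}
    for cyto in CYTOTYPES:
        for pp in PHOTOPERIODS_H:
            g = GroupFactor(cyto, pp)
            if isinstance(n_per_cell, dict):
                n = n_per_cell.get(g, n_per_cell.get((cyto, pp)))
                if n is None:
                    raise ValidationError(f"n_per_cell map missing cell {g.label}")
            else:
                n = n_per_cell
            if not 1 <= int(n) <= 1000:
                raise ValidationError(
                    f"n_per_cell must be in [1, 1000], got {n} for {g.label}")
            cells[g] = int(n)
    design = []
    counter = 0
    for g, n in cells.items():
        for _ in range(n):
            counter += 1
            pid = f"P{counter:03d}_{g.cytotype}_{g.photoperiod_h:g}h"
            design.append((pid, g))
    return design


# ---------------------------------------------------------------------------
# Closed-form models (shared by simulation, ground truth, and test oracles)

def ojip_model(t_s: np.ndarray, truth: GroupTruth, f0: float) -> np.ndarray:
    """Noise-free OJIP transient at times ``t_s`` (seconds)."""
    t = np.asarray(t_s, dtype=float)
    fv = f0 * truth.phi_max_true / (1.0 - truth.phi_max_true)
    taus = np.asarray(truth.ojip_taus_ms, dtype=float) / 1000.0
    w = np.asarray(truth.ojip_weights, dtype=float)
    rise = (w[None, :] * (1.0 - np.exp(-t[:, None] / taus[None, :]))).sum(axis=1)
    return f0 + fv * rise


@dataclass(frozen=True)
class KautskyModel:
    """Closed-form Kautsky kinetics for one plant; evaluable at any time.

    Times are absolute trace times; the actinic phase runs on
    ``[t_on, t_off)``.
    """

    truth: GroupTruth
    params: SimulationParams
    t_on: float
    t_off: float

    @property
    def f0(self) -> float:
        return self.params.f0_base

    @property
    def fm(self) -> float:
        return self.f0 / (1.0 - self.truth.phi_max_true)

    def npq(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = self.params.tau_npq_s
        ss, qi = self.truth.npq_ss, self.truth.qi_frac
        light = ss * (1.0 - np.exp(-np.clip(t - self.t_on, 0, None) / tau))
        npq_off = ss * (1.0 - np.exp(-(self.t_off - self.t_on) / tau))
        floor = ss * qi
        dark = floor + (npq_off - floor) * np.exp(
            -np.clip(t - self.t_off, 0, None) / tau)
        return np.where(t < self.t_on, 0.0, np.where(t < self.t_off, light, dark))

    def closed_fraction(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = self.params.tau_closed_s
        ss = self.truth.closed_frac_ss
        light = ss * (1.0 - np.exp(-np.clip(t - self.t_on, 0, None) / tau))
        c_off = ss * (1.0 - np.exp(-(self.t_off - self.t_on) / tau))
        dark = c_off * np.exp(-np.clip(t - self.t_off, 0, None) / tau)
        return np.where(t < self.t_on, 0.0, np.where(t < self.t_off, light, dark))

    def fm_prime(self, t: np.ndarray) -> np.ndarray:
        return self.fm / (1.0 + self.npq(t))

    def f0_prime(self, t: np.ndarray) -> np.ndarray:
        # same estimator the analysis applies: F0' = F0/(FV/FM + F0/FM')
        phi = self.truth.phi_max_true
        return self.f0 / (phi + self.f0 / self.fm_prime(t))

    def measuring_fluorescence(self, t: np.ndarray) -> np.ndarray:
        f0p = self.f0_prime(t)
        fmp = self.fm_prime(t)
        return f0p + (fmp - f0p) * self.closed_fraction(t)

    def phi_psii(self, t: float) -> float:
        """Effective PSII yield a pulse at time t would report."""
        fmp = float(self.fm_prime(np.array([t]))[0])
        ft = float(self.measuring_fluorescence(np.array([t]))[0])
        return (fmp - ft) / fmp


def retr_response(ppfd, retr_max: float, alpha: float):
    """Saturating light-response curve ``retr_max·(1 − exp(−α·I/retr_max))``."""
    ppfd = np.asarray(ppfd, dtype=float)
    if retr_max <= 0:
        return alpha * ppfd
    return retr_max * (1.0 - np.exp(-alpha * ppfd / retr_max))


def fit_retr_response(ppfd, retr) -> tuple[float, float]:
    """Least-squares fit of the saturating response; the simulator's own
    consistency check.  Returns (retr_max, alpha)."""
    from scipy.optimize import curve_fit

    ppfd = np.asarray(ppfd, float)
    retr = np.asarray(retr, float)
    p0 = (max(retr.max(), 1e-6), max(retr[0] / max(ppfd[0], 1e-9), 1e-6))
    popt, _ = curve_fit(lambda i, rm, a: retr_response(i, rm, a), ppfd, retr, p0=p0,
                        maxfev=10000)
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Trace simulators

def _apply_noise(f: np.ndarray, rng: np.random.Generator, cv: float) -> np.ndarray:
    return f * _lognormal_noise(rng, cv, len(f))


def _trace_meta(group: GroupFactor, plant_id: str, seed: int) -> dict:
    return {
        "plant_id": plant_id,
        "cytotype": group.cytotype,
        "photoperiod_h": group.photoperiod_h,
        "seed": seed,
    }


def simulate_ojip(
    params: SimulationParams,
    group: GroupFactor,
    seed: int | None = None,
    plant_id: str = "plant",
    n_points: int = 120,
    t_min_s: float = 1e-5,
    t_max_s: float = 2.0,
) -> FluorescenceTrace:
    """Fast fluorescence transient under a continuous 3000 µmol saturating
    pulse, sampled log-uniformly on [10 µs, 2 s]."""
    if n_points < 60:
        raise ValidationError("OJIP needs >= 60 sample points")
    seed = params.seed if seed is None else seed
    truth = params.truth_for(group)
    t = np.geomspace(t_min_s, t_max_s, n_points)
    f = ojip_model(t, truth, params.f0_base)
    rng = plant_rng(seed, plant_id, "ojip")
    f = _apply_noise(f, rng, params.noise_cv)
    return FluorescenceTrace(
        time_s=t,
        fluorescence=f,
        actinic_ppfd=np.full_like(t, OJIP_PULSE_PPFD),
        pulse_flag=np.ones_like(t, dtype=bool),
        protocol_id="OJIP",
        meta=_trace_meta(group, plant_id, seed),
    )


def _protocol_grid(protocol: ProtocolSpec, dt: float = 0.1, pulse_hz: float = 1000.0):
    """Sampling grid: a uniform measuring-light grid with 1 kHz bursts inside
    saturating-pulse windows.  Returns (time, actinic, pulse_flag)."""
    total = protocol.total_duration_s
    base = np.arange(int(round(total / dt))) * dt
    windows = [(t, t + PULSE_WINDOW_S) for _, t in protocol.absolute_pulse_times()]
    in_pulse = np.zeros_like(base, dtype=bool)
    for a, b in windows:
        in_pulse |= (base >= a) & (base < b)
    times = [base[~in_pulse]]
    flags = [np.zeros(np.count_nonzero(~in_pulse), dtype=bool)]
    for a, b in windows:
        tp = a + np.arange(int(round((b - a) * pulse_hz))) / pulse_hz
        times.append(tp)
        flags.append(np.ones(len(tp), dtype=bool))
    t = np.concatenate(times)
    flag = np.concatenate(flags)
    order = np.argsort(t, kind="stable")
    t, flag = t[order], flag[order]
    actinic = np.zeros_like(t)
    for i, phase in enumerate(protocol.phases):
        a = protocol.phase_start_s(i)
        sel = (t >= a) & (t < a + phase.duration_s)
        actinic[sel] = phase.actinic_ppfd
    actinic[flag] = protocol.saturating_ppfd
    return t, actinic, flag


def kautsky_model_for(
    params: SimulationParams, group: GroupFactor, protocol: ProtocolSpec | None = None
) -> KautskyModel:
    protocol = kautsky_protocol() if protocol is None else protocol
    _check_kc_protocol(protocol)
    t_on = protocol.phase_start_s(1)
    return KautskyModel(params.truth_for(group), params, t_on,
                        t_on + protocol.phases[1].duration_s)


def _check_kc_protocol(protocol: ProtocolSpec) -> None:
    names = [p.name for p in protocol.phases]
    if names != ["dark", "actinic", "dark_recovery"]:
        from .errors import ProtocolError

        raise ProtocolError(
            f"Kautsky protocol needs phases dark/actinic/dark_recovery, got {names}")
    if len(protocol.phases[0].pulse_times_s) != 1:
        from .errors import ProtocolError

        raise ProtocolError("Kautsky dark pre-phase needs exactly one super pulse")


def simulate_kautsky(
    params: SimulationParams,
    group: GroupFactor,
    protocol: ProtocolSpec | None = None,
    seed: int | None = None,
    plant_id: str = "plant",
) -> FluorescenceTrace:
    """Kautsky induction (actinic light) and dark-relaxation trace with
    saturating pulses per the protocol schedule."""
    protocol = kautsky_protocol() if protocol is None else protocol
    seed = params.seed if seed is None else seed
    model = kautsky_model_for(params, group, protocol)
    t, actinic, flag = _protocol_grid(protocol)
    f = np.where(flag, model.fm_prime(t), model.measuring_fluorescence(t))
    rng = plant_rng(seed, plant_id, "kc")
    f = _apply_noise(f, rng, params.noise_cv)
    return FluorescenceTrace(t, f, actinic, flag, "KC",
                             meta=_trace_meta(group, plant_id, seed))


def simulate_light_curve(
    params: SimulationParams,
    group: GroupFactor,
    steps: tuple[float, ...] | None = None,
    seed: int | None = None,
    plant_id: str = "plant",
) -> FluorescenceTrace:
    """Rapid light curve: dark super pulse, then one actinic step per PPFD
    with a saturating pulse near the end of each step.

    Within step k the measuring fluorescence is held at
    ``FM′(t)·(1 − ϕ(I_k))`` so the pulse pair (F(t), FM′) reports exactly the
    model's effective yield ϕ(I_k); FM′ follows the same first-order NPQ
    kinetics as the Kautsky simulator, driven by cumulative light exposure.
    """
    steps = tuple(params.lc_steps_ppfd if steps is None else steps)
    seed = params.seed if seed is None else seed
    protocol = light_curve_protocol(steps)
    truth = params.truth_for(group)
    alpha = params.alpha_for(truth)
    f0 = params.f0_base
    fm = f0 / (1.0 - truth.phi_max_true)
    t_on = protocol.phase_start_s(1)  # light starts after the dark phase

    t, actinic, flag = _protocol_grid(protocol)
    tau = params.tau_npq_s
    npq = truth.npq_ss * (1.0 - np.exp(-np.clip(t - t_on, 0, None) / tau))
    npq[t < t_on] = 0.0
    fmp = fm / (1.0 + npq)

    # effective yield at each sample's actinic level (dark -> phi_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        retr = retr_response(actinic, truth.retr_max, alpha)
        phi = np.where(actinic > 0, retr / (params.etr_factor * np.maximum(actinic, 1e-12)),
                       truth.phi_max_true)
    # during the dark phase the plant sits at F0; pulses emit FM'(t)
    f_meas = np.where(t < t_on, f0, fmp * (1.0 - phi))
    f = np.where(flag, fmp, f_meas)
    rng = plant_rng(seed, plant_id, "lc")
    f = _apply_noise(f, rng, params.noise_cv)
    tr = FluorescenceTrace(t, f, actinic, flag, "LC",
                           meta=_trace_meta(group, plant_id, seed))
    tr.meta["steps_ppfd"] = list(map(float, steps))
    return tr


# ---------------------------------------------------------------------------
# Ground truth

#: controlled coefficient vocabulary, shared with trace_io
def coefficient_names(lc_steps=LC_STEPS_PPFD) -> list[str]:
    return (
        ["phi_PSII", "phi_max", "NPQ", "qE", "qI", "qP", "qL", "PQ"]
        + [f"rETR@{s:g}" for s in lc_steps]
        + ["ABS/RC", "TR0/RC", "ET0/RC", "DI0/RC", "PI_ABS"]
    )


def true_coefficients(
    params: SimulationParams,
    group: GroupFactor,
    protocol: ProtocolSpec | None = None,
    o_time_ms: float = 0.05,
    jip_timepoints_ms: tuple[float, float, float] = (2.0, 30.0, 1000.0),
) -> dict[str, float]:
    """Ground-truth coefficient values implied by the generative model.

    Kautsky coefficients refer to the protocol's last actinic-phase pulse
    (steady state) and last dark-recovery pulse, matching the analysis
    convention; JIP fluxes are computed from the noise-free transient at the
    standard extraction times.
    """
    from .jip import jip_coefficients
    from .landmarks import OJIPLandmarks

    protocol = kautsky_protocol() if protocol is None else protocol
    truth = params.truth_for(group)
    model = kautsky_model_for(params, group, protocol)

    light_pulses = [model.t_on + t for t in protocol.phases[1].pulse_times_s]
    dark_pulses = [model.t_off + t for t in protocol.phases[2].pulse_times_s]
    t_ss, t_dark = light_pulses[-1], dark_pulses[-1]

    npq_ss_val = float(model.npq(np.array([t_ss]))[0])
    qi_val = float(model.npq(np.array([t_dark]))[0])
    c_ss = float(model.closed_fraction(np.array([t_ss]))[0])
    f0p = float(model.f0_prime(np.array([t_ss]))[0])
    fmp = float(model.fm_prime(np.array([t_ss]))[0])
    ft = f0p + (fmp - f0p) * c_ss
    qp = 1.0 - c_ss
    out = {
        "phi_max": truth.phi_max_true,
        "phi_PSII": model.phi_psii(t_ss),
        "NPQ": npq_ss_val,
        "qI": qi_val,
        "qE": npq_ss_val - qi_val,
        "qP": qp,
        "qL": qp * f0p / ft,
        "PQ": 1.0 - qp,
    }

    alpha = params.alpha_for(truth)
    for s in params.lc_steps_ppfd:
        out[f"rETR@{s:g}"] = float(retr_response(s, truth.retr_max, alpha))

    times_ms = np.array([o_time_ms, 0.3, *jip_timepoints_ms])
    f = ojip_model(times_ms / 1000.0, truth, params.f0_base)
    fp = params.f0_base / (1.0 - truth.phi_max_true)  # asymptote
    lm = OJIPLandmarks(FO=f[0], F300=f[1], FJ=f[2], FI=f[3], FP=fp,
                       timepoints_ms=(o_time_ms, *jip_timepoints_ms))
    jip = jip_coefficients(lm)
    out.update({
        "ABS/RC": jip.ABS_RC, "TR0/RC": jip.TR0_RC,
        "ET0/RC": jip.ET0_RC, "DI0/RC": jip.DI0_RC, "PI_ABS": jip.PI_ABS,
    })
    return out


# ---------------------------------------------------------------------------
# Whole-study simulation

@dataclass
class StudyData:
    """Simulated study: per-plant traces for all three protocols plus the
    ground-truth coefficient table (long format)."""

    design: list[tuple[str, GroupFactor]]
    traces: dict[str, dict[str, FluorescenceTrace]]
    ground_truth: pd.DataFrame


def simulate_study(params: SimulationParams, seed: int | None = None) -> StudyData:
    """One LC, KC and OJIP trace per plant of the factorial design, plus the
    table of true coefficient values.  The ground truth depends only on the
    group parameters (identical across seeds); the noise realization depends
    on the seed."""
    seed = params.seed if seed is None else seed
    design = make_design(params.n_per_cell, seed)
    traces: dict[str, dict[str, FluorescenceTrace]] = {}
    rows = []
    for plant_id, group in design:
        traces[plant_id] = {
            "LC": simulate_light_curve(params, group, seed=seed, plant_id=plant_id),
            "KC": simulate_kautsky(params, group, seed=seed, plant_id=plant_id),
            "OJIP": simulate_ojip(params, group, seed=seed, plant_id=plant_id),
        }
        for name, value in true_coefficients(params, group).items():
            rows.append((plant_id, group.cytotype, group.photoperiod_h, name, value))
    gt = pd.DataFrame(
        rows, columns=["plant_id", "cytotype", "photoperiod_h", "coefficient", "value"])
    return StudyData(design=design, traces=traces, ground_truth=gt)


# ---------------------------------------------------------------------------
# Coefficient-scale generators for statistical studies

def simulate_coefficient_table(
    params: SimulationParams,
    coefficient: str,
    seed: int,
    cv: float = 0.10,
) -> pd.DataFrame:
    """Per-plant coefficient values drawn around the group truths with
    multiplicative log-normal between-plant variability (default cv 10%).
    The fast route for Monte-Carlo studies of the statistics stage."""
    design = make_design(params.n_per_cell, seed)
    truth_by_group = {g: true_coefficients(params, g) for g in
                      {grp for _, grp in design}}
    rows = []
    for plant_id, group in design:
        mu = truth_by_group[group][coefficient]
        rng = plant_rng(seed, plant_id, f"coef:{coefficient}")
        value = mu * _lognormal_noise(rng, cv, 1)[0]
        rows.append((plant_id, group.cytotype, group.photoperiod_h, coefficient, value))
    return pd.DataFrame(
        rows, columns=["plant_id", "cytotype", "photoperiod_h", "coefficient", "value"])


def simulate_null_table(
    coefficient: str = "phi_max",
    mean: float = 0.8,
    sd: float = 0.05,
    n_per_cell: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Global-null dataset: every design cell shares one mean; Gaussian
    within-cell noise.  Used to study familywise type-I behaviour."""
    return _gaussian_table(coefficient, {}, mean, sd, n_per_cell, seed)


def simulate_shifted_table(
    coefficient: str = "phi_max",
    mean: float = 0.8,
    sd: float = 0.05,
    shift_sd: float = 3.0,
    shifted_cytotype: str = "6x_35",
    n_per_cell: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """One cytotype depressed by ``shift_sd`` residual standard deviations in
    both photoperiods — the qualitative single-deviant-clone pattern."""
    shifts = {c: (-shift_sd * sd if c == shifted_cytotype else 0.0) for c in CYTOTYPES}
    return _gaussian_table(coefficient, shifts, mean, sd, n_per_cell, seed)


def _gaussian_table(coefficient, cyto_shift, mean, sd, n_per_cell, seed):
    design = make_design(n_per_cell, seed)
    rows = []
    for plant_id, group in design:
        rng = plant_rng(seed, plant_id, f"gauss:{coefficient}")
        value = mean + cyto_shift.get(group.cytotype, 0.0) + rng.normal(0.0, sd)
        rows.append((plant_id, group.cytotype, group.photoperiod_h, coefficient, value))
    return pd.DataFrame(
        rows, columns=["plant_id", "cytotype", "photoperiod_h", "coefficient", "value"])
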