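# Methods

## The measurement model

A PAM fluorometer separates three light fields: a weak measuring beam
(0.09 µmol photons m⁻² s⁻¹) that excites fluorescence without driving
photochemistry, actinic light that does drive it, and brief saturating
("super") pulses (2400 µmol m⁻² s⁻¹; 3000 µmol m⁻² s⁻¹ red light for the
fast transient) that transiently close all PSII centres and reveal the
maximal fluorescence of the current state (F_M dark-adapted, F_M′ in
light, F_M″ in dark recovery).  All analyses start from a
`FluorescenceTrace`: time, fluorescence, actinic level, and a pulse flag.

Three instrument programmes are modelled:

* **LC** — dark super pulse, then actinic steps at 10, 20, 50, 100, 300,
  500 µmol m⁻² s⁻¹ (20 s each here) with one pulse near each step's end;
* **KC** — dark super pulse, 60 s actinic light at 300 µmol m⁻² s⁻¹ with
  five pulses (first at 7 s, then every 12 s), then 88 s darkness with
  three pulses (first at 11 s, then every 26 s);
* **OJIP** — one continuous saturating pulse, sampled log-uniformly on
  [10 µs, 2 s] (120 points).

## The synthetic generator

No public generative model exists for these instruments, so the generator
uses the simplest kinetics that reproduce the qualitative shapes:

* **OJIP**: F(t) = F_0 + F_V·Σₖ wₖ(1 − e^(−t/τₖ)), three exponentials with
  τ = (0.25, 4, 120) ms and weights (0.5, 0.3, 0.2) by default — enough to
  produce distinct J and I inflections on a log-time axis.  F_V is forced
  to F_0·ϕ/(1−ϕ) so that (F_M − F_0)/F_M equals the prescribed ϕ_max.
* **KC**: Stern–Volmer quenching with first-order kinetics.  NPQ rises to
  its steady state npq_ss with τ_N = 10 s in light and relaxes in darkness
  toward the sustained component npq_ss·q_i_frac with the same τ_N;
  F_M′(t) = F_M/(1 + NPQ(t)).  The closed-centre fraction c(t) relaxes
  toward closed_frac_ss with τ_c = 3 s (and to 0 in darkness); measuring
  fluorescence is F(t) = F_0′(t) + (F_M′ − F_0′)·c(t), with F_0′ computed
  by the *same estimator the analysis uses* so that the noise-free
  round trip is exact by construction.
* **LC**: the saturating response rETR(I) = rETR_max(1 − e^(−αI/rETR_max)),
  with α capped at ϕ_max·f so the yield at vanishing light equals ϕ_max;
  each step's measuring fluorescence is set to F_M′(t)(1 − ϕ(I)) so the
  pulse pair reports exactly the model yield.

Noise is multiplicative log-normal with unit mean and a prescribed CV
(default 4%); fluorescence is strictly positive, which additive Gaussian
noise would violate.  Each plant draws from an RNG stream keyed by a
stable hash of (seed, plant_id, purpose), so traces are independent of
generation order and bit-reproducible.

The default group preset encodes the qualitative pattern the design is
meant to exhibit — a depressed ϕ_max in the 6x_35 clone (0.74 at 10 h,
0.70 at 16.5 h, 0.80 elsewhere), stronger NPQ in 4x and 6x_35 with the
extended photoperiod raising 2x and 6x_29 toward them, and a lower
closed-centre fraction in the polyploids except 6x_35.  These numbers are
a synthetic preset, not estimates from measured data.  Between-plant
spread for the statistics-level simulators is log-normal with CV 10% (or
Gaussian with a prescribed SD for the calibration scenarios); no published
within-group variances exist to calibrate against, so these are declared
defaults.  Consequently the passing recovery tests demonstrate the
*internal* consistency of extraction and formulas, not instrument realism:
real traces carry drift, detector nonlinearity and biological kinetics far
richer than first-order.

## Landmark conventions

F_M-type landmarks take the **maximum** inside each 0.8 s pulse window
(plateaus can be short); pre-pulse F(t) is the **median** of the 0.5 s
before the pulse (robust to measuring noise); F_0 is the median of the
dark samples before the first pulse; F_0″ the **minimum** of the
dark-recovery measuring samples (recovery drifts downward).  OJIP levels
are linear interpolations on log-time.  The O point defaults to 50 µs, the
conventional transient origin; devices that report O at 0.5 ms are served
by passing `timepoints_ms=(0.5, 2, 30, 1000)` — the choice propagates
consistently into the JIP formulas and is never silently assumed.  The
0.3 ms sample is always extracted because M_0 needs it.

## Coefficient conventions

All definitions are the standard PAM-literature forms (see README for the
formulas) and are serialized with every coefficient table
(`pamflux.psii.CONVENTIONS`): steady-state quenching is read from the
**last** actinic-phase pulse (55 s — earlier pulses are still inducing),
qI from the **last** dark pulse, so NPQ = qE + qI holds exactly by
construction.  Negative NPQ/qE (F_M′ > F_M in noisy data) are retained
with warnings, never clipped — clipping would bias group means upward.
The PQ coefficient is reported as 1 − qP (closed-centre fraction,
"lower is better"); vendor conventions differ here, and the definition
travels with the output metadata.  rETR uses f = 0.5 and no absorptance
("relative" ETR).

## Statistics

Each coefficient is analyzed as a two-factor fixed-effects model with
interaction.  Sums of squares are **Type II** by default (computed by
nested-model residual comparisons; Type III via sum-to-zero contrasts is
available) — appropriate for the unbalanced 3–11-plants-per-cell design
when both main effects and the interaction are reported.  Post-hoc
comparisons run over the 8 cytotype × photoperiod cell means against the
pooled residual mean square (a factor-marginal mode exists but is not the
default, since the letters annotate per-cell boxes):

* **Tukey–Kramer**: pair (i, j) significant iff
  |m_i − m_j| > q(1−α; k, ν)·√(MSE/2·(1/n_i + 1/n_j));
* **Duncan MRT**: means sorted; a span of p ordered means uses the
  protection level α_p = 1 − (1−α)^(p−1) and q(1−α_p; p, ν), tested
  step-down with the classical blocking rule (pairs inside a
  non-significant span are retained).  Duncan returns decisions, not exact
  p-values; pairs carry the interval (0, α_p] or (α_p, 1].

The studentized-range CDF/quantile comes from scipy's numerical
integration and root-finding; quantiles are memoized because the
Monte-Carlo studies reuse a handful of (p, k, ν) triples.  Exact per-pair
Tukey p-values integrate the same density and can be switched off
(`with_p=False`) in simulation loops where only decisions matter.

Letters use insert-and-absorb: start from one group holding all cells;
each significant pair splits every group containing both; subset groups
are absorbed.  The construction guarantees cells share a letter iff
non-significant (a runtime tripwire re-checks every output); minimal
letter count is attempted, not guaranteed.  No multiplicity correction is
applied across coefficients, and that fact is recorded in the output
metadata.

The Duncan-never-misses-Tukey property is asserted over balanced random
datasets: with Kramer standard errors under strong imbalance, a blocked
outer span whose endpoint cells are small can in principle shield a pair
that Tukey rejects; the classical containment statement assumes equal n.

## Problem sizes and numerical choices

The demo study runs 5 plants/cell (40 plants, 120 traces, ~30 s); the
validation studies use 1 plant/cell noise-free for recovery and 200
replicates at 8 plants/cell for the letter-rate calibrations — sizes
chosen so each driver finishes in well under a minute while the binomial
noise on a 200-replicate rate (±2–3 percentage points) stays small against
the 90%/95% expectations.  Degenerate inputs fail loudly rather than
produce numbers: zero residual variance, V_J ∈ {0, 1}, ϕ_P0 ∈ {0, 1},
F_M ≤ F_0, empty design cells and missing pulse windows all raise typed
errors naming the offending cell, time or file line.  Ties in the letter
ordering follow descending means; group order in the design is the fixed
cytotype × photoperiod enumeration.

## Known limitations

* The generator's first-order kinetics cannot produce state transitions,
  photoinhibition dynamics beyond a constant sustained fraction, or the
  K band and double-peak pathologies of stressed transients.
* qI is read at a fixed dark-recovery time (63 s); true photoinhibitory
  quenching relaxes over tens of minutes and is underestimated by design.
* The light-curve analysis reports rETR at the measured steps only; no
  saturating-curve fit is part of the coefficient table (the fit exists as
  the simulator's own consistency check).
* Import of vendor binary exports is out of scope; the TSV dialect is an
  emulation, not a reverse-engineered format.
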