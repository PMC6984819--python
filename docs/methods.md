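# Methods

This note records the scientific assumptions, parameter choices and known
limitations of the package, in the spirit of a model-description section.

## Reversal potentials (biophys)

The GABA-A receptor conducts both chloride and bicarbonate; its reversal
potential is computed with the anionic Goldman–Hodgkin–Katz voltage
equation, internal concentrations in the numerator:

    E_GABA-A = (RT/F) · ln( ([Cl⁻]ᵢ + p·[HCO₃⁻]ᵢ) / ([Cl⁻]ₒ + p·[HCO₃⁻]ₒ) )

with p = P_HCO₃/P_Cl = 0.1. At p = 0 this reduces exactly to the chloride
Nernst potential, which is asserted as a property test.

Intracellular bicarbonate is rarely measured directly. It is derived by
Henderson–Hasselbalch assuming CO₂ equilibrates freely across the
membrane, so [HCO₃⁻]ᵢ = [HCO₃⁻]ₒ·10^(pHᵢ−pHₒ); with 24 mM external
bicarbonate and a 7.4/7.0 pH pair this gives 9.55 mM. Ignoring
bicarbonate entirely would shift the computed reversal ≈ 2.5 mV
hyperpolarized.

Bath chloride is the sum over the slicing-solution recipe: 130 (NaCl) +
3.5 (KCl) + 2×1 (CaCl₂) = 135.5 mM; a storage-solution variant with 3 mM
CaCl₂ (139.5 mM Cl⁻) is available as a preset but is not the default,
since recordings reference the standard bath. The physiological pipette
carries 8 mM Cl⁻ and 126 mM K⁺; the elevated-chloride pipette replaces
K-gluconate with 130 mM KCl (138 mM Cl⁻), which moves E_GABA-A to ≈ +0.2
mV and makes GABA-A responses robustly depolarizing — the configuration
used to screen for self-innervation in current clamp.

Temperature is an explicit argument of every operation (no hidden
default); the recording range is 36–37 °C and both printed reversal values
(−73 mV GABA-A, −95 mV potassium/AHP) round correctly anywhere in it.
Physical constants are CODATA R and F via scipy.

Two reversal presets exist and are never mixed implicitly: `methods`
(−73/−95 mV, the values computed from the recipes, used when converting
recorded currents) and `simulation` (−78.89/−90 mV, the values used in the
conductance-injection protocols, where membrane-potential readings carry a
junction-potential correction). The ~6 mV gap between the computed and
protocol E_GABA-A is not derivable from the recipes; the package therefore
exposes the reversal as a per-protocol parameter rather than guessing a
correction.

## Conductance extraction (traces)

The autaptic conductance is isolated by pharmacological subtraction:
pointwise means of at least six control sweeps and six sweeps in a GABA-A
blocker are subtracted (control − blocker), and the difference current is
divided by the driving force V_h − E_GABA-A. The AHP conductance comes
from the blocker average itself (the blocker removes only the GABA-A
component) against the potassium reversal. All times are referenced to t0,
the minimum of the action-current transient (earliest sample on ties;
traces whose inward deflection never exceeds 100 pA are rejected as
containing no spike).

Peak location uses a 0.1 ms boxcar-smoothed copy of the trace to avoid
single-sample noise peaks; the reported amplitude is the raw sample at
that location. Default search windows are 0–15 ms post-t0 for the autaptic
peak and 0–5 ms for the AHP peak; the windows are configurable because the
two outward currents overlap and are separated only by their timing.

Decay kinetics are measured by a monoexponential fit
A·exp(−(t−t_peak)/τ) from the detected peak, initialized by log-linear
regression and refined by nonlinear least squares; the default window runs
to five initial-estimate time constants. Fits with r² below 0.85 (and
non-convergent fits) are returned flagged, never silently dropped — poor
fits are data too. A 1000-replicate Monte-Carlo experiment at 5% amplitude
noise puts the tau estimator's error spread at ~0.9% (sd), far inside the
10% recovery tolerance asserted by the acceptance tests. A genuinely
biexponential decay (taus 1 and 20 ms, equal weights) fits a single
exponential with r² ≈ 0.94 — measurably worse than clean data (> 0.999)
but above the 0.85 default threshold, so threshold choice, not the flag
mechanism, decides such cases.

Passive properties come from current-clamp step families: R_m from the
steady-state deflection (last-50 ms mean) regressed through the origin
against injected current, τ_m from a monoexponential fit of the charging
transient, C_m = τ_m/R_m, E_m from the pre-step baseline. Steps shorter
than five time constants yield a flagged estimate.

Sweeps occasionally contain a second "escape" action current; sweeps whose
post-t0 window contains a second inward transient above the floor can be
excluded from averaging (`exclude_escape_after_ms`), mimicking trial
curation. Minimum event counts (6 for subtraction averages, 12 for
synaptic conductance averages) are enforced and only overridable by an
explicit force flag that warns.

Sign and unit conventions throughout: outward current positive; ms, pA,
nS, pF, MΩ, mV. With pA and mV, Ohm's law yields nS with no conversion
factor.

## Single-compartment model (model)

The membrane is one compartment, C dV/dt = −g_leak(V−E_leak) −
Σ gᵢ(t)(V−Eᵢ), integrated from V(0) = E_leak = −68 mV. Spike currents are
deliberately absent: the model addresses the milliseconds *after* a spike,
and all waveform timings are referenced to where the action-current peak
(t0) would be. Default parameters are the median human pvBC: C_m 43.81 pF,
g_leak 5.44 nS (R_m 183.83 MΩ); AHP 17.48 nS peaking 0.78 ms after t0,
decay 5.43 ms, reversal −90 mV; autapse 3.79 nS peaking at 2.31 ms, decay
4.18 ms, reversal −78.89 mV; EPSP 10 nS, rise 0.2 ms, decay 1.2 ms,
reversal 0 mV.

Waveform shape: only peak, time-to-peak and decay tau are measured, so the
rise shape is a modeling choice. A difference of exponentials normalized
to the stated peak is used, with the rise tau solved numerically (brentq)
so the maximum falls at the measured time-to-peak; it degrades gracefully
to an instantaneous rise when the requested time-to-peak is not attainable
(≥ decay tau, possible for extreme sampled parameter combinations).

Onset convention: recorded conductances switch on when the action current
ends, not at its peak. The t0-to-onset gap is not a printed quantity; the
package uses 0.3 ms — half the measured human action-current width
(0.536 ms) — as the default `ahp_onset_offset_ms`, configurable in every
builder. EPSP delays are always quoted relative to t0.

Integrator: fixed-step classical Runge–Kutta on the caller's dt grid
(default 0.01 ms), with conductances evaluated analytically at half-steps.
A fixed-step scheme keeps runs deterministic and makes the dt-convergence
check meaningful (EPSP peak changes < 0.1% when dt halves from 0.01 ms); a
stiff-capable adaptive mode (LSODA, absolute tolerance 1e−6 mV) is
retained as an independent cross-check and agrees to < 1e−3 mV on the
reference protocols. Every simulation asserts the maximum principle — the
voltage stays inside the envelope of the reversal potentials present
(1e−3 mV numerical slack) — and the tests additionally check charge
balance, C·ΔV = ∫I dt, to trapezoid accuracy.

EPSP amplitude is measured onset-to-peak **against the EPSP-free
trajectory**: the protocol simulates each condition twice, with and
without the EPSP branch, and takes the maximum of the voltage difference
after onset. This removes the decaying post-spike baseline, which would
otherwise contaminate onset-to-peak measurements at short delays. The
suppression ratio at each delay is amp(with autapse)/amp(autapse peak
forced to 0). With E_GABA-A pinned exactly at E_leak the autapse passes
zero current at rest yet the ratio stays below 1 — the pure shunting
signature, asserted as an acceptance property.

Per-cell parameter tables for the simulated cohort are not published (only
summary statistics), so the package ships the median "reference cell" plus
a cohort sampler (below); exact reproduction of the published per-cell
spread is not attempted.

## In-silico dynamic clamp (dynclamp)

The original protocols inject computed conductances into living neurons;
reproducing them in software requires a spike generator. The surrogate is
an exponential integrate-and-fire neuron (spike-initiation term
g_leak·Δ_T·exp((V−V_T)/Δ_T)) with an intrinsic per-spike AHP conductance
increment. Its parameters — V_T −55 mV, Δ_T 1.5 mV, reset −62 mV,
refractory 1 ms, AHP increment 20 nS decaying with 2.5 ms — are
**calibrated fixtures, not biological claims**: they were chosen once so
that the baseline (0 nS) doublet protocol fires two spikes ~6.3 ms apart,
inside the observed 5.6–6.6 ms interval range. Only orderings are claimed:
second-spike probability non-increasing and interspike delay
non-decreasing in the injected autaptic conductance, and selective
suppression of the post-spike (not pre-spike) EPSP. The experimental
probabilities themselves depend on living-cell excitability and are not
reproduction targets.

Injected commands follow the recorded protocol values: EPSCs decay with
1.25 ms at 0 mV reversal; the doublet-evoking EPSC is 15 nS with 5 ms
decay (within the 8–21 nS / 4–5 ms protocol ranges; its 0.2 ms rise is
adopted from the EPSP kinetics since the protocol does not state one); the
triggered IPSC has 1–10 nS peak, 5 ms decay, −78 mV reversal, fires on the
upward −20 mV crossing with a 1 ms delay, and a 1 ms trigger refractory
guards against double triggers on noisy upswings. The doublet surrogate
rests at −74.5 mV (inside the −72…−77 mV protocol range, near E_GABA-A so
suppression is shunting-dominated). The pre/post protocol pairs the
printed 20 nS/0.5 ms suprathreshold step with a −63 mV resting potential —
the depolarized end of that protocol's −63…−78 mV range — because a 20 nS
conductance step cannot ignite the surrogate from the median −74.5 mV
rest.

Cycle-to-cycle variability comes from Ornstein–Uhlenbeck current noise
with 1 ms correlation time; its amplitude is specified as the stationary
membrane-voltage standard deviation it produces (default 1 mV) and
converted internally via σ_I = σ_V·g_leak·√((τ_noise+τ_m)/τ_noise). The
same per-cycle noise streams are replayed at every autapse level, pairing
the comparison so that level differences reflect the injected inhibition
alone; identical seeds give bit-identical outcomes. Integration is forward
Euler at 0.02 ms, adequate for a noisy threshold model whose claims are
orderings.

## Synthetic data (synth)

The generators emulate the study conditions with known ground truth.
Voltage-clamp pairs: control sweeps carry an action-current transient, the
AHP outward current, and the autaptic outward current; blocker sweeps omit
the autaptic component; Gaussian trace noise of 5 pA; holding −43 mV
against the `methods` reversals. Defaults are the printed medians (autapse
3.79 nS / 2.31 ms / 4.18 ms; AHP 17.48 nS / 0.78 ms / 5.43 ms; R_m 183.83
MΩ, C_m 43.81 pF).

Two shape choices matter and are deliberate:

* The conductance transients rise as sin² and decay as a *pure*
  monoexponential from the peak. The published decay constants are defined
  by a monoexponential fit from the peak, and a difference-of-exponentials
  waveform decays slower than its tail tau for several ms after the peak
  (a from-peak fit on one returns ~15% more than the tail constant), which
  would make "recover the generating tau" an ill-posed target.
* The action-current artifact is a Gaussian pulse of the printed 0.536 ms
  full width at half amplitude. It is scenery for the t0 detector, and a
  compact pulse — like the real biphasic action current — has decayed to
  nothing by the AHP peak 0.78 ms later; an exponential-tailed transient
  of the same width would still contribute ~−230 pA there and corrupt the
  AHP measurement by design rather than by physics.

Escape-spike transients (a second, smaller inward pulse 2–6 ms after t0)
are available with configurable probability but default to off: at the
6-sweeps-per-condition study scale, excluding a contaminated sweep drops
the count below the mandatory minimum of six and the pipeline refuses —
the experimenters simply recorded more trials, which the generator caller
can do too.

What the generator does *not* emulate: series-resistance and filtering
artifacts, blocker wash-in time courses, correlated (non-white) recording
noise, biphasic action-current shapes, and trial-to-trial latency jitter.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the stated noise model, not robustness to every property of
real recordings.

Cohorts: per-cell parameters are drawn from distributions matched to the
printed statistics — normal for mean ± sem quantities with the sem scaled
to a between-cell sd via the printed n (human n = 13–14, mouse n = 11),
log-normal solved from median/quartiles for the right-skewed ones —
truncated at physiological bounds by rejection sampling. The mouse autapse
delay-to-peak and capacitance are not published; the human delay and a
capacitance matched to the human membrane time constant at the mouse input
resistance stand in. The published G_ahp–G_leak correlation (Pearson
r = 0.671) can be imposed through a Gaussian copula that leaves both
marginals intact; it is off by default because the full joint structure of
the parameters is unknown.

## Problem sizes

Default test and protocol sizes: 200 seeded replicates for the recovery
rate; 10⁴ cells for cohort moments; 20 cycles per autapse level (5 levels)
for the doublet protocol; 18 delays × 4 simulations for the suppression
curve at dt 0.01 ms. The full suite runs in well under a minute on one
core; the sizes were chosen as the smallest that make the asserted
statistics stable across seeds.

## Known limitations

* Single compartment: no dendritic filtering, no spatial segregation of
  autaptic contacts; the shunt is perisomatic by construction.
* The model contains no active spike currents; conclusions are limited to
  the inter-spike interval.
* The surrogate spiker's absolute probabilities are calibration artifacts;
  only their ordering across inhibition levels is meaningful.
* The liquid-junction-potential correction applied to recorded potentials
  is not modeled; the two reversal presets bracket its effect.
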