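"""Conductance extraction from patch-clamp sweeps.

Implements the pharmacological-subtraction workflow used to isolate the
autaptic GABA-A conductance (G_aut) and the afterhyperpolarization potassium
conductance (G_ahp) from paired voltage-clamp recordings: sweeps recorded
under control conditions contain the action-current artifact, the AHP
outward current and the delayed autaptic outward current; sweeps recorded in
a GABA-A blocker (gabazine) lack the autaptic component.  Averaging each
condition (≥ 6 events), subtracting the blocker average from the control
average, and dividing by the driving force yields the blocker-sensitive
conductance waveform.  Times are referenced to the action-potential inward
current peak (the "0" time point, t0); outward currents are positive.

Also provides passive-property estimation (R_m, C_m, τ_m, E_m) from
current-clamp step families and plain-text sweep-bundle I/O.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .config import KeyValueConfig, format_config, load_config

__all__ = [
    "Sweep",
    "SweepSet",
    "MeanTrace",
    "DifferenceTrace",
    "DecayFit",
    "IsolatedConductance",
    "PassiveProperties",
    "average_condition",
    "action_current_zero",
    "isolate_blocker_sensitive",
    "peak_and_delay",
    "fit_monoexp_decay",
    "conductance_from_difference",
    "conductance_from_current_trace",
    "passive_from_steps",
    "shunt_ratio",
    "detect_escape_spike",
    "analyze_pair",
    "write_bundle",
    "read_bundle",
]

#: Monoexponential fits below this r² are flagged (never silently dropped).
R2_ACCEPT_THRESHOLD = 0.85
#: Minimum sweep counts for condition averages / synaptic peak averages.
MIN_SUBTRACTION_EVENTS = 6
MIN_SYNAPTIC_EVENTS = 12
#: Inward transients must exceed this magnitude (pA) to count as an action
#: current; below it a trace is treated as containing no spike.
ACTION_CURRENT_FLOOR_PA = 100.0
#: Boxcar width used to pre-smooth traces for extremum *location* only.
PEAK_SMOOTH_MS = 0.1


class TraceError(ValueError):
    """Structural or domain error in sweep handling."""


# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class Sweep:
    """One uniformly sampled clamp trace."""

    samples: np.ndarray
    dt_ms: float
    signal_kind: str  # "current_pA" | "voltage_mV"
    holding_mV: Optional[float] = None
    condition: Optional[str] = None  # "control" | "blocker"
    index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt_ms <= 0:
            raise TraceError(f"dt_ms must be > 0, got {self.dt_ms}")
        if self.samples.size == 0:
            raise TraceError("sweep has no samples")
        if self.signal_kind not in ("current_pA", "voltage_mV"):
            raise TraceError(f"unknown signal_kind {self.signal_kind!r}")
        if self.signal_kind == "current_pA" and self.holding_mV is None:
            raise TraceError("voltage-clamp sweeps require holding_mV")

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return (self.samples.size - 1) * self.dt_ms


@dataclass(frozen=True)
class SweepSet:
    sweeps: tuple[Sweep, ...]
    cell_id: str = ""
    stimulus: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sweeps", tuple(self.sweeps))
        if self.sweeps:
            dt = self.sweeps[0].dt_ms
            kind = self.sweeps[0].signal_kind
            for sweep in self.sweeps:
                if sweep.dt_ms != dt or sweep.signal_kind != kind:
                    raise TraceError(
                        "all sweeps in a set must share dt_ms and signal_kind"
                    )

    def __len__(self) -> int:
        return len(self.sweeps)

    def by_condition(self, condition: str) -> list[Sweep]:
        return [s for s in self.sweeps if s.condition == condition]


@dataclass(frozen=True)
class MeanTrace:
    """Pointwise average of same-condition sweeps."""

    samples: np.ndarray
    dt_ms: float
    n_averaged: int
    condition: Optional[str] = None
    holding_mV: Optional[float] = None

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms


@dataclass(frozen=True)
class DifferenceTrace:
    """Control-minus-blocker current, time-referenced to the action current."""

    samples: np.ndarray  # pA, outward positive
    dt_ms: float
    t0_ms: float
    n_control: int
    n_blocker: int

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms


@dataclass(frozen=True)
class DecayFit:
    """Monoexponential decay fit A·exp(−(t − t_peak)/τ) from a peak."""

    amplitude_at_peak: float
    tau_ms: float
    r2: float
    window: tuple[float, float]
    flags: tuple[str, ...] = ()

    @property
    def accepted(self) -> bool:
        return not self.flags

    def __post_init__(self) -> None:
        if self.tau_ms <= 0 and "non_convergent" not in self.flags:
            raise TraceError(f"tau_ms must be > 0, got {self.tau_ms}")


@dataclass(frozen=True)
class IsolatedConductance:
    """An extracted conductance transient (autaptic, AHP or synaptic)."""

    role: str  # "autaptic" | "ahp" | "synaptic"
    peak_nS: float
    delay_to_peak_ms: float
    decay: DecayFit
    reversal_used_mV: float
    holding_mV: float

    def __post_init__(self) -> None:
        if self.peak_nS < 0:
            raise TraceError(f"peak_nS must be >= 0, got {self.peak_nS}")
        if self.delay_to_peak_ms < 0:
            raise TraceError(
                f"delay_to_peak_ms must be >= 0, got {self.delay_to_peak_ms}"
            )


@dataclass(frozen=True)
class PassiveProperties:
    r_m_MOhm: float
    c_m_pF: float
    e_m_mV: float
    tau_m_ms: float
    flags: tuple[str, ...] = ()

    @property
    def g_leak_nS(self) -> float:
        # unit identity: nS = 1000 / MΩ
        return 1000.0 / self.r_m_MOhm

    def __post_init__(self) -> None:
        if self.r_m_MOhm <= 0:
            raise TraceError(f"r_m_MOhm must be > 0, got {self.r_m_MOhm}")
        if self.c_m_pF <= 0:
            raise TraceError(f"c_m_pF must be > 0, got {self.c_m_pF}")


# ---------------------------------------------------------------------------
# Core operations


def average_condition(
    sweep_set: SweepSet,
    condition: str,
    min_count: int = MIN_SUBTRACTION_EVENTS,
    force: bool = False,
    exclude_escape_after_ms: Optional[float] = None,
    escape_floor_pA: float = ACTION_CURRENT_FLOOR_PA,
) -> MeanTrace:
    """Pointwise mean of all sweeps of one condition.

    Refuses (unless ``force``) when fewer than ``min_count`` sweeps are
    available, mirroring the at-least-six-events averaging rule.  When
    ``exclude_escape_after_ms`` is given, sweeps containing a second inward
    transient after that time (an occasional escape spike) are dropped
    before averaging, mimicking trial curation.
    """
    chosen = sweep_set.by_condition(condition)
    if exclude_escape_after_ms is not None:
        chosen = [
            s for s in chosen
            if not detect_escape_spike(s, exclude_escape_after_ms, escape_floor_pA)
        ]
    if len(chosen) < min_count:
        if not force:
            raise TraceError(
                f"condition {condition!r}: {len(chosen)} usable sweeps, "
                f"need at least {min_count}"
            )
        import warnings

        warnings.warn(
            f"averaging only {len(chosen)} sweeps (< {min_count}) under force",
            stacklevel=2,
        )
    if not chosen:
        raise TraceError(f"no sweeps for condition {condition!r}")
    length = chosen[0].samples.size
    for sweep in chosen:
        if sweep.samples.size != length:
            raise TraceError("sweeps of unequal length cannot be averaged")
    stack = np.stack([s.samples for s in chosen])
    return MeanTrace(
        samples=stack.mean(axis=0),
        dt_ms=chosen[0].dt_ms,
        n_averaged=len(chosen),
        condition=condition,
        holding_mV=chosen[0].holding_mV,
    )


def _window_slice(
    n: int, dt_ms: float, window_ms: tuple[float, float]
) -> tuple[int, int]:
    start, end = window_ms
    i0 = int(np.ceil(start / dt_ms - 1e-9))
    i1 = int(np.floor(end / dt_ms + 1e-9)) + 1
    i0 = max(i0, 0)
    i1 = min(i1, n)
    if i1 <= i0:
        raise TraceError(f"window {window_ms} ms is empty or outside the trace")
    return i0, i1


def action_current_zero(
    trace: MeanTrace | np.ndarray,
    dt_ms: Optional[float] = None,
    window_ms: Optional[tuple[float, float]] = None,
    floor_pA: float = ACTION_CURRENT_FLOOR_PA,
) -> float:
    """Time of the action-potential inward current peak (the "0" point), ms.

    Returns the time of the most negative sample inside ``window_ms``
    (earliest sample on ties).  A trace whose inward deflection never
    exceeds ``floor_pA`` in magnitude carries no action current and raises.
    """
    if isinstance(trace, MeanTrace):
        samples, dt = trace.samples, trace.dt_ms
    else:
        if dt_ms is None:
            raise TraceError("dt_ms required when passing a bare array")
        samples, dt = np.asarray(trace, dtype=float), dt_ms
    if window_ms is None:
        window_ms = (0.0, (samples.size - 1) * dt)
    i0, i1 = _window_slice(samples.size, dt, window_ms)
    segment = samples[i0:i1]
    imin = int(np.argmin(segment))  # argmin returns the first minimum
    if segment[imin] > -floor_pA:
        raise TraceError(
            f"no inward transient: minimum {segment[imin]:.1f} pA is above "
            f"the −{floor_pA:.0f} pA detection floor"
        )
    return (i0 + imin) * dt


def detect_escape_spike(
    sweep: Sweep, after_ms: float, floor_pA: float = ACTION_CURRENT_FLOOR_PA
) -> bool:
    """True when a second inward transient exceeds the floor after ``after_ms``."""
    i0 = int(np.ceil(after_ms / sweep.dt_ms))
    if i0 >= sweep.samples.size:
        return False
    return bool(np.min(sweep.samples[i0:]) < -floor_pA)


def isolate_blocker_sensitive(
    control_avg: MeanTrace, blocker_avg: MeanTrace, t0_ms: float
) -> DifferenceTrace:
    """Blocker-sensitive current: control average minus blocker average."""
    if control_avg.dt_ms != blocker_avg.dt_ms:
        raise TraceError("control and blocker averages have different dt_ms")
    if control_avg.samples.size != blocker_avg.samples.size:
        raise TraceError("control and blocker averages have different lengths")
    return DifferenceTrace(
        samples=control_avg.samples - blocker_avg.samples,
        dt_ms=control_avg.dt_ms,
        t0_ms=t0_ms,
        n_control=control_avg.n_averaged,
        n_blocker=blocker_avg.n_averaged,
    )


def _boxcar_smooth(samples: np.ndarray, dt_ms: float, width_ms: float) -> np.ndarray:
    width = max(int(round(width_ms / dt_ms)), 1)
    if width <= 1:
        return samples
    kernel = np.ones(width) / width
    return np.convolve(samples, kernel, mode="same")


def peak_and_delay(
    diff: DifferenceTrace,
    polarity: str = "outward",
    window_ms: tuple[float, float] = (0.0, 15.0),
    smooth_ms: float = PEAK_SMOOTH_MS,
) -> tuple[float, float]:
    """Extremum amplitude and its delay from t0.

    ``window_ms`` is relative to t0 and must not precede it.  Location is
    found on a lightly smoothed copy (boxcar, ``smooth_ms``) to avoid
    single-sample noise peaks; the amplitude reported is the raw sample at
    that location.  Ties break to the earliest time.  On a monotonically
    decaying trace the peak falls at the window start.
    """
    if polarity not in ("outward", "inward"):
        raise TraceError(f"polarity must be outward or inward, got {polarity!r}")
    if window_ms[0] < 0:
        raise TraceError("search window must start at or after t0")
    absolute = (window_ms[0] + diff.t0_ms, window_ms[1] + diff.t0_ms)
    i0, i1 = _window_slice(diff.samples.size, diff.dt_ms, absolute)
    smoothed = _boxcar_smooth(diff.samples, diff.dt_ms, smooth_ms)[i0:i1]
    if polarity == "outward":
        ipk = int(np.argmax(smoothed))
    else:
        ipk = int(np.argmin(smoothed))
    amplitude = float(diff.samples[i0 + ipk])
    delay = (i0 + ipk) * diff.dt_ms - diff.t0_ms
    return amplitude, delay


def fit_monoexp_decay(
    samples: np.ndarray,
    dt_ms: float,
    peak_time_ms: float,
    window_end_ms: Optional[float] = None,
    r2_threshold: float = R2_ACCEPT_THRESHOLD,
) -> DecayFit:
    """Least-squares monoexponential fit A·exp(−(t − t_peak)/τ) of a decay.

    The fit window runs from the peak to ``window_end_ms``; when the end is
    not given it defaults to t_peak + 5× an initial log-linear τ estimate,
    clipped to the trace.  Initialization comes from a log-linear regression
    on the positive samples, refined by nonlinear least squares.  Poor fits
    (r² below ``r2_threshold``) and non-convergent fits are returned flagged,
    never silently discarded.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    ipk = int(round(peak_time_ms / dt_ms))
    if not 0 <= ipk < n:
        raise TraceError(f"peak_time_ms {peak_time_ms} outside the trace")

    # initial log-linear estimate on positive samples after the peak
    tail = samples[ipk:]
    t_rel = np.arange(tail.size) * dt_ms
    positive = tail > 0
    tau0 = None
    if positive.sum() >= 3:
        slope, intercept = np.polyfit(t_rel[positive], np.log(tail[positive]), 1)
        if slope < 0:
            tau0 = -1.0 / slope
    if tau0 is None or not np.isfinite(tau0):
        tau0 = max(tail.size * dt_ms / 5.0, dt_ms)

    if window_end_ms is None:
        window_end_ms = peak_time_ms + 5.0 * tau0
    window_end_ms = min(window_end_ms, (n - 1) * dt_ms)
    iend = int(round(window_end_ms / dt_ms)) + 1
    if iend - ipk < 10:
        raise TraceError(
            f"decay window [{peak_time_ms}, {window_end_ms}] ms holds fewer "
            "than 10 samples"
        )
    y = samples[ipk:iend]
    t = np.arange(y.size) * dt_ms
    a0 = float(y[0]) if y[0] > 0 else float(np.max(y))

    flags: list[str] = []
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t, y, p0=(a0, tau0), maxfev=5000,
            bounds=((0.0, dt_ms / 10.0), (np.inf, np.inf)),
        )
        amplitude, tau = float(popt[0]), float(popt[1])
    except (RuntimeError, ValueError):
        amplitude, tau = a0, float(tau0)
        flags.append("non_convergent")

    residual = y - amplitude * np.exp(-t / tau)
    ss_res = float(np.sum(residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    if r2 < r2_threshold:
        flags.append("low_r2")
    return DecayFit(
        amplitude_at_peak=amplitude,
        tau_ms=tau,
        r2=r2,
        window=(peak_time_ms, window_end_ms),
        flags=tuple(flags),
    )


def conductance_from_current_trace(
    samples_pA: np.ndarray,
    dt_ms: float,
    t0_ms: float,
    holding_mV: float,
    reversal_mV: float,
    role: str,
    peak_window_ms: tuple[float, float] = (0.0, 15.0),
    n_control: int = 0,
    n_blocker: int = 0,
) -> IsolatedConductance:
    """Convert a baseline-free current trace to a conductance transient.

    G(t) = I(t) / (V_hold − E); the peak, its delay from t0 and the decay
    fit are populated via :func:`peak_and_delay` and
    :func:`fit_monoexp_decay` on the conductance trace.
    """
    driving = holding_mV - reversal_mV
    if driving == 0:
        raise TraceError("zero driving force: holding equals reversal")
    g = np.asarray(samples_pA, dtype=float) / driving
    gdiff = DifferenceTrace(g, dt_ms, t0_ms, n_control, n_blocker)
    peak, delay = peak_and_delay(gdiff, polarity="outward", window_ms=peak_window_ms)
    decay = fit_monoexp_decay(g, dt_ms, peak_time_ms=t0_ms + delay)
    return IsolatedConductance(
        role=role,
        peak_nS=max(peak, 0.0),
        delay_to_peak_ms=delay,
        decay=decay,
        reversal_used_mV=reversal_mV,
        holding_mV=holding_mV,
    )


def conductance_from_difference(
    diff: DifferenceTrace,
    holding_mV: float,
    reversal_mV: float,
    role: str = "autaptic",
    peak_window_ms: tuple[float, float] = (0.0, 15.0),
) -> IsolatedConductance:
    """Ohm's-law conversion of a blocker-sensitive difference current."""
    return conductance_from_current_trace(
        diff.samples, diff.dt_ms, diff.t0_ms, holding_mV, reversal_mV,
        role=role, peak_window_ms=peak_window_ms,
        n_control=diff.n_control, n_blocker=diff.n_blocker,
    )


def passive_from_steps(
    steps: SweepSet,
    injected_pA: Sequence[float],
    step_start_ms: float,
    step_end_ms: float,
) -> PassiveProperties:
    """Passive membrane properties from a current-clamp step family.

    R_m comes from the steady-state voltage deflection (mean of the last
    50 ms of each step) against injected current; τ_m from a monoexponential
    fit of the charging transient of the largest hyperpolarizing step;
    C_m = τ_m / R_m; E_m from the pre-step baseline.  Steps shorter than
    ~5 τ_m are flagged as not reaching steady state.
    """
    if len(steps) != len(injected_pA):
        raise TraceError("one injected current per sweep required")
    if any(i == 0 for i in injected_pA):
        raise TraceError("zero-amplitude steps carry no information")
    if steps.sweeps[0].signal_kind != "voltage_mV":
        raise TraceError("passive_from_steps needs voltage (current-clamp) sweeps")
    hyper = [i for i in injected_pA if i < 0]
    if not hyper:
        raise TraceError("at least one hyperpolarizing step is required")

    dt = steps.sweeps[0].dt_ms
    step_dur = step_end_ms - step_start_ms
    ss_window = min(50.0, step_dur / 4.0)
    deflections = []
    baselines = []
    for sweep, current in zip(steps.sweeps, injected_pA):
        i0, i1 = _window_slice(sweep.samples.size, dt, (0.0, max(step_start_ms - dt, dt)))
        baseline = float(sweep.samples[i0:i1].mean())
        j0, j1 = _window_slice(
            sweep.samples.size, dt, (step_end_ms - ss_window, step_end_ms)
        )
        steady = float(sweep.samples[j0:j1].mean())
        baselines.append(baseline)
        deflections.append(steady - baseline)
    # ΔV = R·ΔI through the origin; R in MΩ with mV/pA ⇒ GΩ, so ×1e3
    currents = np.asarray(injected_pA, dtype=float)
    dv = np.asarray(deflections)
    r_gohm = float(np.sum(dv * currents) / np.sum(currents**2))  # mV/pA = GΩ
    r_m = r_gohm * 1e3
    e_m = float(np.mean(baselines))

    # τ_m from the largest hyperpolarizing step's charging transient
    k = int(np.argmin(currents))
    sweep = steps.sweeps[k]
    i_start = int(round(step_start_ms / dt))
    i_end = int(round(step_end_ms / dt))
    charging = sweep.samples[i_start:i_end] - baselines[k]
    # fit ΔV(t) = ΔV_ss·(1 − e^(−t/τ)); the residual ΔV_ss − ΔV(t) is a pure
    # decay, made positive regardless of step polarity before fitting
    residual = np.sign(deflections[k]) * (deflections[k] - charging)
    fit = fit_monoexp_decay(residual, dt, peak_time_ms=0.0)
    tau_m = fit.tau_ms
    flags: list[str] = []
    if step_dur < 5 * tau_m:
        flags.append("steady_state_not_reached")
    if fit.flags:
        flags.extend(f"tau_fit_{f}" for f in fit.flags)
    c_m = tau_m / r_m * 1e3  # ms / MΩ ⇒ nF; ×1e3 ⇒ pF
    return PassiveProperties(
        r_m_MOhm=r_m, c_m_pF=c_m, e_m_mV=e_m, tau_m_ms=tau_m, flags=tuple(flags)
    )


def shunt_ratio(g_aut_peak_nS: float, g_leak_nS: float) -> float:
    """(G_aut + G_leak) / G_leak — input conductance at the autaptic peak
    relative to rest; 1.0 means no shunt."""
    if g_leak_nS <= 0:
        raise TraceError(f"g_leak_nS must be > 0, got {g_leak_nS}")
    if g_aut_peak_nS < 0:
        raise TraceError(f"g_aut_peak_nS must be >= 0, got {g_aut_peak_nS}")
    return (g_aut_peak_nS + g_leak_nS) / g_leak_nS


# ---------------------------------------------------------------------------
# End-to-end pair analysis


def analyze_pair(
    sweep_set: SweepSet,
    e_gaba_mV: float,
    e_ahp_mV: float,
    min_count: int = MIN_SUBTRACTION_EVENTS,
    force: bool = False,
    autapse_window_ms: tuple[float, float] = (0.0, 15.0),
    ahp_window_ms: tuple[float, float] = (0.0, 5.0),
    t0_search_ms: Optional[tuple[float, float]] = None,
    exclude_escape: bool = True,
) -> dict[str, IsolatedConductance]:
    """Full subtraction pipeline on a control/blocker voltage-clamp pair.

    Returns the autaptic conductance (from the control − blocker difference,
    against ``e_gaba_mV``) and the AHP conductance (from the blocker average
    itself, which isolates the GABA-A-independent outward current, against
    ``e_ahp_mV``).  A pre-t0 baseline (mean of the first samples up to 1 ms
    before t0) is removed from each current before conversion.
    """
    control = average_condition(sweep_set, "control", min_count, force)
    blocker = average_condition(sweep_set, "blocker", min_count, force)
    t0 = action_current_zero(blocker, window_ms=t0_search_ms)
    if exclude_escape:
        # redo the control average without escape-contaminated sweeps
        control = average_condition(
            sweep_set, "control", min_count, force,
            exclude_escape_after_ms=t0 + 1.0,
        )
    holding = control.holding_mV
    if holding is None:
        raise TraceError("sweeps carry no holding potential")

    def _debaseline(samples: np.ndarray, dt: float) -> np.ndarray:
        n_base = max(int((t0 - 1.0) / dt), 1)
        return samples - samples[:n_base].mean()

    diff = isolate_blocker_sensitive(control, blocker, t0)
    diff = replace(diff, samples=_debaseline(diff.samples, diff.dt_ms))
    autaptic = conductance_from_difference(
        diff, holding, e_gaba_mV, role="autaptic", peak_window_ms=autapse_window_ms
    )
    ahp_current = _debaseline(blocker.samples, blocker.dt_ms)
    # mask the action-current artifact so the outward-peak search does not
    # land on its rebound; the AHP peak sits ≲ 1 ms after t0
    ahp = conductance_from_current_trace(
        ahp_current, blocker.dt_ms, t0, holding, e_ahp_mV,
        role="ahp", peak_window_ms=ahp_window_ms,
        n_control=control.n_averaged, n_blocker=blocker.n_averaged,
    )
    return {"autaptic": autaptic, "ahp": ahp}


# ---------------------------------------------------------------------------
# Sweep-bundle I/O
#
# A bundle is a directory holding a key-value manifest and one two-column
# delimited text file (time_ms <TAB> value) per sweep, written with 8
# significant digits so a read→write cycle is byte-identical.

_FMT = "%.8g"


def write_bundle(path: str | Path, sweep_set: SweepSet,
                 extra: Optional[dict[str, object]] = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries: list[tuple[str, object]] = [
        ("cell_id", sweep_set.cell_id),
        ("stimulus", sweep_set.stimulus),
        ("n_sweeps", len(sweep_set)),
        ("dt_ms", _FMT % sweep_set.sweeps[0].dt_ms),
        ("signal_kind", sweep_set.sweeps[0].signal_kind),
    ]
    for i, sweep in enumerate(sweep_set.sweeps):
        name = f"sweep_{i:03d}"
        entries.append((f"{name}.file", name + ".txt"))
        entries.append((f"{name}.condition", sweep.condition or ""))
        entries.append((f"{name}.index", sweep.index))
        if sweep.holding_mV is not None:
            entries.append((f"{name}.holding_mV", _FMT % sweep.holding_mV))
        t = sweep.time_ms
        lines = "".join(
            f"{_FMT % tv}\t{_FMT % sv}\n" for tv, sv in zip(t, sweep.samples)
        )
        (path / (name + ".txt")).write_text(lines)
    if extra:
        entries.extend(extra.items())
    (path / "manifest.txt").write_text(format_config(entries))
    return path


def read_bundle(path: str | Path) -> tuple[SweepSet, KeyValueConfig]:
    path = Path(path)
    manifest = load_config(path / "manifest.txt")
    n = manifest.get_int("n_sweeps")
    if n == 0:
        raise TraceError(f"no sweeps in bundle {path}")
    dt = manifest.get_float("dt_ms")
    kind = manifest.get_str("signal_kind")
    sweeps = []
    for i in range(n):
        name = f"sweep_{i:03d}"
        fname = manifest.get_str(f"{name}.file")
        data = np.loadtxt(path / fname)
        if data.ndim != 2 or data.shape[1] != 2:
            raise TraceError(f"sweep file {fname} is not two-column")
        holding = manifest.get_float(f"{name}.holding_mV", np.nan)
        sweeps.append(
            Sweep(
                samples=data[:, 1],
                dt_ms=dt,
                signal_kind=kind,
                holding_mV=None if np.isnan(holding) else holding,
                condition=manifest.get_str(f"{name}.condition", "") or None,
                index=manifest.get_int(f"{name}.index", i),
            )
        )
    return (
        SweepSet(
            sweeps=tuple(sweeps),
            cell_id=manifest.get_str("cell_id", ""),
            stimulus=manifest.get_str("stimulus", ""),
        ),
        manifest,
    )


def bundle_checksum(path: str | Path) -> str:
    """SHA-256 over every file in a bundle, for run provenance records."""
    digest = hashlib.sha256()
    for file in sorted(Path(path).iterdir()):
        if file.is_file():
            digest.update(file.name.encode())
            digest.update(file.read_bytes())
    return digest.hexdigest()
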