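"""In-silico dynamic clamp: spike-triggered conductance injection.

The real protocols inject computed conductances into living basket cells;
reproducing them in silico needs a spike generator, so a surrogate
exponential integrate-and-fire (EIF) neuron stands in for the recorded
cell.  Its parameters are calibrated fixtures (baseline doublet interspike
intervals near the observed 5.6–6.6 ms range), not biological claims: only
the orderings the protocols probe — autaptic suppression of the second
spike, selective inhibition of the post-spike EPSP — are meaningful.

Two protocols are provided:

* **pre/post EPSP** — two subthreshold EPSCs bracket an evoked spike
  (40 ms before, 5 ms after); the autaptic IPSC, triggered at the −20 mV
  upward crossing with a 1 ms delay, shunts only the post-spike EPSP.
* **doublet suppression** — one large EPSC evokes a spike doublet; the
  spike-triggered IPSC (1–10 nS, 5 ms decay, −78 mV reversal) lowers the
  second-spike probability and stretches the interspike interval.

Cycle-to-cycle variability comes from seeded Ornstein–Uhlenbeck current
noise; identical seeds give bit-identical outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .model import CellModelSpec

__all__ = [
    "SpikingMechanism",
    "ConductanceEvent",
    "TriggeredIPSC",
    "ClampCommand",
    "CycleResult",
    "PrePostOutcome",
    "DoubletOutcome",
    "triggered_conductance_onsets",
    "run_cycle",
    "run_pre_post_protocol",
    "run_doublet_protocol",
    "default_surrogate_cell",
    "default_spiker",
    "default_prepost_command",
    "default_doublet_command",
]


class DynClampError(ValueError):
    """Configuration error in a dynamic-clamp protocol."""


@dataclass(frozen=True)
class SpikingMechanism:
    """Exponential integrate-and-fire surrogate spiker.

    The membrane equation gains the EIF spike-initiation term
    g_leak·Δ_T·exp((V−V_T)/Δ_T); when V reaches ``spike_peak_mV`` a spike is
    registered, the voltage is reset and held for ``refractory_ms``, and an
    intrinsic AHP conductance (reversal ``e_ahp_mV``) is incremented — the
    surrogate's own potassium AHP, distinct from any injected conductance.
    """

    threshold_mV: float = -55.0  # EIF V_T
    sharpness_mV: float = 1.5    # EIF Δ_T
    reset_mV: float = -62.0
    refractory_ms: float = 1.0
    spike_peak_mV: float = 20.0
    ahp_increment_nS: float = 20.0
    ahp_decay_ms: float = 2.5
    e_ahp_mV: float = -90.0

    def __post_init__(self) -> None:
        if self.refractory_ms < 0:
            raise DynClampError("refractory_ms must be >= 0")
        if self.reset_mV >= self.threshold_mV:
            raise DynClampError("reset must lie below threshold")
        if self.sharpness_mV <= 0:
            raise DynClampError("sharpness_mV must be > 0")


@dataclass(frozen=True)
class ConductanceEvent:
    """One commanded conductance transient.

    ``kind`` is ``"synaptic"`` (difference-of-exponentials, or pure decay
    when ``rise_tau_ms == 0``) or ``"step"`` (square pulse of
    ``duration_ms``).  ``onset_ms`` is on the cycle clock.
    """

    onset_ms: float
    peak_nS: float
    decay_tau_ms: float
    reversal_mV: float
    rise_tau_ms: float = 0.0
    kind: str = "synaptic"
    duration_ms: float = 0.5  # step events only

    def __post_init__(self) -> None:
        if self.peak_nS < 0:
            raise DynClampError("peak_nS must be >= 0")
        if self.decay_tau_ms <= 0:
            raise DynClampError("decay_tau_ms must be > 0")
        if self.kind not in ("synaptic", "step"):
            raise DynClampError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class TriggeredIPSC:
    """Spike-triggered autaptic IPSC command."""

    peak_nS: float
    trigger_threshold_mV: float = -20.0
    onset_delay_ms: float = 1.0
    decay_tau_ms: float = 5.0
    rise_tau_ms: float = 0.2
    reversal_mV: float = -78.0
    trigger_refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_nS < 0:
            raise DynClampError("peak_nS must be >= 0")
        if self.decay_tau_ms <= 0:
            raise DynClampError("decay_tau_ms must be > 0")


@dataclass(frozen=True)
class ClampCommand:
    """A full per-cycle stimulus program."""

    events: tuple[ConductanceEvent, ...] = ()
    spike_triggered_events: tuple[tuple[float, ConductanceEvent], ...] = ()
    ipsc: Optional[TriggeredIPSC] = None
    cycle_duration_ms: float = 100.0
    n_cycles: int = 1

    def without_ipsc(self) -> "ClampCommand":
        return replace(self, ipsc=None)


def triggered_conductance_onsets(
    v_trace: np.ndarray,
    dt_ms: float,
    trigger_threshold_mV: float = -20.0,
    delay_ms: float = 1.0,
    trigger_refractory_ms: float = 1.0,
) -> np.ndarray:
    """IPSC onset times from upward threshold crossings of a voltage trace.

    One onset per upward crossing of ``trigger_threshold_mV``, placed
    ``delay_ms`` after the crossing; crossings within
    ``trigger_refractory_ms`` of the previous accepted trigger are ignored
    (guards against double triggers on noisy upswings).  No crossing gives
    an empty array.
    """
    v = np.asarray(v_trace, dtype=float)
    above = v >= trigger_threshold_mV
    crossing_idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    onsets = []
    last_trigger = -math.inf
    for idx in crossing_idx:
        t_cross = idx * dt_ms
        if t_cross - last_trigger < trigger_refractory_ms:
            continue
        last_trigger = t_cross
        onsets.append(t_cross + delay_ms)
    return np.asarray(onsets, dtype=float)


# ---------------------------------------------------------------------------
# Core cycle engine


class _SynapseState:
    """Dual-exponential conductance state advanced multiplicatively."""

    __slots__ = ("a", "b", "mult_a", "mult_b", "norm", "reversal")

    def __init__(self, rise_tau: float, decay_tau: float, reversal: float,
                 dt: float):
        self.a = 0.0
        self.b = 0.0
        self.mult_a = math.exp(-dt / decay_tau)
        self.mult_b = math.exp(-dt / rise_tau) if rise_tau > 0 else 0.0
        if rise_tau > 0:
            ttp = (decay_tau * rise_tau / (decay_tau - rise_tau)
                   * math.log(decay_tau / rise_tau))
            self.norm = 1.0 / (math.exp(-ttp / decay_tau)
                               - math.exp(-ttp / rise_tau))
        else:
            self.norm = 1.0
        self.reversal = reversal

    def add(self, peak: float) -> None:
        self.a += peak * self.norm
        self.b += peak * self.norm if self.mult_b > 0 else 0.0

    def advance(self) -> None:
        self.a *= self.mult_a
        self.b *= self.mult_b

    @property
    def g(self) -> float:
        return self.a - self.b


@dataclass(frozen=True)
class CycleResult:
    time_ms: np.ndarray
    v_mV: np.ndarray
    spike_times_ms: tuple[float, ...]
    ipsc_onsets_ms: tuple[float, ...]
    triggered_event_onsets_ms: tuple[float, ...]
    ipsc_charge_pC: float


def run_cycle(
    cell: CellModelSpec,
    spiker: SpikingMechanism,
    command: ClampCommand,
    dt_ms: float = 0.02,
    noise_sd_mV: float = 0.0,
    noise_tau_ms: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    record_trace: bool = True,
) -> CycleResult:
    """Integrate one stimulus cycle of the surrogate neuron (forward Euler).

    ``cell`` supplies the passive membrane (C_m, g_leak, E_leak as resting
    potential); waveforms attached to the cell spec are ignored here — all
    stimuli come from ``command``.  ``noise_sd_mV`` sets the stationary
    standard deviation of the voltage fluctuations produced by an
    Ornstein–Uhlenbeck current noise with correlation time
    ``noise_tau_ms``.
    """
    n_steps = int(round(command.cycle_duration_ms / dt_ms))
    c_m, g_leak, e_leak = cell.c_m_pF, cell.g_leak_nS, cell.e_leak_mV
    sp = spiker

    # OU current amplitude giving the requested voltage sd on an RC membrane
    tau_m = c_m / g_leak
    if noise_sd_mV > 0:
        sigma_i = noise_sd_mV * g_leak * math.sqrt(
            (noise_tau_ms + tau_m) / noise_tau_ms
        )
        rho = math.exp(-dt_ms / noise_tau_ms)
        noise_scale = sigma_i * math.sqrt(1.0 - rho * rho)
        white = (rng or np.random.default_rng()).standard_normal(n_steps)
    else:
        rho = noise_scale = 0.0
        white = None

    # synapse states: one per distinct (rise, decay, reversal) channel
    event_states: list[_SynapseState] = []
    schedule: list[tuple[int, int, float]] = []  # (step, state_idx, peak)
    step_events: list[tuple[int, int, float]] = []  # (start, stop, peak) steps

    def _state_for(rise: float, decay: float, reversal: float) -> int:
        for i, s in enumerate(event_states):
            if (s.reversal == reversal
                    and s.mult_a == math.exp(-dt_ms / decay)
                    and (s.mult_b > 0) == (rise > 0)):
                if rise <= 0 or abs(s.mult_b - math.exp(-dt_ms / rise)) < 1e-15:
                    return i
        event_states.append(_SynapseState(rise, decay, reversal, dt_ms))
        return len(event_states) - 1

    step_channels: list[tuple[int, int, float, float]] = []
    for ev in command.events:
        if ev.kind == "step":
            i0 = int(round(ev.onset_ms / dt_ms))
            i1 = int(round((ev.onset_ms + ev.duration_ms) / dt_ms))
            step_channels.append((i0, i1, ev.peak_nS, ev.reversal_mV))
        else:
            idx = _state_for(ev.rise_tau_ms, ev.decay_tau_ms, ev.reversal_mV)
            schedule.append((int(round(ev.onset_ms / dt_ms)), idx, ev.peak_nS))
    schedule.sort()

    ipsc = command.ipsc
    ipsc_state: Optional[_SynapseState] = (
        _SynapseState(ipsc.rise_tau_ms, ipsc.decay_tau_ms, ipsc.reversal_mV,
                      dt_ms)
        if ipsc is not None and ipsc.peak_nS > 0 else None
    )

    v = e_leak
    i_noise = 0.0
    g_ahp = 0.0
    ahp_mult = math.exp(-dt_ms / sp.ahp_decay_ms)
    refractory_left = 0
    refractory_steps = int(round(sp.refractory_ms / dt_ms))
    spike_times: list[float] = []
    ipsc_onsets: list[float] = []
    trig_onsets: list[float] = []
    pending: list[tuple[int, str, float]] = []  # (step, kind, payload)
    last_trigger_ms = -math.inf
    ipsc_charge = 0.0
    exp_cap = 30.0

    trace = np.empty(n_steps + 1) if record_trace else None
    if record_trace:
        trace[0] = v
    sched_pos = 0

    for i in range(n_steps):
        t = i * dt_ms
        # activate scheduled fixed events
        while sched_pos < len(schedule) and schedule[sched_pos][0] <= i:
            _, idx, peak = schedule[sched_pos]
            event_states[idx].add(peak)
            sched_pos += 1
        # activate pending triggered payloads
        if pending:
            remaining = []
            for step, kind, payload in pending:
                if step <= i:
                    if kind == "ipsc":
                        ipsc_state.add(ipsc.peak_nS)
                        ipsc_onsets.append(step * dt_ms)
                    else:  # triggered synaptic event; payload = state idx/peak
                        idx, peak = payload
                        event_states[idx].add(peak)
                        trig_onsets.append(step * dt_ms)
                else:
                    remaining.append((step, kind, payload))
            pending = remaining

        if white is not None:
            i_noise = rho * i_noise + noise_scale * white[i]

        v_prev = v
        if refractory_left > 0:
            refractory_left -= 1
            v = sp.reset_mV
        else:
            i_total = -g_leak * (v - e_leak) + i_noise
            arg = (v - sp.threshold_mV) / sp.sharpness_mV
            i_total += g_leak * sp.sharpness_mV * math.exp(min(arg, exp_cap))
            i_total -= g_ahp * (v - sp.e_ahp_mV)
            for s in event_states:
                i_total -= s.g * (v - s.reversal)
            for i0, i1, peak, rev in step_channels:
                if i0 <= i < i1:
                    i_total -= peak * (v - rev)
            if ipsc_state is not None:
                i_ipsc = ipsc_state.g * (v - ipsc_state.reversal)
                i_total -= i_ipsc
                ipsc_charge += abs(i_ipsc) * dt_ms * 1e-3  # pA·ms → pC
            v = v + dt_ms * i_total / c_m

            if v >= sp.spike_peak_mV:
                v = sp.spike_peak_mV
                spike_times.append((i + 1) * dt_ms)
                g_ahp += sp.ahp_increment_nS
                refractory_left = refractory_steps
                # schedule spike-triggered EPSC payloads on the first spike
                if len(spike_times) == 1:
                    for delay, ev in command.spike_triggered_events:
                        idx = _state_for(
                            ev.rise_tau_ms, ev.decay_tau_ms, ev.reversal_mV
                        )
                        pending.append((
                            i + 1 + int(round(delay / dt_ms)), "event",
                            (idx, ev.peak_nS),
                        ))

        # IPSC trigger: upward crossing of the trigger threshold
        if ipsc_state is not None:
            t_now = (i + 1) * dt_ms
            if (v_prev < ipsc.trigger_threshold_mV <= v
                    and t_now - last_trigger_ms >= ipsc.trigger_refractory_ms):
                last_trigger_ms = t_now
                pending.append((
                    i + 1 + int(round(ipsc.onset_delay_ms / dt_ms)), "ipsc",
                    None,
                ))

        for s in event_states:
            s.advance()
        if ipsc_state is not None:
            ipsc_state.advance()
        g_ahp *= ahp_mult
        if record_trace:
            trace[i + 1] = v

    time = np.arange(n_steps + 1) * dt_ms
    return CycleResult(
        time_ms=time,
        v_mV=trace if record_trace else np.empty(0),
        spike_times_ms=tuple(spike_times),
        ipsc_onsets_ms=tuple(ipsc_onsets),
        triggered_event_onsets_ms=tuple(trig_onsets),
        ipsc_charge_pC=ipsc_charge,
    )


# ---------------------------------------------------------------------------
# Default surrogate cell and commands


def default_surrogate_cell(resting_mV: float = -74.5) -> CellModelSpec:
    """Passive membrane of the surrogate: median human pvBC passive values,
    resting potential inside the −72…−77 mV range of the firing protocols
    (close to E_GABA −78 mV, so injected inhibition acts mostly by
    shunting)."""
    return CellModelSpec(
        c_m_pF=43.81, g_leak_nS=1000.0 / 183.83, e_leak_mV=resting_mV,
        label="surrogate pvBC",
    )


def default_spiker() -> SpikingMechanism:
    return SpikingMechanism()


def default_prepost_command(
    epsc_peak_nS: float = 4.0,
    step_peak_nS: float = 20.0,
    ipsc_peak_nS: float = 8.0,
    prespike_onset_ms: float = 10.0,
    step_onset_ms: float = 50.0,
    postspike_delay_ms: float = 5.0,
) -> ClampCommand:
    """Pre/post-spike EPSP protocol: subthreshold EPSC 40 ms before the
    evoked spike, a 0.5 ms suprathreshold step, and a second EPSC
    time-locked 5 ms after the spike peak.  EPSCs decay with 1.25 ms at
    0 mV reversal; the IPSC decays with 5 ms at −78 mV, triggered at
    −20 mV with 1 ms delay.  The 20 nS step ignites the default surrogate
    from a resting potential of −63 mV (the depolarized end of the
    protocol's resting range); pair this command with
    ``default_surrogate_cell(resting_mV=-63.0)``."""
    epsc = dict(peak_nS=epsc_peak_nS, decay_tau_ms=1.25, reversal_mV=0.0,
                rise_tau_ms=0.2)
    return ClampCommand(
        events=(
            ConductanceEvent(onset_ms=prespike_onset_ms, **epsc),
            ConductanceEvent(onset_ms=step_onset_ms, peak_nS=step_peak_nS,
                             decay_tau_ms=1.0, reversal_mV=0.0, kind="step",
                             duration_ms=0.5),
        ),
        spike_triggered_events=(
            (postspike_delay_ms,
             ConductanceEvent(onset_ms=0.0, **epsc)),
        ),
        ipsc=TriggeredIPSC(peak_nS=ipsc_peak_nS),
        cycle_duration_ms=80.0,
    )


def default_doublet_command(
    epsc_peak_nS: float = 15.0,
    epsc_decay_tau_ms: float = 5.0,
    ipsc_peak_nS: float = 0.0,
    epsc_onset_ms: float = 5.0,
) -> ClampCommand:
    """Doublet protocol: one large EPSC (8–21 nS range, decay 4–5 ms)
    driving two spikes, optionally opposed by the triggered IPSC."""
    return ClampCommand(
        events=(
            ConductanceEvent(onset_ms=epsc_onset_ms, peak_nS=epsc_peak_nS,
                             decay_tau_ms=epsc_decay_tau_ms, reversal_mV=0.0,
                             rise_tau_ms=0.2),
        ),
        ipsc=TriggeredIPSC(peak_nS=ipsc_peak_nS),
        cycle_duration_ms=50.0,
    )


# ---------------------------------------------------------------------------
# Protocols


@dataclass(frozen=True)
class PrePostOutcome:
    pre_amplitudes_mV: np.ndarray
    post_amplitudes_mV: np.ndarray
    pre_mean_mV: float
    post_mean_mV: float
    n_cycles_used: int
    n_cycles_flagged: int
    autapse_on: bool


def run_pre_post_protocol(
    cell: CellModelSpec,
    spiker: SpikingMechanism,
    command: ClampCommand,
    autapse_on: bool,
    n_cycles: int = 10,
    noise_sd_mV: float = 0.0,
    seed: int = 0,
    dt_ms: float = 0.02,
) -> PrePostOutcome:
    """Onset-to-peak amplitudes of the pre- and post-spike EPSPs.

    Turning the autapse off (``autapse_on=False``) emulates the GABA-A
    blocker condition.  Cycles in which the suprathreshold step fails to
    evoke a spike are flagged and excluded from the post-EPSP statistics.
    """
    if not command.spike_triggered_events:
        raise DynClampError("pre/post protocol needs a spike-triggered EPSC")
    cmd = command if autapse_on else command.without_ipsc()
    pre_onset = command.events[0].onset_ms
    post_delay = command.spike_triggered_events[0][0]
    pre_amps, post_amps = [], []
    flagged = 0
    for cycle in range(n_cycles):
        rng = np.random.default_rng([seed, cycle])
        result = run_cycle(cell, spiker, cmd, dt_ms=dt_ms,
                           noise_sd_mV=noise_sd_mV, rng=rng)
        v, dt = result.v_mV, dt_ms
        i_pre = int(round(pre_onset / dt))
        i_pre_end = min(int(round((pre_onset + 8.0) / dt)), v.size)
        pre_amps.append(float(np.max(v[i_pre:i_pre_end]) - v[i_pre]))
        if not result.spike_times_ms:
            flagged += 1
            continue
        post_onset = result.spike_times_ms[0] + post_delay
        i_post = int(round(post_onset / dt))
        i_post_end = min(int(round((post_onset + 8.0) / dt)), v.size)
        if i_post >= v.size:
            flagged += 1
            continue
        post_amps.append(float(np.max(v[i_post:i_post_end]) - v[i_post]))
    pre = np.asarray(pre_amps)
    post = np.asarray(post_amps)
    return PrePostOutcome(
        pre_amplitudes_mV=pre,
        post_amplitudes_mV=post,
        pre_mean_mV=float(pre.mean()) if pre.size else float("nan"),
        post_mean_mV=float(post.mean()) if post.size else float("nan"),
        n_cycles_used=post.size,
        n_cycles_flagged=flagged,
        autapse_on=autapse_on,
    )


@dataclass(frozen=True)
class DoubletOutcome:
    autapse_level_nS: float
    spike_times_per_cycle: tuple[tuple[float, ...], ...]
    second_spike: np.ndarray  # bool per cycle
    interspike_delays_ms: np.ndarray  # delay where a 2nd spike fired
    probability_second_spike: float
    mean_delay_ms: float
    n_cycles: int


def run_doublet_protocol(
    cell: CellModelSpec,
    spiker: SpikingMechanism,
    command: ClampCommand,
    autapse_levels_nS: Sequence[float] = (0.0, 1.0, 2.5, 5.0, 10.0),
    n_cycles: int = 20,
    membrane_noise_sd_mV: float = 1.0,
    seed: int = 0,
    dt_ms: float = 0.02,
) -> list[DoubletOutcome]:
    """Second-spike probability and interspike delay per autapse level.

    The same per-cycle noise stream is replayed at every level (pairing the
    comparison), so identical seeds give identical outcomes and level
    differences reflect the injected inhibition alone.  The 0 nS condition
    must fire at least one doublet; otherwise the configuration cannot
    measure suppression and an error is raised.
    """
    outcomes = []
    for level in autapse_levels_nS:
        if level < 0:
            raise DynClampError("autapse level must be >= 0")
        cmd = replace(command, ipsc=replace(command.ipsc, peak_nS=level)) \
            if command.ipsc is not None else replace(
                command, ipsc=TriggeredIPSC(peak_nS=level))
        spikes_all: list[tuple[float, ...]] = []
        second = np.zeros(n_cycles, dtype=bool)
        delays = []
        for cycle in range(n_cycles):
            rng = np.random.default_rng([seed, cycle])
            result = run_cycle(cell, spiker, cmd, dt_ms=dt_ms,
                               noise_sd_mV=membrane_noise_sd_mV, rng=rng,
                               record_trace=False)
            st = result.spike_times_ms
            spikes_all.append(st)
            if len(st) >= 2:
                second[cycle] = True
                delays.append(st[1] - st[0])
        delays_arr = np.asarray(delays)
        outcomes.append(
            DoubletOutcome(
                autapse_level_nS=float(level),
                spike_times_per_cycle=tuple(spikes_all),
                second_spike=second,
                interspike_delays_ms=delays_arr,
                probability_second_spike=float(second.mean()),
                mean_delay_ms=float(delays_arr.mean()) if delays_arr.size
                else float("nan"),
                n_cycles=n_cycles,
            )
        )
    if outcomes and outcomes[0].autapse_level_nS == 0.0 \
            and outcomes[0].probability_second_spike == 0.0:
        raise DynClampError(
            "the 0 nS condition never fires a doublet; raise the EPSC "
            "conductance — suppression cannot be measured"
        )
    return outcomes
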