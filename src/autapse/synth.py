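"""Seeded generators of synthetic recordings with known ground truth.

The study's raw electrophysiology is not deposited, so every pipeline test
runs against synthetic data whose generating parameters are the published
summary statistics.  Three generators are provided:

* paired control/blocker voltage-clamp sweeps — an action-current artifact
  (scenery for the zero-point detector), the AHP outward current, and
  (control only) the delayed autaptic outward current, plus white Gaussian
  noise and optional occasional escape-spike transients;
* current-clamp step families for passive-property estimation;
* parameter cohorts: per-cell model specs drawn from distributions matched
  to the printed location/scale statistics (normal for mean ± sem
  quantities with sem→sd scaled by the printed n; log-normal solved from
  median/quartiles for the right-skewed ones), truncated at physiological
  bounds.

Every generated artifact carries its :class:`GroundTruth`, and identical
seeds reproduce bundles byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from .config import format_config
from .model import (
    AHP_ONSET_OFFSET_MS,
    CellModelSpec,
    ConductanceWaveform,
    cell_spec_from_measurements,
    waveform_value,
)
from .traces import PassiveProperties, Sweep, SweepSet, write_bundle

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "generate_voltage_clamp_pair",
    "generate_step_family",
    "sample_cohort",
    "merge_sweep_sets",
    "save_pair_bundle",
    "ground_truth_entries",
    "COHORT_PRESETS",
]


class SynthError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters embedded in every synthetic artifact."""

    passive: PassiveProperties
    ahp_peak_nS: float
    ahp_delay_ms: float
    ahp_tau_ms: float
    aut_peak_nS: float
    aut_delay_ms: float
    aut_tau_ms: float
    holding_mV: float
    e_gaba_mV: float
    e_ahp_mV: float
    noise_sd_pA: float
    noise_sd_mV: float
    escape_spike_probability: float
    seed: int
    dt_ms: float = 0.02
    t0_ms: float = 8.0
    sweep_duration_ms: float = 30.0
    action_current_width_ms: float = 0.536
    action_current_amp_pA: float = -2500.0
    onset_offset_ms: float = AHP_ONSET_OFFSET_MS

    def __post_init__(self) -> None:
        for name in ("ahp_peak_nS", "aut_peak_nS", "noise_sd_pA",
                     "noise_sd_mV"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")
        if not 0.0 <= self.escape_spike_probability <= 1.0:
            raise SynthError("escape_spike_probability must lie in [0, 1]")


def default_ground_truth(seed: int = 0, **overrides) -> GroundTruth:
    """Median human recording conditions.

    Autapse 3.79 nS / 2.31 ms delay / 4.18 ms decay; AHP 17.48 nS /
    0.78 ms / 5.43 ms; holding −43 mV against the analysis reversals
    (−73 mV GABA-A, −95 mV AHP); 5 pA trace noise.  Escape-spike
    transients are off by default and opt-in per experiment.
    """
    passive = PassiveProperties(
        r_m_MOhm=183.83, c_m_pF=43.81, e_m_mV=-74.15,
        tau_m_ms=183.83 * 43.81 / 1000.0,
    )
    truth = GroundTruth(
        passive=passive,
        ahp_peak_nS=17.48, ahp_delay_ms=0.78, ahp_tau_ms=5.43,
        aut_peak_nS=3.79, aut_delay_ms=2.31, aut_tau_ms=4.18,
        holding_mV=-43.0, e_gaba_mV=-73.0, e_ahp_mV=-95.0,
        noise_sd_pA=5.0, noise_sd_mV=0.2,
        escape_spike_probability=0.0, seed=seed,
    )
    return replace(truth, **overrides) if overrides else truth


def ground_truth_entries(truth: GroundTruth) -> list[tuple[str, object]]:
    fields_ = (
        "ahp_peak_nS ahp_delay_ms ahp_tau_ms aut_peak_nS aut_delay_ms "
        "aut_tau_ms holding_mV e_gaba_mV e_ahp_mV noise_sd_pA noise_sd_mV "
        "escape_spike_probability seed dt_ms t0_ms sweep_duration_ms "
        "action_current_width_ms action_current_amp_pA onset_offset_ms"
    ).split()
    entries: list[tuple[str, object]] = [
        ("truth." + name, repr(getattr(truth, name))) for name in fields_
    ]
    for name in ("r_m_MOhm", "c_m_pF", "e_m_mV", "tau_m_ms"):
        entries.append(("truth.passive." + name, repr(getattr(truth.passive, name))))
    return entries


# ---------------------------------------------------------------------------
# Voltage-clamp pair generator


def _artifact_trace(t_ms: np.ndarray, truth: GroundTruth,
                    peak_time_ms: float, scale: float = 1.0) -> np.ndarray:
    """Gaussian inward action-current transient of the printed full width at
    half amplitude.  A compact pulse is used (rather than an exponential-
    tailed one) so that this scenery has decayed to nothing by the time the
    AHP outward current peaks ~0.8 ms later, as the real biphasic action
    current has; its shape carries no model claim."""
    sigma = truth.action_current_width_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return truth.action_current_amp_pA * scale * np.exp(
        -((t_ms - peak_time_ms) ** 2) / (2.0 * sigma * sigma)
    )


def _rise_decay_conductance(
    t_ms: np.ndarray, onset_ms: float, time_to_peak_ms: float,
    peak_nS: float, tau_ms: float,
) -> np.ndarray:
    """Smooth sin²-rise / monoexponential-decay conductance waveform.

    Zero before onset, rises as sin²(π/2 · t/ttp) to exactly ``peak_nS`` at
    ``onset + time_to_peak``, then decays as a *pure* monoexponential with
    ``tau_ms``.  The decay tau of the generated transient therefore equals
    the value a from-the-peak monoexponential fit reports — matching how
    the experimental decay constants are defined."""
    rel = t_ms - onset_ms
    rising = (rel > 0) & (rel < time_to_peak_ms)
    g = np.zeros_like(t_ms)
    if time_to_peak_ms > 0:
        g[rising] = peak_nS * np.sin(
            0.5 * math.pi * rel[rising] / time_to_peak_ms
        ) ** 2
    after = rel >= time_to_peak_ms
    g[after] = peak_nS * np.exp(-(rel[after] - time_to_peak_ms) / tau_ms)
    return g


def _conductance_current(
    t_ms: np.ndarray, truth: GroundTruth, peak_nS: float, delay_ms: float,
    tau_ms: float, reversal_mV: float,
) -> np.ndarray:
    g = _rise_decay_conductance(
        t_ms,
        onset_ms=truth.t0_ms + truth.onset_offset_ms,
        time_to_peak_ms=max(delay_ms - truth.onset_offset_ms, 0.0),
        peak_nS=peak_nS,
        tau_ms=tau_ms,
    )
    return g * (truth.holding_mV - reversal_mV)


def generate_voltage_clamp_pair(
    truth: GroundTruth,
    n_control: int = 6,
    n_blocker: int = 6,
    seed: Optional[int] = None,
    cell_id: str = "synthetic",
) -> tuple[SweepSet, SweepSet]:
    """Paired control and blocker voltage-clamp sweep sets.

    Control sweeps carry artifact + AHP current + autaptic current; blocker
    sweeps omit the autaptic component (the blocker-sensitive current).
    With probability ``truth.escape_spike_probability`` a control sweep
    additionally carries a second, smaller inward escape transient 2–6 ms
    after t0.  ``seed`` defaults to ``truth.seed``; equal seeds give
    identical sweep sets.
    """
    if n_control < 1 or n_blocker < 1:
        raise SynthError("need at least one sweep per condition")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_samples = int(round(truth.sweep_duration_ms / truth.dt_ms)) + 1
    t = np.arange(n_samples) * truth.dt_ms

    base = _artifact_trace(t, truth, truth.t0_ms)
    base = base + _conductance_current(
        t, truth, truth.ahp_peak_nS, truth.ahp_delay_ms, truth.ahp_tau_ms,
        truth.e_ahp_mV,
    )
    autaptic = _conductance_current(
        t, truth, truth.aut_peak_nS, truth.aut_delay_ms, truth.aut_tau_ms,
        truth.e_gaba_mV,
    )

    def _make(condition: str, index: int, signal: np.ndarray) -> Sweep:
        samples = signal.copy()
        if condition == "control" and truth.escape_spike_probability > 0:
            if rng.random() < truth.escape_spike_probability:
                t_escape = truth.t0_ms + rng.uniform(2.0, 6.0)
                samples = samples + _artifact_trace(t, truth, t_escape, 0.7)
        if truth.noise_sd_pA > 0:
            samples = samples + rng.normal(0.0, truth.noise_sd_pA, n_samples)
        return Sweep(
            samples=samples, dt_ms=truth.dt_ms, signal_kind="current_pA",
            holding_mV=truth.holding_mV, condition=condition, index=index,
        )

    control = SweepSet(
        sweeps=tuple(_make("control", i, base + autaptic)
                     for i in range(n_control)),
        cell_id=cell_id, stimulus="single-spike voltage clamp",
    )
    blocker = SweepSet(
        sweeps=tuple(_make("blocker", i, base) for i in range(n_blocker)),
        cell_id=cell_id, stimulus="single-spike voltage clamp (blocker)",
    )
    return control, blocker


def merge_sweep_sets(*sets: SweepSet) -> SweepSet:
    sweeps: list[Sweep] = []
    for s in sets:
        sweeps.extend(s.sweeps)
    return SweepSet(sweeps=tuple(sweeps), cell_id=sets[0].cell_id,
                    stimulus=sets[0].stimulus)


def save_pair_bundle(
    path: str | Path, control: SweepSet, blocker: SweepSet, truth: GroundTruth
) -> Path:
    """Write the pair as one on-disk bundle with a ground-truth sidecar."""
    merged = merge_sweep_sets(control, blocker)
    entries = ground_truth_entries(truth)
    out = write_bundle(path, merged, extra=dict(entries))
    (out / "ground_truth.txt").write_text(format_config(entries))
    return out


# ---------------------------------------------------------------------------
# Current-clamp step families


def generate_step_family(
    truth: GroundTruth,
    injected_pA: Sequence[float] = (-50.0, 50.0, 100.0),
    seed: Optional[int] = None,
    step_start_ms: float = 100.0,
    step_duration_ms: float = 600.0,
    dt_ms: float = 0.1,
    cell_id: str = "synthetic",
) -> SweepSet:
    """RC voltage responses to current steps delivered at rest.

    V(t) = E_m + I·R·(1 − e^(−t/τ_m)) during the step and a symmetric
    monoexponential relaxation afterwards, plus Gaussian voltage noise
    (``truth.noise_sd_mV``).
    """
    if any(i == 0 for i in injected_pA):
        raise SynthError("step amplitudes must be nonzero")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    total_ms = step_start_ms + step_duration_ms + 300.0
    n_samples = int(round(total_ms / dt_ms)) + 1
    t = np.arange(n_samples) * dt_ms
    tau = truth.passive.tau_m_ms
    r_gohm = truth.passive.r_m_MOhm / 1e3  # mV/pA
    sweeps = []
    for idx, current in enumerate(injected_pA):
        dv_ss = current * r_gohm
        v = np.full(n_samples, truth.passive.e_m_mV)
        during = (t >= step_start_ms) & (t < step_start_ms + step_duration_ms)
        v[during] += dv_ss * (1.0 - np.exp(-(t[during] - step_start_ms) / tau))
        after = t >= step_start_ms + step_duration_ms
        v_end = dv_ss * (1.0 - math.exp(-step_duration_ms / tau))
        v[after] += v_end * np.exp(
            -(t[after] - step_start_ms - step_duration_ms) / tau
        )
        if truth.noise_sd_mV > 0:
            v = v + rng.normal(0.0, truth.noise_sd_mV, n_samples)
        sweeps.append(
            Sweep(samples=v, dt_ms=dt_ms, signal_kind="voltage_mV",
                  condition="control", index=idx)
        )
    return SweepSet(sweeps=tuple(sweeps), cell_id=cell_id,
                    stimulus="current steps at rest")


# ---------------------------------------------------------------------------
# Parameter cohorts

_Z_QUARTILE = 0.6744897501960817  # Φ⁻¹(0.75)


@dataclass(frozen=True)
class _NormalFromSem:
    mean: float
    sem: float
    n_printed: int
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        sd = self.sem * math.sqrt(self.n_printed)
        return _truncated(rng, size, self.lo, self.hi,
                          lambda z: self.mean + sd * z)

    def from_z(self, z: np.ndarray) -> np.ndarray:
        sd = self.sem * math.sqrt(self.n_printed)
        return np.clip(self.mean + sd * z, self.lo, self.hi)


@dataclass(frozen=True)
class _LogNormalFromQuartiles:
    median: float
    q1: float
    q3: float
    lo: float
    hi: float

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        spread = 0.5 * (math.log(self.q3 / self.median)
                        + math.log(self.median / self.q1))
        return spread / _Z_QUARTILE

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return _truncated(rng, size, self.lo, self.hi,
                          lambda z: np.exp(self.mu + self.sigma * z))

    def from_z(self, z: np.ndarray) -> np.ndarray:
        return np.clip(np.exp(self.mu + self.sigma * z), self.lo, self.hi)


def _truncated(rng, size, lo, hi, transform) -> np.ndarray:
    out = np.empty(size)
    remaining = np.arange(size)
    for _ in range(200):
        draw = transform(rng.standard_normal(remaining.size))
        good = (draw >= lo) & (draw <= hi)
        out[remaining[good]] = draw[good]
        remaining = remaining[~good]
        if remaining.size == 0:
            return out
    # pathological bounds: clip the stragglers rather than loop forever
    out[remaining] = np.clip(transform(rng.standard_normal(remaining.size)),
                             lo, hi)
    return out


#: Printed location/scale statistics per species.  sem-reported quantities
#: are scaled to between-cell sd with the printed n; quartile-reported ones
#: are log-normal solved from median and quartiles.  The mouse autapse
#: delay-to-peak and membrane capacitance are not reported; the human delay
#: and a capacitance matched to the human membrane time constant at the
#: mouse input resistance stand in (documented package choices).
COHORT_PRESETS: dict[str, dict[str, object]] = {
    "human": {
        "g_aut": _LogNormalFromQuartiles(3.79, 2.39, 6.45, 0.2, 40.0),
        "tau_aut": _NormalFromSem(4.18, 0.31, 13, 1.0, 12.0),
        "delay_aut": _NormalFromSem(2.31, 0.16, 13, 0.5, 6.0),
        "g_ahp": _NormalFromSem(17.48, 1.81, 14, 0.5, 60.0),
        "tau_ahp": _NormalFromSem(5.43, 0.54, 14, 1.0, 15.0),
        "delay_ahp": _NormalFromSem(0.78, 0.06, 14, 0.31, 2.5),
        "r_m": _NormalFromSem(183.83, 22.34, 14, 40.0, 600.0),
        "c_m": _LogNormalFromQuartiles(43.81, 27.65, 58.60, 10.0, 150.0),
        "e_gaba": _NormalFromSem(-78.89, 0.53, 13, -90.0, -70.0),
    },
    "mouse": {
        "g_aut": _LogNormalFromQuartiles(4.09, 1.93, 5.67, 0.2, 40.0),
        "tau_aut": _LogNormalFromQuartiles(3.91, 3.55, 6.47, 1.0, 15.0),
        "delay_aut": _NormalFromSem(2.31, 0.16, 13, 0.5, 6.0),
        "g_ahp": _NormalFromSem(25.21, 2.60, 11, 0.5, 80.0),
        "tau_ahp": _NormalFromSem(2.91, 0.26, 11, 0.8, 10.0),
        "delay_ahp": _NormalFromSem(0.59, 0.068, 11, 0.31, 2.5),
        "r_m": _NormalFromSem(139.60, 6.69, 19, 40.0, 400.0),
        "c_m": _LogNormalFromQuartiles(57.7, 43.0, 77.0, 10.0, 150.0),
        "e_gaba": _NormalFromSem(-78.89, 0.53, 13, -90.0, -70.0),
    },
}


def sample_cohort(
    n_cells: int,
    species_preset: str = "human",
    seed: int = 0,
    ahp_leak_correlation: float = 0.0,
    e_ahp_mV: float = -90.0,
) -> list[CellModelSpec]:
    """Draw a cohort of single-compartment cell specs.

    Per-cell parameters come from the species preset's marginals;
    ``ahp_leak_correlation`` optionally couples the AHP peak to the leak
    conductance through a Gaussian copula (the printed pairwise Pearson
    r = 0.671 between G_ahp and G_leak), leaving both marginals intact.
    Deterministic under ``seed``.
    """
    if n_cells < 1:
        raise SynthError("n_cells must be >= 1")
    if species_preset not in COHORT_PRESETS:
        raise SynthError(
            f"unknown preset {species_preset!r}; choose from "
            f"{sorted(COHORT_PRESETS)}"
        )
    if not -1.0 < ahp_leak_correlation < 1.0:
        raise SynthError("ahp_leak_correlation must lie in (−1, 1)")
    preset = COHORT_PRESETS[species_preset]
    rng = np.random.default_rng(seed)

    if ahp_leak_correlation != 0.0:
        # copula: correlate the G_ahp score with the g_leak score; g_leak is
        # 1/R_m, so the R_m score gets the opposite sign
        rho = ahp_leak_correlation
        z_ahp = rng.standard_normal(n_cells)
        z_ind = rng.standard_normal(n_cells)
        z_rm = -(rho * z_ahp + math.sqrt(1 - rho * rho) * z_ind)
        g_ahp = preset["g_ahp"].from_z(z_ahp)
        r_m = preset["r_m"].from_z(z_rm)
    else:
        g_ahp = preset["g_ahp"].draw(rng, n_cells)
        r_m = preset["r_m"].draw(rng, n_cells)

    columns = {
        name: preset[name].draw(rng, n_cells)
        for name in ("g_aut", "tau_aut", "delay_aut", "tau_ahp", "delay_ahp",
                     "c_m", "e_gaba")
    }
    cohort = []
    for i in range(n_cells):
        cohort.append(
            cell_spec_from_measurements(
                c_m_pF=float(columns["c_m"][i]),
                g_leak_nS=1000.0 / float(r_m[i]),
                e_leak_mV=-68.0,
                ahp=(float(g_ahp[i]), float(columns["delay_ahp"][i]),
                     float(columns["tau_ahp"][i])),
                autapse=(float(columns["g_aut"][i]),
                         float(columns["delay_aut"][i]),
                         float(columns["tau_aut"][i])),
                e_ahp_mV=e_ahp_mV,
                e_gaba_mV=float(columns["e_gaba"][i]),
                label=f"{species_preset}_cell_{i:04d}",
            )
        )
    return cohort
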