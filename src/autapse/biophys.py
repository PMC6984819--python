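"""Reversal-potential and conductance arithmetic.

Closed-form electrochemistry shared by every other module: the Nernst
potential for a single ion species, the anionic Goldman–Hodgkin–Katz (GHK)
voltage for a chloride/bicarbonate-permeable channel (the GABA-A receptor),
Henderson–Hasselbalch partitioning of bicarbonate across the membrane, and
Ohm's-law conversion of clamp currents to conductances.

Unit conventions (package-wide): concentrations mM, temperature °C,
potentials mV, currents pA, conductances nS.  With pA and mV, Ohm's law
I/(V − E) yields nS directly.  Outward current is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.constants import R as GAS_CONSTANT  # J / (mol K)
from scipy.constants import physical_constants

FARADAY: float = physical_constants["Faraday constant"][0]  # C / mol

__all__ = [
    "IonicSolution",
    "ReversalContext",
    "nernst_potential",
    "bicarbonate_inside",
    "ghk_anion_reversal",
    "ohmic_conductance",
    "PIPETTE_PHYSIOLOGICAL",
    "PIPETTE_HIGH_CHLORIDE",
    "BATH_SLICING",
    "BATH_STORAGE",
    "REVERSAL_PRESETS",
    "default_reversal_context",
]


class BiophysicsError(ValueError):
    """Domain error in an electrochemical computation."""


def _celsius_to_kelvin(temperature_c: float) -> float:
    if not 20.0 <= temperature_c <= 40.0:
        raise BiophysicsError(
            f"temperature {temperature_c} °C outside the supported 20–40 °C range"
        )
    return temperature_c + 273.15


@dataclass(frozen=True)
class IonicSolution:
    """Ionic composition of one compartment (pipette/intracellular or bath).

    Concentrations are total free concentrations in mM; any species not
    relevant to a given computation may be left ``None``.
    """

    chloride_mM: Optional[float] = None
    bicarbonate_mM: Optional[float] = None
    potassium_mM: Optional[float] = None
    ph: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("chloride_mM", "bicarbonate_mM", "potassium_mM"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise BiophysicsError(f"{name} must be >= 0, got {value}")
        if self.ph is not None and not 0.0 < self.ph < 14.0:
            raise BiophysicsError(f"ph must lie in (0, 14), got {self.ph}")

    def require(self, species: str) -> float:
        value = getattr(self, species)
        if value is None:
            where = self.label or "solution"
            raise BiophysicsError(f"{species} missing from {where}")
        return value


@dataclass(frozen=True)
class ReversalContext:
    """Everything needed to evaluate the anionic GHK reversal potential.

    ``p_hco3_rel`` is the bicarbonate:chloride relative permeability of the
    GABA-A channel (dimensionless, ~0.1 under physiological conditions).
    """

    internal: IonicSolution
    external: IonicSolution
    temperature_C: float
    p_hco3_rel: float = 0.1

    def __post_init__(self) -> None:
        _celsius_to_kelvin(self.temperature_C)  # range check
        if self.p_hco3_rel < 0:
            raise BiophysicsError(
                f"p_hco3_rel must be >= 0, got {self.p_hco3_rel}"
            )


def nernst_potential(
    valence: int, conc_in: float, conc_out: float, temperature: float
) -> float:
    """Nernst equilibrium potential in mV.

    Parameters
    ----------
    valence
        Signed ionic charge (e.g. +1 for K+, −1 for Cl−).
    conc_in, conc_out
        Intra-/extracellular concentrations, mM (any common unit cancels).
    temperature
        Bath temperature, °C.

    Returns
    -------
    float
        (R·T / z·F) · ln(out/in) in mV.
    """
    if valence == 0:
        raise BiophysicsError("valence must be nonzero")
    if conc_in <= 0 or conc_out <= 0:
        raise BiophysicsError(
            f"concentrations must be > 0, got in={conc_in}, out={conc_out}"
        )
    kelvin = _celsius_to_kelvin(temperature)
    return (
        1e3 * GAS_CONSTANT * kelvin / (valence * FARADAY) * math.log(conc_out / conc_in)
    )


def bicarbonate_inside(hco3_out: float, ph_out: float, ph_in: float) -> float:
    """Intracellular bicarbonate from the transmembrane pH gradient.

    Assumes CO2 equilibrates freely across the membrane, so by
    Henderson–Hasselbalch the HCO3− ratio follows the proton gradient:
    [HCO3−]i = [HCO3−]o · 10^(pHi − pHo).
    """
    if hco3_out <= 0:
        raise BiophysicsError(f"hco3_out must be > 0, got {hco3_out}")
    return hco3_out * 10.0 ** (ph_in - ph_out)


def _internal_bicarbonate(ctx: ReversalContext) -> float:
    if ctx.internal.bicarbonate_mM is not None:
        return ctx.internal.bicarbonate_mM
    if ctx.internal.ph is None or ctx.external.ph is None:
        raise BiophysicsError(
            "bicarbonate_mM missing from internal solution and no pH pair "
            "available to derive it"
        )
    return bicarbonate_inside(
        ctx.external.require("bicarbonate_mM"), ctx.external.ph, ctx.internal.ph
    )


def ghk_anion_reversal(ctx: ReversalContext) -> float:
    """Anionic GHK reversal potential of a Cl−/HCO3−-permeable channel, mV.

    For anions the internal concentrations sit in the numerator::

        E = (R·T/F) · ln( ([Cl]i + p·[HCO3]i) / ([Cl]o + p·[HCO3]o) )

    with p the HCO3:Cl relative permeability.  At p = 0 this reduces exactly
    to the chloride Nernst potential.  Internal bicarbonate is taken from the
    solution if given, otherwise derived from the pH pair via
    :func:`bicarbonate_inside`.
    """
    cl_in = ctx.internal.require("chloride_mM")
    cl_out = ctx.external.require("chloride_mM")
    if cl_in <= 0 or cl_out <= 0:
        raise BiophysicsError("chloride concentrations must be > 0")
    p = ctx.p_hco3_rel
    if p > 0:
        hco3_in = _internal_bicarbonate(ctx)
        hco3_out = ctx.external.require("bicarbonate_mM")
    else:
        hco3_in = hco3_out = 0.0
    kelvin = _celsius_to_kelvin(ctx.temperature_C)
    return (
        1e3
        * GAS_CONSTANT
        * kelvin
        / FARADAY
        * math.log((cl_in + p * hco3_in) / (cl_out + p * hco3_out))
    )


def ohmic_conductance(
    peak_current: float, holding_potential: float, reversal: float
) -> float:
    """Peak conductance from a clamp current by Ohm's law, nS.

    ``peak_current`` in pA (outward positive), potentials in mV:
    G = I / (V_hold − E_rev).
    """
    driving_force = holding_potential - reversal
    if driving_force == 0:
        raise BiophysicsError(
            f"zero driving force: holding {holding_potential} mV equals "
            f"reversal {reversal} mV"
        )
    return peak_current / driving_force


# ---------------------------------------------------------------------------
# Solution presets
#
# Bath chloride follows the slicing-solution recipe: 130 NaCl + 3.5 KCl +
# 2×1 CaCl2 = 135.5 mM Cl−; the storage variant raises CaCl2 to 3 mM
# (139.5 mM Cl−).  The physiological pipette carries 8 mM Cl− (8 NaCl) and
# 126 mM K+ (K-gluconate); the elevated-chloride pipette replaces the
# gluconate with 130 mM KCl.

PIPETTE_PHYSIOLOGICAL = IonicSolution(
    chloride_mM=8.0, potassium_mM=126.0, ph=7.0, label="physiological pipette"
)
PIPETTE_HIGH_CHLORIDE = IonicSolution(
    chloride_mM=138.0, potassium_mM=130.0, ph=7.0, label="high-chloride pipette"
)
BATH_SLICING = IonicSolution(
    chloride_mM=135.5, bicarbonate_mM=24.0, potassium_mM=3.5, ph=7.4,
    label="slicing aCSF",
)
BATH_STORAGE = IonicSolution(
    chloride_mM=139.5, bicarbonate_mM=24.0, potassium_mM=3.5, ph=7.4,
    label="storage aCSF",
)

#: Named reversal-potential presets (mV).  ``methods`` carries the values
#: computed from the solution recipes (GHK/Nernst at 36 °C); ``simulation``
#: carries the values used in the conductance-injection protocols, where a
#: junction-potential-corrected E_GABA-A and a −90 mV AHP reversal apply.
#: The two sets are never mixed implicitly: every protocol names its preset.
REVERSAL_PRESETS: dict[str, dict[str, float]] = {
    "methods": {"e_gaba_mV": -73.0, "e_ahp_mV": -95.0},
    "simulation": {"e_gaba_mV": -78.89, "e_ahp_mV": -90.0},
}


def default_reversal_context(
    temperature_C: float = 36.0, high_chloride: bool = False
) -> ReversalContext:
    """The standard recording configuration: pipette vs. slicing aCSF."""
    pipette = PIPETTE_HIGH_CHLORIDE if high_chloride else PIPETTE_PHYSIOLOGICAL
    return ReversalContext(
        internal=pipette, external=BATH_SLICING, temperature_C=temperature_C,
        p_hco3_rel=0.1,
    )
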