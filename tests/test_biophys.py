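"""Reversal-potential and Ohm's-law arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autapse.biophys import (
    BATH_SLICING,
    PIPETTE_PHYSIOLOGICAL,
    BiophysicsError,
    IonicSolution,
    ReversalContext,
    bicarbonate_inside,
    default_reversal_context,
    ghk_anion_reversal,
    nernst_potential,
    ohmic_conductance,
)


class TestNernst:
    def test_potassium_gradient_rounds_to_minus_95(self):
        # 126 mM K+ inside vs 3.5 mM outside at bath temperature
        e_k = nernst_potential(+1, 126.0, 3.5, 36.0)
        assert e_k == pytest.approx(-95.4667, abs=1e-3)
        assert round(e_k) == -95

    def test_equal_concentrations_give_zero(self):
        for temp in (20.0, 36.0, 40.0):
            assert nernst_potential(+1, 7.7, 7.7, temp) == 0.0

    @given(
        a=st.floats(0.5, 200.0),
        b=st.floats(0.5, 200.0),
        temp=st.floats(20.0, 40.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_valence_sign_swap_symmetry(self, a, b, temp):
        assert nernst_potential(-1, a, b, temp) == pytest.approx(
            nernst_potential(+1, b, a, temp), abs=1e-9
        )

    def test_monotone_in_outside_concentration(self):
        values = [nernst_potential(+1, 126.0, c, 36.0) for c in (1, 3.5, 10, 50)]
        assert values == sorted(values)

    @pytest.mark.parametrize(
        "args",
        [(0, 1.0, 1.0, 36.0), (+1, 0.0, 3.5, 36.0), (+1, 126.0, -2.0, 36.0)],
    )
    def test_domain_errors(self, args):
        with pytest.raises(BiophysicsError):
            nernst_potential(*args)


class TestBicarbonatePartition:
    def test_physiological_ph_pair(self):
        # 24 mM · 10^(7.0−7.4), frozen from an independent evaluation
        assert bicarbonate_inside(24.0, 7.4, 7.0) == pytest.approx(
            9.554572093283927, rel=1e-12
        )

    def test_equal_ph_is_identity(self):
        assert bicarbonate_inside(17.0, 7.2, 7.2) == 17.0

    def test_one_ph_unit_is_factor_ten(self):
        assert bicarbonate_inside(24.0, 7.4, 6.4) == pytest.approx(2.4)

    def test_rejects_nonpositive_bicarbonate(self):
        with pytest.raises(BiophysicsError):
            bicarbonate_inside(0.0, 7.4, 7.0)


class TestGhkAnionReversal:
    def test_physiological_recording_rounds_to_minus_73(self):
        for temp in (36.0, 37.0):
            e = ghk_anion_reversal(default_reversal_context(temperature_C=temp))
            assert round(e) == -73

    def test_high_chloride_pipette_near_zero(self):
        e = ghk_anion_reversal(
            default_reversal_context(high_chloride=True)
        )
        assert e == pytest.approx(0.2, abs=0.1)

    def test_no_gradient_gives_zero(self):
        ctx = ReversalContext(
            internal=IonicSolution(chloride_mM=100.0),
            external=IonicSolution(chloride_mM=100.0),
            temperature_C=36.0,
            p_hco3_rel=0.0,
        )
        assert ghk_anion_reversal(ctx) == 0.0

    def test_reduces_to_chloride_nernst_at_zero_permeability(self):
        for cl_in in (4.0, 8.0, 40.0, 140.0):
            ctx = ReversalContext(
                internal=IonicSolution(chloride_mM=cl_in),
                external=BATH_SLICING,
                temperature_C=36.0,
                p_hco3_rel=0.0,
            )
            assert ghk_anion_reversal(ctx) == pytest.approx(
                nernst_potential(-1, cl_in, 135.5, 36.0), abs=1e-9
            )

    def test_grid_against_independent_formula(self):
        # second implementation written against the same physics, but with
        # numpy in a different algebraic arrangement
        from scipy.constants import R, physical_constants

        F = physical_constants["Faraday constant"][0]

        def oracle(cl_in, hco3_in, cl_out, hco3_out, p, temp_c):
            rt_f = R * (temp_c + 273.15) / F * 1000.0
            num = np.log(cl_in + p * hco3_in) - np.log(cl_out + p * hco3_out)
            return rt_f * num

        hco3_in = bicarbonate_inside(24.0, 7.4, 7.0)
        for cl_in in np.linspace(4, 140, 18):
            for p in (0.0, 0.1, 0.3):
                ctx = ReversalContext(
                    internal=IonicSolution(
                        chloride_mM=cl_in,
                        bicarbonate_mM=hco3_in if p > 0 else None,
                    ),
                    external=BATH_SLICING,
                    temperature_C=36.0,
                    p_hco3_rel=p,
                )
                assert ghk_anion_reversal(ctx) == pytest.approx(
                    oracle(cl_in, hco3_in, 135.5, 24.0, p, 36.0), abs=1e-9
                )

    def test_monotone_in_internal_chloride(self):
        values = [
            ghk_anion_reversal(
                ReversalContext(
                    internal=IonicSolution(chloride_mM=c, ph=7.0),
                    external=BATH_SLICING,
                    temperature_C=36.0,
                )
            )
            for c in (4, 8, 20, 60, 140)
        ]
        assert values == sorted(values)

    def test_missing_species_named_in_error(self):
        ctx = ReversalContext(
            internal=IonicSolution(chloride_mM=8.0),  # no HCO3, no pH
            external=BATH_SLICING,
            temperature_C=36.0,
        )
        with pytest.raises(BiophysicsError, match="bicarbonate"):
            ghk_anion_reversal(ctx)

    def test_internal_bicarbonate_derived_from_ph_pair(self):
        explicit = ReversalContext(
            internal=IonicSolution(
                chloride_mM=8.0,
                bicarbonate_mM=bicarbonate_inside(24.0, 7.4, 7.0),
            ),
            external=BATH_SLICING,
            temperature_C=36.0,
        )
        derived = default_reversal_context()
        assert ghk_anion_reversal(derived) == pytest.approx(
            ghk_anion_reversal(explicit), abs=1e-12
        )


class TestOhmicConductance:
    def test_zero_current_is_zero_conductance(self):
        assert ohmic_conductance(0.0, -50.0, -73.0) == 0.0

    def test_median_autaptic_current(self):
        # 150.2 pA over a 30 mV driving force
        assert ohmic_conductance(150.2, -43.0, -73.0) == pytest.approx(
            5.006667, abs=1e-6
        )

    def test_inward_epsc(self):
        assert ohmic_conductance(-30.0, -55.0, 0.0) == pytest.approx(
            0.545455, abs=1e-6
        )

    @given(
        g=st.floats(0.01, 50.0),
        v=st.floats(-90.0, 0.0),
        e=st.floats(-90.0, 0.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, g, v, e):
        if abs(v - e) < 1e-6:
            return
        assert ohmic_conductance(g * (v - e), v, e) == pytest.approx(g, rel=1e-9)

    def test_zero_driving_force_rejected(self):
        with pytest.raises(BiophysicsError):
            ohmic_conductance(10.0, -73.0, -73.0)


class TestIonicSolutionValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(BiophysicsError):
            IonicSolution(chloride_mM=-1.0)

    def test_ph_bounds(self):
        with pytest.raises(BiophysicsError):
            IonicSolution(ph=15.0)

    def test_solution_presets_carry_printed_recipes(self):
        assert PIPETTE_PHYSIOLOGICAL.chloride_mM == 8.0
        assert BATH_SLICING.chloride_mM == 135.5
        assert BATH_SLICING.bicarbonate_mM == 24.0
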