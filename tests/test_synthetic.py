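"""Generators: determinism, thermodynamic consistency, round-trips."""

import numpy as np
import pytest

from nmrdyn.constants import R_GAS
from nmrdyn.dispersion import r2eff_from_intensities
from nmrdyn.shifts import binding_isotherm
from nmrdyn.synthetic import (
    ThermoTruth,
    generate_dispersion_intensities,
    generate_hollow_structure,
    generate_relaxation_series,
    generate_temp_shift_series,
    generate_titration_shifts,
    generate_two_state_system,
    reference_thermo_truth,
    truth_r2eff,
)


class TestTwoStateSystem:
    def test_reference_design_shape(self):
        truth = generate_two_state_system(n_residues=22, seed=0)
        assert len(truth.residue_ids) == 22
        assert truth.temperatures == [298.0, 300.5, 303.0, 305.5, 308.0]
        assert truth.fields_mhz == (500.0, 700.0)
        assert len(truth.per_residue_per_field_r20) == 44

    def test_reference_truth_anchored_at_printed_kinetics(self):
        truth = generate_two_state_system(seed=0)
        assert truth.p_b_at(298.0) == pytest.approx(0.085, rel=1e-9)
        assert truth.kex_at(298.0) == pytest.approx(812.0, rel=1e-9)

    def test_zero_enthalpy_gives_constant_ke(self):
        tt = reference_thermo_truth()
        flat = ThermoTruth(0.0, tt.ds_ba, tt.dh_act, tt.ds_act)
        truth = generate_two_state_system(thermo_truth=flat, seed=0)
        kes = [kab / kba for _, kab, kba in truth.per_temperature_kinetics]
        np.testing.assert_allclose(kes, kes[0], rtol=1e-12)

    def test_population_from_equilibrium_constant(self):
        # Ke chosen as 0.085/0.915 -> p_B = Ke/(1+Ke) = 0.085
        ds = R_GAS * np.log(0.085 / 0.915)
        truth = generate_two_state_system(
            thermo_truth=ThermoTruth(0.0, ds, 40e3, -50.0), seed=0
        )
        for t in truth.temperatures:
            assert truth.p_b_at(t) == pytest.approx(0.085, rel=1e-12)

    def test_vant_hoff_and_eyring_lines_exact(self):
        truth = generate_two_state_system(seed=3)
        temps = np.array(truth.temperatures)
        ke = np.array([kab / kba for _, kab, kba in truth.per_temperature_kinetics])
        kab = np.array([k for _, k, _ in truth.per_temperature_kinetics])
        # ln(Ke) and ln(kAB/T) exactly linear in 1/T
        for y in (np.log(ke), np.log(kab / temps)):
            coeffs = np.polyfit(1.0 / temps, y, 1)
            np.testing.assert_allclose(
                np.polyval(coeffs, 1.0 / temps), y, rtol=1e-12
            )

    def test_rejects_unidentifiable_population(self):
        with pytest.raises(ValueError, match="0.5"):
            generate_two_state_system(
                thermo_truth=ThermoTruth(0.0, 10.0, 40e3, -50.0), seed=0
            )

    def test_rejects_empty_field_list(self):
        with pytest.raises(ValueError, match="non-empty"):
            generate_two_state_system(fields=[], seed=0)

    def test_seed_determinism(self):
        a = generate_two_state_system(seed=42)
        b = generate_two_state_system(seed=42)
        assert a.per_residue_dw_ppm == b.per_residue_dw_ppm
        assert a.per_residue_per_field_r20 == b.per_residue_per_field_r20


class TestDispersionIntensities:
    def test_noiseless_roundtrip_recovers_forward_model(self, noiseless_truth):
        nus = (66.7, 200.0, 1000.0)
        table = generate_dispersion_intensities(noiseless_truth, nus)
        curves = r2eff_from_intensities(table)
        clean = truth_r2eff(noiseless_truth, nus)
        for c in curves:
            ref = clean[
                (clean["residue_id"] == c.residue_id)
                & (clean["field_mhz"] == c.field_mhz)
                & (clean["temp_k"] == c.temp_k)
            ].sort_values("nu_cpmg_hz")
            np.testing.assert_allclose(c.r2eff, ref["r2eff"], rtol=1e-10)

    def test_reference_row_always_present(self, noiseless_truth):
        table = generate_dispersion_intensities(noiseless_truth, (66.7, 1000.0))
        for _, grp in table.groupby(["residue_id", "field_mhz", "temp_k"]):
            assert (grp["nu_cpmg_hz"] == 0.0).sum() == 1

    def test_identical_seeds_bitwise_identical(self, noiseless_truth):
        a = generate_dispersion_intensities(noiseless_truth, (66.7,), seed=5)
        b = generate_dispersion_intensities(noiseless_truth, (66.7,), seed=5)
        assert a.equals(b)

    def test_incompatible_frequency_rejected(self, noiseless_truth):
        with pytest.raises(ValueError, match="closest valid"):
            generate_dispersion_intensities(noiseless_truth, (80.0,))


class TestRelaxationSeries:
    def test_zero_delay_returns_i0(self):
        df = generate_relaxation_series(1.0, [0.0, 0.1, 0.2, 0.3], i0=100.0)
        assert df["intensity"].iloc[0] == pytest.approx(100.0)

    def test_hand_evaluated_point(self):
        df = generate_relaxation_series(2.0, [0.0, 0.5], i0=100.0)
        assert df["intensity"].iloc[1] == pytest.approx(100.0 * np.exp(-1.0))

    def test_r2_delay_grid_accepted(self):
        delays = [0.01696, 0.03392, 0.05088, 0.06784, 0.0848, 0.10176,
                  0.11872, 0.13568, 0.20352, 0.23744]
        df = generate_relaxation_series(14.0, delays)
        assert len(df) == 10


class TestTitration:
    def test_zero_ligand_means_zero_shift(self):
        s = generate_titration_shifts(50e-6, 2.0, 80e-6, [0.0, 1e-5, 1e-4, 1e-3])
        assert s.dw_obs_ppm[0] == 0.0

    def test_tight_binding_saturates_at_dw_max(self):
        s = generate_titration_shifts(1e-12, 2.0, 80e-6, [0.0, 200e-6])
        assert s.dw_obs_ppm[-1] == pytest.approx(2.0, rel=1e-4)

    def test_isotherm_limits(self):
        # L0 = 0 exact zero; L0 -> infinity saturates
        assert binding_isotherm(np.array([0.0]), 5e-5, 2.0, 8e-5)[0] == 0.0
        huge = binding_isotherm(np.array([1e6 * 5e-5]), 5e-5, 2.0, 8e-5)[0]
        assert huge == pytest.approx(2.0, rel=1e-4)


class TestTempShiftSeries:
    def test_zero_slope_constant(self):
        s = generate_temp_shift_series(0.0, (298.0, 303.0, 308.0))
        assert np.ptp(s.h_ppm) == 0.0

    def test_linear_slope_exact(self):
        s = generate_temp_shift_series(-7.0, (298.0, 300.0, 303.0, 308.0))
        slope = np.polyfit(s.axis_values, s.h_ppm * 1000.0, 1)[0]
        assert slope == pytest.approx(-7.0, rel=1e-9)


class TestHollowShell:
    def test_analytic_volume_for_8A_cavity(self):
        fx = generate_hollow_structure(8.0, 12.5)
        assert fx.analytic_cavity_volume == pytest.approx(2144.66, abs=0.1)

    def test_degenerate_inner_radius(self):
        fx = generate_hollow_structure(0.0, 4.0, atom_radius=1.5,
                                       check_leaks=False)
        assert fx.analytic_cavity_volume == 0.0

    def test_pr10_sized_cavity(self):
        fx = generate_hollow_structure(8.4, 13.0)
        assert 2000.0 < fx.analytic_cavity_volume < 3000.0
        assert fx.analytic_cavity_volume == pytest.approx(2482.7, abs=1.0)

    def test_leaky_shell_rejected(self):
        with pytest.raises(ValueError, match="leaky"):
            generate_hollow_structure(8.0, 12.5, packing_spacing=4.5)

    def test_geometry_precondition(self):
        with pytest.raises(ValueError, match="outer_radius"):
            generate_hollow_structure(8.0, 9.0, atom_radius=1.5)
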