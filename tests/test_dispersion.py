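"""R2,eff extraction, error model, forward models and exchange filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdyn.constants import n15_omega_rad_per_ppm
from nmrdyn.dispersion import (
    DispersionCurve,
    DispersionDataset,
    bm_r2eff,
    bm_r2eff_batch,
    carver_richards_r2eff,
    echo_count,
    luz_meiboom_rex,
    r2eff_error,
    r2eff_from_intensities,
    select_exchange_residues,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["residue_id", "field_mhz", "temp_k", "condition",
                 "nu_cpmg_hz", "intensity"],
    )


class TestR2effFromIntensities:
    def test_equal_intensities_give_zero_rate(self):
        table = make_table([
            (1, 500.0, 298.0, "reference", 0.0, 100.0),
            (1, 500.0, 298.0, "cpmg", 66.7, 100.0),
        ])
        (curve,) = r2eff_from_intensities(table)
        assert curve.r2eff[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_inverted_rate(self):
        # I = I0 exp(-0.3) over 30 ms -> R2,eff = 10 s^-1 exactly
        table = make_table([
            (1, 500.0, 298.0, "reference", 0.0, 100.0),
            (1, 500.0, 298.0, "cpmg", 500.0, 100.0 * np.exp(-0.3)),
        ])
        (curve,) = r2eff_from_intensities(table, t_relax=0.030)
        assert curve.r2eff[0] == pytest.approx(10.0, rel=1e-12)

    def test_missing_reference_row_is_reported(self):
        table = make_table([(1, 500.0, 298.0, "cpmg", 66.7, 50.0)])
        with pytest.raises(ValueError, match="reference"):
            r2eff_from_intensities(table)

    def test_non_positive_intensity_flagged_with_frequency(self):
        table = make_table([
            (1, 500.0, 298.0, "reference", 0.0, 100.0),
            (1, 500.0, 298.0, "cpmg", 66.7, -1.0),
        ])
        with pytest.raises(ValueError, match="66.7"):
            r2eff_from_intensities(table)

    def test_roundtrip_identity_with_synthesised_intensities(self):
        # intensity synthesis from known rates inverts to machine precision
        rates = np.array([12.0, 9.5, 8.1])
        nus = np.array([66.7, 200.0, 1000.0])
        rows = [(1, 500.0, 298.0, "reference", 0.0, 100.0)]
        rows += [
            (1, 500.0, 298.0, "cpmg", nu, 100.0 * np.exp(-r * 0.03))
            for nu, r in zip(nus, rates)
        ]
        (curve,) = r2eff_from_intensities(make_table(rows))
        np.testing.assert_allclose(curve.r2eff, rates, rtol=1e-12)


class TestR2effError:
    def test_noise_term_dominates(self):
        assert r2eff_error(1.0, 100.0, 0.03, 5.0) == pytest.approx(1.0 / 3.0,
                                                                   rel=1e-9)

    def test_three_percent_floor(self):
        assert r2eff_error(0.0, 100.0, 0.03, 10.0) == pytest.approx(0.3)

    def test_floor_applies_to_every_emitted_error(self, small_noisy_dataset):
        _, dataset = small_noisy_dataset
        for curve in dataset.curves:
            assert np.all(curve.r2eff_err >= 0.03 * np.abs(curve.r2eff) - 1e-12)


class TestEchoCount:
    def test_nominal_frequencies_accepted(self):
        assert echo_count(66.7, 0.030) == 4
        assert echo_count(1000.0, 0.030) == 60

    def test_incompatible_frequency_reports_closest(self):
        with pytest.raises(ValueError, match="closest valid"):
            echo_count(80.0, 0.030)


class TestBlochMcConnell:
    def test_no_shift_difference_means_no_dispersion(self):
        for nu in (66.7, 200.0, 1000.0):
            assert bm_r2eff(50.0, 500.0, 0.0, 12.0, nu) == pytest.approx(
                12.0, rel=1e-9
            )

    def test_vanishing_minor_population_means_no_dispersion(self):
        dw = 2.0 * n15_omega_rad_per_ppm(500.0)
        assert bm_r2eff(1e-6, 1000.0, dw, 12.0, 66.7) == pytest.approx(
            12.0, abs=1e-3
        )

    def test_fast_exchange_matches_luz_meiboom(self):
        # kex = 10 |dw|: closed-form fast-exchange limit within 5%
        dw = 1.0 * n15_omega_rad_per_ppm(500.0)
        kex = 10.0 * dw
        p_b = 0.05
        for nu in (66.7, 200.0, 1000.0):
            rex_bm = bm_r2eff(p_b * kex, (1 - p_b) * kex, dw, 10.0, nu) - 10.0
            rex_lm = luz_meiboom_rex(1 - p_b, p_b, dw, kex, nu)
            assert rex_bm == pytest.approx(rex_lm, rel=0.05)

    def test_batch_agrees_with_scalar(self):
        nus = np.array([66.7, 133.3, 200.0, 600.0, 1000.0])
        n_echo = np.array([echo_count(v, 0.03) for v in nus])
        dw = 2.0 * n15_omega_rad_per_ppm(700.0)
        batch = bm_r2eff_batch(
            np.full(5, 70.0), np.full(5, 750.0), np.full(5, dw),
            np.full(5, 14.0), n_echo,
        )
        scalar = [bm_r2eff(70.0, 750.0, dw, 14.0, v) for v in nus]
        np.testing.assert_allclose(batch, scalar, rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        kex=st.floats(100.0, 5000.0),
        p_b=st.floats(0.01, 0.15),
        dw_ppm=st.floats(0.5, 6.0),
        r20=st.floats(5.0, 25.0),
    )
    def test_monotonically_non_increasing_in_nu(self, kex, p_b, dw_ppm, r20):
        dw = dw_ppm * n15_omega_rad_per_ppm(500.0)
        nus = [66.7, 133.3, 200.0, 333.3, 600.0, 1000.0]
        vals = [bm_r2eff(p_b * kex, (1 - p_b) * kex, dw, r20, v) for v in nus]
        assert all(b <= a + 1e-6 for a, b in zip(vals, vals[1:]))


class TestCarverRichards:
    def test_no_exchange_returns_intrinsic_rate(self):
        assert carver_richards_r2eff(50.0, 500.0, 0.0, 12.0, 66.7) == 12.0

    def test_high_frequency_limit_refocuses(self):
        dw = 2.0 * n15_omega_rad_per_ppm(500.0)
        # echo spacing -> 0: exchange contribution refocused
        val = carver_richards_r2eff(70.0, 750.0, dw, 12.0, 100000.0 / 3.0)
        assert val == pytest.approx(12.0, abs=0.2)

    def test_asymptotic_form_matches_full_form_in_fast_exchange(self):
        dw = 0.5 * n15_omega_rad_per_ppm(500.0)
        kex = 5000.0
        for nu in (66.7, 333.3, 1000.0):
            full = carver_richards_r2eff(0.05 * kex, 0.95 * kex, dw, 10.0, nu)
            asym = carver_richards_r2eff(0.05 * kex, 0.95 * kex, dw, 10.0, nu,
                                         asymptotic=True)
            assert full == pytest.approx(asym, rel=0.005)

    def test_asymptotic_form_deviates_in_slow_exchange(self):
        # documented disagreement region of the eigenvalue-only shorthand
        dw = 1.0 * n15_omega_rad_per_ppm(700.0)
        kex, p_b = 300.0, 0.15
        full = carver_richards_r2eff(p_b * kex, (1 - p_b) * kex, dw, 10.0, 66.7)
        asym = carver_richards_r2eff(p_b * kex, (1 - p_b) * kex, dw, 10.0,
                                     66.7, asymptotic=True)
        assert abs(asym - full) / full > 0.02


class TestSelectExchangeResidues:
    @staticmethod
    def flat_curve(res, level=10.0):
        nus = np.array([66.7, 200.0, 1000.0])
        return DispersionCurve(res, 500.0, 298.0, nus,
                               np.full(3, level), np.full(3, 0.3))

    @staticmethod
    def dispersive_curve(res, rex=8.0):
        nus = np.array([66.7, 200.0, 1000.0])
        r2 = np.array([10.0 + rex, 10.0 + 0.5 * rex, 10.0])
        return DispersionCurve(res, 500.0, 298.0, nus, r2, 0.03 * r2 + 0.1)

    def test_flat_curves_excluded_dispersive_retained(self):
        ds = DispersionDataset([self.flat_curve(1), self.dispersive_curve(2)])
        selected, table = select_exchange_residues(ds)
        assert selected == [2]
        assert set(table["residue_id"]) == {1, 2}

    def test_any_condition_above_threshold_retains(self):
        curves = [self.flat_curve(1), self.dispersive_curve(1, rex=8.0)]
        curves[1].temp_k = 308.0
        selected, _ = select_exchange_residues(DispersionDataset(curves))
        assert selected == [1]

    def test_quality_tags_override_amplitude(self):
        ds = DispersionDataset(
            [self.dispersive_curve(3)], excluded=[(3, "overlap")]
        )
        with pytest.warns(UserWarning, match="quality"):
            selected, _ = select_exchange_residues(ds)
        assert selected == []
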