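"""Constitutive models: dielectric sigmoids, water content, heat capacities."""

import numpy as np
import pytest

from mwablate import properties as P


class TestSigmoidDielectrics:
    @pytest.mark.parametrize(
        "fn, amp",
        [
            (P.relative_permittivity, "s1"),
            (P.electrical_conductivity, "r1"),
        ],
    )
    def test_saturation_and_midpoint(self, fn, amp):
        c = P.HEALTHY_LIVER_DIELECTRIC
        a = getattr(c, amp)
        assert fn(-1e4, c) == pytest.approx(a, rel=1e-12)
        mid = c.s2 / c.s3 if amp == "s1" else c.r2 / c.r3
        assert fn(mid, c) == pytest.approx(a / 2.0, rel=1e-12)

    def test_baseline_values_at_body_temperature(self):
        # frozen regression values from direct evaluation of the defaults
        assert P.relative_permittivity(37.0, P.HEALTHY_LIVER_DIELECTRIC) == (
            pytest.approx(46.915283697426915, rel=1e-12)
        )
        assert P.electrical_conductivity(37.0, P.TUMOR_DIELECTRIC) == (
            pytest.approx(2.3320015487866814, rel=1e-12)
        )

    def test_strictly_decreasing(self):
        T = np.linspace(0.0, 150.0, 600)
        for c in (P.HEALTHY_LIVER_DIELECTRIC, P.TUMOR_DIELECTRIC):
            assert np.all(np.diff(P.relative_permittivity(T, c)) < 0)
            assert np.all(np.diff(P.electrical_conductivity(T, c)) < 0)

    def test_tumor_contrast_at_37C(self):
        """Tumors read higher than healthy liver: ~24% permittivity, ~11% conductivity."""
        re = P.relative_permittivity(37.0, P.TUMOR_DIELECTRIC) / P.relative_permittivity(
            37.0, P.HEALTHY_LIVER_DIELECTRIC
        )
        rs = P.electrical_conductivity(37.0, P.TUMOR_DIELECTRIC) / P.electrical_conductivity(
            37.0, P.HEALTHY_LIVER_DIELECTRIC
        )
        assert 1.15 <= re <= 1.35
        assert 1.05 <= rs <= 1.20

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            P.SigmoidDielectric(s1=-1, s2=1, s3=1, r1=1, r2=1, r3=1)


class TestWaterContent:
    def test_steady_state_value(self):
        assert P.water_content(70.0) == pytest.approx(0.778, abs=5e-4)

    def test_constant_extension_below_70C(self):
        assert P.water_content(20.0) == P.water_content(70.0)

    def test_branch_joins_agree(self):
        # both adjoining branch formulas evaluated at the join temperature
        w1 = 0.778 * (1 - np.exp((100.0 - 106.0) / 3.42))
        w2 = 7.053 - 0.064096 * 100.0
        assert abs(w1 - w2) < 1e-3
        assert w1 == pytest.approx(0.6434, abs=1e-4)
        w2b = 7.053 - 0.064096 * 104.0
        w3 = 0.778 * np.exp(-(104.0 - 80.0) / 34.37)
        assert abs(w2b - w3) < 1e-3
        assert w3 == pytest.approx(0.387, abs=1e-3)

    def test_continuous_and_non_increasing(self):
        T = np.arange(60.0, 200.0, 0.01)
        W = P.water_content(T)
        assert np.all(np.diff(W) <= 0)
        assert np.max(np.abs(np.diff(W))) < 1e-3  # no jump at any branch join
        assert np.all((W >= 0) & (W <= 0.778 + 1e-12))


class TestEffectiveSpecificHeat:
    def test_equals_c_below_70C(self):
        liver = P.material_lookup("healthy_liver")
        assert P.effective_specific_heat(50.0, liver) == liver.specific_heat

    def test_linear_branch_latent_surplus(self):
        # analytic derivative of the 100-104 degC branch: alpha * 0.064096
        liver = P.material_lookup("healthy_liver")
        surplus = P.effective_specific_heat(102.0, liver) - liver.specific_heat
        assert surplus == pytest.approx(2.26e6 * 0.064096, rel=1e-12)

    def test_exponential_tail_at_130C(self):
        liver = P.material_lookup("healthy_liver")
        surplus = P.effective_specific_heat(130.0, liver) - liver.specific_heat
        expected = 2.26e6 * (0.778 / 34.37) * np.exp(-(130.0 - 80.0) / 34.37)
        assert surplus == pytest.approx(expected, rel=1e-12)

    def test_matches_finite_difference_of_water_curve(self):
        """c' - c must equal -alpha dW/dT: centered-difference oracle to 1%."""
        liver = P.material_lookup("healthy_liver")
        h = 1e-4
        for T in np.concatenate(
            [np.arange(72.0, 99.0, 1.7), np.arange(100.5, 103.5, 0.7), [110.0, 150.0]]
        ):
            fd = -(P.water_content(T + h) - P.water_content(T - h)) / (2 * h)
            surplus = P.effective_specific_heat(T, liver) - liver.specific_heat
            assert surplus == pytest.approx(2.26e6 * fd, rel=1e-2)

    def test_never_below_c(self):
        liver = P.material_lookup("tumor")
        T = np.linspace(0.0, 200.0, 2000)
        assert np.all(P.effective_specific_heat(T, liver) >= liver.specific_heat)

    def test_as_printed_mode_differs_by_density(self):
        liver = P.material_lookup("healthy_liver")
        a = P.effective_specific_heat(102.0, liver) - liver.specific_heat
        b = P.effective_specific_heat(102.0, liver, mode="as_printed") - liver.specific_heat
        assert b == pytest.approx(a * liver.density, rel=1e-12)


class TestVaporizationRhoC:
    def test_three_branches(self):
        liver = P.material_lookup("healthy_liver")
        vc = P.DEFAULT_VAPORIZATION
        assert P.vaporization_rho_c(50.0, "tissue") == pytest.approx(
            liver.density * liver.specific_heat
        )
        assert P.vaporization_rho_c(99.5, "tissue") == pytest.approx(
            vc.h_fg * vc.C_w_tissue / 1.0
        )
        assert P.vaporization_rho_c(120.0, "tissue") == pytest.approx(vc.rho_g * vc.c_g)

    def test_blood_phase_uses_blood_constants(self):
        blood = P.material_lookup("blood")
        vc = P.DEFAULT_VAPORIZATION
        assert P.vaporization_rho_c(80.0, "blood") == pytest.approx(blood.rho_c)
        assert P.vaporization_rho_c(99.5, "blood") == pytest.approx(
            vc.h_fg * vc.C_w_blood
        )

    def test_invalid_band_width_rejected(self):
        with pytest.raises(ValueError):
            P.VaporizationConstants(delta_T=0.0)

    def test_gas_phase_below_liquid_enforced(self):
        with pytest.raises(ValueError):
            P.VaporizationConstants(rho_g=2000.0, c_g=4000.0)


class TestMaterialLookup:
    @pytest.mark.parametrize(
        "name, rho, k, c",
        [
            ("healthy_liver", 1079.0, 0.52, 3540.0),
            ("tumor", 1040.0, 0.57, 3960.0),
            ("blood", 1060.0, 0.5, 3600.0),
        ],
    )
    def test_tabulated_constants(self, name, rho, k, c):
        m = P.material_lookup(name)
        assert (m.density, m.thermal_conductivity, m.specific_heat) == (rho, k, c)

    def test_unknown_material(self):
        with pytest.raises(KeyError, match="unknown material"):
            P.material_lookup("bone")

    def test_positive_invariant(self):
        with pytest.raises(ValueError):
            P.MaterialConstants("x", -1.0, 0.5, 3500.0)
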