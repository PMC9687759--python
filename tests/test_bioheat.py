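"""Bioheat backends: conduction/perfusion oracles, model limits, conservation."""

import math

import numpy as np
import pytest

from mwablate import bioheat as B
from mwablate import geometry as G
from mwablate import properties as P


def insulated(r, z):
    return "insulated"


class TestPennes:
    def test_uniform_equilibrium_is_stationary(self):
        m = G.rectangle_mesh(0.0, 0.02, 0.0, 0.02, 8, 8)
        s = B.BioheatSolver(m)
        st = s.step_pennes(B.initial_state(m), 1.0, 0.0)
        assert np.max(np.abs(st.T - 37.0)) < 1e-9

    def test_uniform_source_perfusion_steady_state(self):
        """T* = 37 + Q / (rho_b omega_b c_b) with no-flux walls, 0.5%."""
        m = G.rectangle_mesh(0.005, 0.015, 0.0, 0.01, 5, 5, tagger=insulated)
        s = B.BioheatSolver(m)
        st = B.initial_state(m)
        q = 2e4
        for _ in range(260):
            st = s.step_pennes(st, 5.0, q)
        blood = P.material_lookup("blood")
        t_star = 37.0 + q / (blood.density * s.perfusion.omega_b * blood.specific_heat)
        assert st.T.mean() == pytest.approx(t_star, rel=0.005)
        assert st.T.std() < 1e-6  # spatially uniform

    def test_slab_conduction_vs_fourier_series(self):
        """1-D slab cooling matches the analytic series within 0.5%."""
        L, dt, t_end = 0.02, 0.5, 60.0

        def tagger(r, z):
            return "outer" if (abs(z) < 1e-12 or abs(z - L) < 1e-12) else "insulated"

        m = G.rectangle_mesh(0.005, 0.007, 0.0, L, 2, 80, tagger=tagger)
        s = B.BioheatSolver(
            m, vaporization="none", perfusion=B.PerfusionModel(omega_b=0.0)
        )
        st = B.initial_state(m)
        st.T[:] = 57.0
        st.T[s.dirichlet_nodes] = 37.0
        for _ in range(int(t_end / dt)):
            st = s.step_pennes(st, dt, 0.0)
        mat = P.material_lookup("healthy_liver")
        kappa = mat.thermal_conductivity / mat.rho_c
        z = s.mesh.nodes[:, 1]
        t_an = np.full_like(z, 37.0)
        for n in range(1, 399, 2):
            t_an += (
                20.0 * 4 / (n * math.pi)
                * np.sin(n * math.pi * z / L)
                * math.exp(-kappa * (n * math.pi / L) ** 2 * t_end)
            )
        assert np.max(np.abs(st.T - t_an)) / 20.0 < 0.005

    def test_negative_dt_rejected(self):
        m = G.rectangle_mesh(0.0, 0.01, 0.0, 0.01, 4, 4)
        s = B.BioheatSolver(m)
        with pytest.raises(ValueError):
            s.step_pennes(B.initial_state(m), -1.0, 0.0)

    def test_maximum_principle_conduction(self):
        """Source-free conduction stays within initial/boundary extremes."""
        m = G.rectangle_mesh(0.001, 0.02, 0.0, 0.02, 10, 10, tagger=insulated)
        s = B.BioheatSolver(
            m, vaporization="none", perfusion=B.PerfusionModel(omega_b=0.0)
        )
        st = B.initial_state(m)
        rng = np.random.default_rng(3)
        st.T = 37.0 + 30.0 * rng.random(m.num_nodes)
        lo, hi = st.T.min(), st.T.max()
        for _ in range(40):
            st = s.step_pennes(st, 2.0, 0.0)
            assert st.T.min() >= lo - 1e-9 and st.T.max() <= hi + 1e-9

    def test_energy_conservation_insulated(self):
        """Total enthalpy drifts < 0.5% over 600 s with no sinks or sources."""
        from mwablate import fem

        m = G.rectangle_mesh(0.002, 0.022, 0.0, 0.02, 10, 10, tagger=insulated)
        s = B.BioheatSolver(
            m, vaporization="none", perfusion=B.PerfusionModel(omega_b=0.0)
        )
        st = B.initial_state(m)
        r, z = m.nodes[:, 0], m.nodes[:, 1]
        st.T = 37.0 + 25.0 * np.exp(-((r - 0.012) ** 2 + (z - 0.01) ** 2) / 2e-5)
        lump = fem.assemble_mass(
            m.nodes, m.triangles, np.ones(len(m.triangles)), lumped=True
        )
        mat = P.material_lookup("healthy_liver")
        e0 = float(lump @ (st.T * mat.rho_c))
        for _ in range(60):
            st = s.step_pennes(st, 10.0, 0.0)
        e1 = float(lump @ (st.T * mat.rho_c))
        assert abs(e1 - e0) / e0 < 0.005


class TestLTE:
    def test_zero_porosity_equals_conduction(self):
        m = G.rectangle_mesh(0.002, 0.012, 0.0, 0.01, 8, 8, tagger=insulated)
        perf = B.PerfusionModel(omega_b=0.0, porosity_eps=0.0)
        s = B.BioheatSolver(m, perfusion=perf, vaporization="none")
        q = 4e5 * np.ones(len(m.triangles))
        st_a, st_b = B.initial_state(m), B.initial_state(m)
        for _ in range(10):
            st_a = s.step_lte(st_a, 2.0, q)
            st_b = s.step_pennes(st_b, 2.0, q)
        assert np.max(np.abs(st_a.T - st_b.T)) < 1e-9

    def test_advection_of_uniform_field_is_invisible(self):
        m = G.rectangle_mesh(0.002, 0.012, 0.0, 0.01, 8, 8, tagger=insulated)
        perf = B.PerfusionModel(omega_b=0.0, porosity_eps=0.2, u=(0.0, 1e-3))
        s = B.BioheatSolver(m, perfusion=perf, vaporization="none")
        st = B.initial_state(m)
        st.T[:] = 55.0
        st = s.step_lte(st, 2.0, 0.0)
        assert np.max(np.abs(st.T - 55.0)) < 1e-9

    def test_small_porosity_tracks_pennes_with_mapped_parameters(self):
        """LTE(eps small, u=0) stays within 1 degC of the mapped Pennes run."""
        m = G.rectangle_mesh(0.002, 0.016, 0.0, 0.014, 10, 10, tagger=insulated)
        eps = 0.05
        perf = B.PerfusionModel(omega_b=0.0, porosity_eps=eps)
        s = B.BioheatSolver(
            m, perfusion=perf, vaporization="none", lte_conductivity="mixture"
        )
        zc = m.nodes[m.triangles].mean(axis=1)
        q = 5e6 * np.exp(-((zc[:, 0] - 0.009) ** 2 + (zc[:, 1] - 0.007) ** 2) / 4e-6)
        st_l, st_p = B.initial_state(m), B.initial_state(m)
        for _ in range(30):
            st_l = s.step_lte(st_l, 2.0, q)
            st_p = s.step_pennes(st_p, 2.0, q)
        assert st_p.T.max() > 45.0  # the run actually heats
        assert np.max(np.abs(st_l.T - st_p.T)) < 1.0


class TestLTNE:
    def test_stiff_coupling_limit_approaches_lte(self):
        """h_c*a -> large forces T_t = T_b and the LTE trajectory, 1%."""
        m = G.rectangle_mesh(0.002, 0.012, 0.0, 0.01, 8, 8, tagger=insulated)
        perf = B.PerfusionModel(omega_b=0.0, porosity_eps=0.1, h_c_a=1e9)
        s = B.BioheatSolver(
            m, perfusion=perf, vaporization="none", lte_conductivity="mixture"
        )
        zc = m.nodes[m.triangles].mean(axis=1)
        q = 5e5 * np.exp(-((zc[:, 0] - 0.007) ** 2 + (zc[:, 1] - 0.005) ** 2) / 4e-6)
        st_l, st_e = B.initial_state(m, "ltne"), B.initial_state(m, "lte")
        for _ in range(30):
            st_l = s.step_ltne(st_l, 2.0, q)
            st_e = s.step_lte(st_e, 2.0, q)
        spread = st_e.T.max() - 37.0
        assert spread > 2.0
        assert np.max(np.abs(st_l.T - st_l.T_blood)) / spread < 0.01
        assert np.max(np.abs(st_l.T - st_e.T)) / spread < 0.01

    def test_zero_porosity_blood_inert(self):
        m = G.rectangle_mesh(0.002, 0.012, 0.0, 0.01, 6, 6, tagger=insulated)
        perf = B.PerfusionModel(omega_b=1e-3, porosity_eps=0.0, h_c_a=1e4)
        s = B.BioheatSolver(m, perfusion=perf, vaporization="none")
        st = B.initial_state(m, "ltne")
        st.T_blood[:] = 41.0
        out = s.step_ltne(st, 2.0, 1e5)
        assert np.allclose(out.T_blood, 41.0)  # inert phase holds its value
        assert out.T.max() > 37.0  # tissue still heats

    def test_uncoupled_phases_evolve_independently(self):
        """With h_c*a = omega_b = 0 and u = 0 the phases are two conduction
        problems: perturbing the tissue field leaves the blood field unchanged."""
        m = G.rectangle_mesh(0.002, 0.012, 0.0, 0.01, 6, 6, tagger=insulated)
        perf = B.PerfusionModel(omega_b=0.0, porosity_eps=0.3, h_c_a=0.0)
        s = B.BioheatSolver(m, perfusion=perf, vaporization="none")
        q = 2e5 * np.ones(len(m.triangles))
        st1 = B.initial_state(m, "ltne")
        st2 = B.initial_state(m, "ltne")
        st2.T = st2.T + 8.0 * np.exp(
            -((m.nodes[:, 0] - 0.007) ** 2) / 1e-5
        )  # tissue-only perturbation
        out1 = s.step_ltne(st1, 2.0, q)
        out2 = s.step_ltne(st2, 2.0, q)
        assert np.allclose(out1.T_blood, out2.T_blood, atol=1e-10)
        assert not np.allclose(out1.T, out2.T)


class TestVaporizationCoupling:
    @pytest.mark.parametrize("treatment", ["effective_heat", "enthalpy"])
    def test_vaporization_retards_heating(self, treatment):
        """Latent heat holds temperatures near the boiling plateau."""
        m = G.rectangle_mesh(0.002, 0.01, 0.0, 0.008, 6, 6, tagger=insulated)
        base = B.BioheatSolver(
            m, vaporization="none", perfusion=B.PerfusionModel(omega_b=0.0)
        )
        vap = B.BioheatSolver(
            m, vaporization=treatment, perfusion=B.PerfusionModel(omega_b=0.0)
        )
        q = 4e7 * np.ones(len(m.triangles))
        st_a, st_b = B.initial_state(m), B.initial_state(m)
        for _ in range(20):
            st_a = base.step_pennes(st_a, 1.0, q)
            st_b = vap.step_pennes(st_b, 1.0, q)
        assert st_b.T.max() < st_a.T.max()
        assert st_a.T.max() > 100.0
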