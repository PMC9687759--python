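"""Transient bioheat solvers: Pennes (default), LTE and LTNE backends.

All three backends share the axisymmetric P1 discretization, implicit-Euler
time stepping (damped Newton on the cumulative-enthalpy form for the
single-field backends, damped Picard with a chord heat capacity for the
two-field LTNE system), a Dirichlet 37 degC condition on the outer tissue
boundary, and natural (adiabatic) conditions on the symmetry axis and the
antenna-tissue interface.

* Pennes: single tissue temperature with a perfusion heat sink
  beta * rho_b * omega_b * c_b * (T_core - T) that shuts down as thermal
  damage accumulates (beta from the damage module).
* LTNE: two-temperature porous-media model; tissue and blood phases exchange
  heat through a lumped interfacial conductance h_c*a plus the perfusion
  term, the blood phase advects with velocity u and vaporizes with its own
  enthalpy branch.
* LTE: the single-temperature porous-media limit with effective capacity
  (1-eps)(rho c)_t + eps (rho c)_b and an advective blood term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem, properties
from .geometry import Mesh

THERMAL_REGIONS = ("healthy_liver", "tumor")
T_BODY = 37.0


@dataclass(frozen=True)
class PerfusionModel:
    """Blood-side parameters of the bioheat models.

    None of these are printed alongside the governing equations in the
    hepatic-ablation literature's parameter tables used here, so the numeric
    defaults are external literature values: liver perfusion rate
    omega_b ~ 6.4e-3 1/s, blood volume fraction (porosity) ~ 0.1 and a
    lumped interfacial conductance h_c*a ~ 1e5 W/(m^3 degC).
    """

    omega_b: float = 6.4e-3  # 1/s
    porosity_eps: float = 0.1  # blood volume fraction (LTE/LTNE)
    h_c_a: float = 1.0e5  # W/(m^3 degC), LTNE interfacial exchange
    u: tuple[float, float] = (0.0, 0.0)  # blood velocity (r, z), m/s
    T_core: float = T_BODY
    Q_m: float = 0.0  # metabolic heat W/m^3 (negligible during ablation)

    def __post_init__(self) -> None:
        if not 0.0 <= self.porosity_eps < 1.0:
            raise ValueError("porosity must lie in [0, 1)")
        if self.omega_b < 0 or self.h_c_a < 0:
            raise ValueError("perfusion rate and h_c*a must be non-negative")


@dataclass
class ThermalState:
    """Nodal thermal state on the tissue submesh."""

    T: np.ndarray  # tissue temperature, degC
    time: float = 0.0
    T_blood: np.ndarray | None = None  # LTNE only
    Omega: np.ndarray | None = None  # Arrhenius damage, maintained externally

    def copy(self) -> "ThermalState":
        return ThermalState(
            self.T.copy(),
            self.time,
            None if self.T_blood is None else self.T_blood.copy(),
            None if self.Omega is None else self.Omega.copy(),
        )


class PicardNonConvergence(RuntimeError):
    def __init__(self, residual: float, tol: float):
        self.residual = residual
        super().__init__(
            f"Picard iteration stalled: residual {residual:.3g} degC (tol {tol:g})"
        )


class BioheatSolver:
    """Shared FEM scaffolding for the three bioheat backends.

    Operates on the tissue submesh of a simulation mesh (or any mesh made of
    tissue regions). Matrices that do not depend on temperature or damage
    (conductivity stiffness, geometric mass) are assembled once.
    """

    def __init__(
        self,
        mesh: Mesh,
        perfusion: PerfusionModel | None = None,
        vaporization: str = "effective_heat",
        effective_heat_mode: str = "mass_fraction",
        vapor_consts: properties.VaporizationConstants = properties.DEFAULT_VAPORIZATION,
        water: properties.WaterModel = properties.DEFAULT_WATER,
        dirichlet_tags: tuple[str, ...] = ("outer",),
        dirichlet_value: float = T_BODY,
        picard_tol: float = 1e-3,
        picard_max: int = 40,
        lte_conductivity: str = "combined",
    ):
        if any(r not in THERMAL_REGIONS for r in np.unique(mesh.region)):
            mesh = mesh.submesh([r for r in THERMAL_REGIONS if r in mesh.region])
        self.mesh = mesh
        self.perfusion = perfusion or PerfusionModel()
        if vaporization not in ("effective_heat", "enthalpy", "none"):
            raise ValueError(f"unknown vaporization treatment {vaporization!r}")
        self.vaporization = vaporization
        self.effective_heat_mode = effective_heat_mode
        self.vapor_consts = vapor_consts
        self.water = water
        self.picard_tol = picard_tol
        self.picard_max = picard_max
        if lte_conductivity not in ("combined", "mixture"):
            raise ValueError("lte_conductivity must be 'combined' or 'mixture'")
        self.lte_conductivity = lte_conductivity
        self.blood = properties.material_lookup("blood")

        n = mesh.num_nodes
        tris = mesh.triangles
        self._mat = [properties.material_lookup(r) for r in mesh.region]
        self.k_elem = np.array([m.thermal_conductivity for m in self._mat])
        self.rho_elem = np.array([m.density for m in self._mat])
        self.c_elem = np.array([m.specific_heat for m in self._mat])
        self.K = fem.assemble_stiffness(mesh.nodes, tris, self.k_elem)
        self._ones_mass = fem.assemble_mass(mesh.nodes, tris, np.ones(len(tris)))
        dir_nodes: list[np.ndarray] = []
        for tag in dirichlet_tags:
            if tag in mesh.boundary and len(mesh.boundary[tag]):
                dir_nodes.append(mesh.boundary[tag][:, :2].ravel())
        self.dirichlet_nodes = (
            np.unique(np.concatenate(dir_nodes)) if dir_nodes else np.array([], int)
        )
        self.dirichlet_value = dirichlet_value
        self.last_picard: tuple[int, float] = (0, 0.0)

        # nodal lumped quantities for the Newton transient term: geometric
        # volume weights and volume-averaged material constants per node
        self.Mg = np.asarray(self._ones_mass.sum(axis=1)).ravel()
        area, _ = fem.tri_geometry(mesh.nodes, tris)
        w_e = area * mesh.nodes[tris, 0].mean(axis=1) / 3.0
        wsum = np.zeros(n)
        rho_acc = np.zeros(n)
        rhoc_acc = np.zeros(n)
        for k in range(3):
            np.add.at(wsum, tris[:, k], w_e)
            np.add.at(rho_acc, tris[:, k], w_e * self.rho_elem)
            np.add.at(rhoc_acc, tris[:, k], w_e * self.rho_elem * self.c_elem)
        self.rho_node = rho_acc / wsum
        self.rhoc_node = rhoc_acc / wsum

    # -- coefficient evaluation ------------------------------------------------
    #
    # The vaporization band makes (rho c)(T) spike by orders of magnitude over
    # a few degC; a pointwise Picard coefficient then oscillates across the
    # band. The chord (secant) apparent heat capacity
    #   (rho c)_eff = [H(T_guess) - H(T_old)] / (T_guess - T_old),
    # with H the cumulative volumetric enthalpy, is the standard robust and
    # energy-consistent alternative and reduces to the pointwise value for
    # small temperature increments.

    def _tissue_enthalpy(self, T: np.ndarray) -> np.ndarray:
        """Cumulative volumetric enthalpy H(T) of the tissue phase, (M, 3)."""
        if self.vaporization == "effective_heat":
            alpha = self.water.latent_heat_alpha
            if self.effective_heat_mode == "as_printed":
                alpha = alpha * self.rho_elem[:, None]
            W = properties.water_content(T, self.water)
            return self.rho_elem[:, None] * (
                self.c_elem[:, None] * T - alpha * (W - self.water.W0)
            )
        # enthalpy method: piecewise linear in T with a latent spike at 99-100
        vc = self.vapor_consts
        liquid = (self.rho_elem * self.c_elem)[:, None]
        spike = vc.h_fg * vc.C_w_tissue / vc.delta_T
        gas = vc.rho_g * vc.c_g
        t0 = 100.0 - vc.delta_T
        return np.select(
            [T <= t0, T <= 100.0],
            [liquid * T, liquid * t0 + spike * (T - t0)],
            default=liquid * t0 + spike * vc.delta_T + gas * (T - 100.0),
        )

    def _tissue_rho_c_quad(self, T_guess: np.ndarray, T_old: np.ndarray) -> np.ndarray:
        """Apparent (rho c) of the tissue phase at the quadrature points."""
        Tg = fem.at_quad(T_guess, self.mesh.triangles)
        if self.vaporization == "none":
            return (self.rho_elem * self.c_elem)[:, None] * np.ones_like(Tg)
        To = fem.at_quad(T_old, self.mesh.triangles)
        dT = Tg - To
        small = np.abs(dT) < 1e-4
        chord = (self._tissue_enthalpy(Tg) - self._tissue_enthalpy(To)) / np.where(
            small, 1.0, dT
        )
        return np.where(small, self._tissue_rho_c_point(Tg), chord)

    def _tissue_rho_c_point(self, Tq: np.ndarray) -> np.ndarray:
        if self.vaporization == "effective_heat":
            dW = properties.water_content_derivative(Tq, self.water)
            if self.effective_heat_mode == "mass_fraction":
                c_eff = self.c_elem[:, None] - self.water.latent_heat_alpha * dW
            else:
                c_eff = (
                    self.c_elem[:, None]
                    - self.water.latent_heat_alpha * self.rho_elem[:, None] * dW
                )
            return self.rho_elem[:, None] * c_eff
        vc = self.vapor_consts
        liquid = (self.rho_elem * self.c_elem)[:, None] * np.ones_like(Tq)
        spike = vc.h_fg * vc.C_w_tissue / vc.delta_T
        return np.select(
            [Tq <= 100.0 - vc.delta_T, Tq <= 100.0],
            [liquid, spike],
            default=vc.rho_g * vc.c_g,
        )

    def _blood_enthalpy(self, T: np.ndarray) -> np.ndarray:
        vc = self.vapor_consts
        liquid = self.blood.rho_c
        spike = vc.h_fg * vc.C_w_blood / vc.delta_T
        gas = vc.rho_g * vc.c_g
        t0 = 100.0 - vc.delta_T
        return np.select(
            [T <= t0, T <= 100.0],
            [liquid * T, liquid * t0 + spike * (T - t0)],
            default=liquid * t0 + spike * vc.delta_T + gas * (T - 100.0),
        )

    def _blood_rho_c_quad(self, T_guess: np.ndarray, T_old: np.ndarray) -> np.ndarray:
        if self.vaporization != "enthalpy":
            return np.full(
                (len(self.mesh.triangles), 3), self.blood.rho_c, dtype=float
            )
        Tg = fem.at_quad(T_guess, self.mesh.triangles)
        To = fem.at_quad(T_old, self.mesh.triangles)
        dT = Tg - To
        small = np.abs(dT) < 1e-4
        chord = (self._blood_enthalpy(Tg) - self._blood_enthalpy(To)) / np.where(
            small, 1.0, dT
        )
        point = properties.vaporization_rho_c(Tg, "blood", self.vapor_consts)
        return np.where(small, point, chord)

    def _beta_quad(self, beta_node: np.ndarray | float) -> np.ndarray:
        if np.ndim(beta_node) == 0:
            return np.full((len(self.mesh.triangles), 3), float(beta_node))
        return fem.at_quad(np.asarray(beta_node, dtype=float), self.mesh.triangles)

    def _q_elem(self, q_ext) -> np.ndarray:
        q = np.asarray(q_ext, dtype=float)
        if q.ndim == 0:
            return np.full(len(self.mesh.triangles), float(q))
        if len(q) == self.mesh.num_nodes:  # nodal field -> element average
            return q[self.mesh.triangles].mean(axis=1)
        if len(q) == len(self.mesh.triangles):
            return q
        raise ValueError("heat source must be per-node or per-element")

    # -- nodal enthalpy for the Newton transient term --------------------------

    def _enthalpy_node(self, T: np.ndarray) -> np.ndarray:
        """Cumulative volumetric enthalpy of the tissue phase per node."""
        if self.vaporization == "none":
            return self.rhoc_node * T
        if self.vaporization == "effective_heat":
            W = properties.water_content(T, self.water)
            alpha = self.water.latent_heat_alpha
            rho = self.rho_node
            if self.effective_heat_mode == "as_printed":
                alpha = alpha * rho
            return self.rhoc_node * T - rho * alpha * (W - self.water.W0)
        vc = self.vapor_consts
        liq = self.rhoc_node
        spike = vc.h_fg * vc.C_w_tissue / vc.delta_T
        gas = vc.rho_g * vc.c_g
        t0 = 100.0 - vc.delta_T
        return np.select(
            [T <= t0, T <= 100.0],
            [liq * T, liq * t0 + spike * (T - t0)],
            default=liq * t0 + spike * vc.delta_T + gas * (T - 100.0),
        )

    def _enthalpy_deriv_node(self, T: np.ndarray) -> np.ndarray:
        """Pointwise apparent (rho c) per node (dH/dT)."""
        if self.vaporization == "none":
            return self.rhoc_node * np.ones_like(T)
        if self.vaporization == "effective_heat":
            dW = properties.water_content_derivative(T, self.water)
            alpha = self.water.latent_heat_alpha
            rho = self.rho_node
            if self.effective_heat_mode == "as_printed":
                alpha = alpha * rho
            return self.rhoc_node - rho * alpha * dW
        vc = self.vapor_consts
        spike = vc.h_fg * vc.C_w_tissue / vc.delta_T
        return np.select(
            [T <= 100.0 - vc.delta_T, T <= 100.0],
            [self.rhoc_node * np.ones_like(T), np.full_like(T, spike)],
            default=vc.rho_g * vc.c_g,
        )

    def _blood_enthalpy_node(self, T: np.ndarray) -> np.ndarray:
        if self.vaporization != "enthalpy":
            return self.blood.rho_c * T
        vc = self.vapor_consts
        liq = self.blood.rho_c
        spike = vc.h_fg * vc.C_w_blood / vc.delta_T
        gas = vc.rho_g * vc.c_g
        t0 = 100.0 - vc.delta_T
        return np.select(
            [T <= t0, T <= 100.0],
            [liq * T, liq * t0 + spike * (T - t0)],
            default=liq * t0 + spike * vc.delta_T + gas * (T - 100.0),
        )

    def _blood_enthalpy_deriv_node(self, T: np.ndarray) -> np.ndarray:
        if self.vaporization != "enthalpy":
            return np.full_like(T, self.blood.rho_c)
        vc = self.vapor_consts
        spike = vc.h_fg * vc.C_w_blood / vc.delta_T
        return np.select(
            [T <= 100.0 - vc.delta_T, T <= 100.0],
            [np.full_like(T, self.blood.rho_c), np.full_like(T, spike)],
            default=vc.rho_g * vc.c_g,
        )

    # -- implicit stepping helpers --------------------------------------------

    def _newton_step(self, T_old, dt, Kmat, P_diag, rhs, H, Hp):
        """Damped Newton solve of Mg (H(T) - H(T_old))/dt + K T + P T = rhs.

        H is strictly increasing, so the implicit problem has a unique
        solution; the line search makes the iteration robust to nodes
        crossing the vaporization band within one step.
        """
        dn = self.dirichlet_nodes
        H_old = H(T_old)
        T = T_old.copy()
        T[dn] = self.dirichlet_value

        def residual(Tv):
            R = self.Mg * (H(Tv) - H_old) / dt + Kmat @ Tv + P_diag * Tv - rhs
            R[dn] = 0.0
            return R

        R = residual(T)
        for it in range(self.picard_max):
            Jdiag = self.Mg * Hp(T) / dt + P_diag
            J = sp.diags(Jdiag) + Kmat
            J, mrhs = fem.apply_dirichlet(J, -R, dn, 0.0)
            dT = spla.spsolve(J.tocsc(), mrhs)
            r0 = float(np.linalg.norm(R))
            step = 1.0
            for _ in range(25):
                T_try = T + step * dT
                R_try = residual(T_try)
                if float(np.linalg.norm(R_try)) <= (1.0 - 1e-4 * step) * r0:
                    break
                step *= 0.5
            T = T + step * dT
            R = residual(T)
            incr = float(np.max(np.abs(step * dT)))
            if incr < self.picard_tol:
                self.last_picard = (it + 1, incr)
                return T
        self.last_picard = (self.picard_max, incr)
        if incr > 5.0:
            raise PicardNonConvergence(incr, self.picard_tol)
        return T

    # -- backends --------------------------------------------------------------

    def step_pennes(
        self, state: ThermalState, dt: float, q_ext, beta=1.0
    ) -> ThermalState:
        """One implicit Euler step of the Pennes equation."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        mesh, perf = self.mesh, self.perfusion
        q = self._q_elem(q_ext)
        bq = self._beta_quad(beta)
        sink = bq * self.blood.density * perf.omega_b * self.blood.specific_heat
        T_old = state.T
        P = fem.assemble_mass(mesh.nodes, mesh.triangles, sink, lumped=True)
        rhs = P * perf.T_core + fem.assemble_load(
            mesh.nodes, mesh.triangles, q + perf.Q_m
        )
        T_new = self._newton_step(
            T_old, dt, self.K, P, rhs, self._enthalpy_node, self._enthalpy_deriv_node
        )
        out = state.copy()
        out.T = T_new
        out.time = state.time + dt
        return out

    def step_lte(self, state: ThermalState, dt: float, q_ext, beta=1.0) -> ThermalState:
        """One implicit step of the single-temperature porous-media model."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        mesh, perf = self.mesh, self.perfusion
        eps = perf.porosity_eps
        q = self._q_elem(q_ext)
        bq = self._beta_quad(beta)
        k_mix = (1 - eps) * self.k_elem + eps * self.blood.thermal_conductivity
        if self.lte_conductivity == "combined":
            k_mix = k_mix * (1 - eps)
        K = fem.assemble_stiffness(mesh.nodes, mesh.triangles, k_mix)
        u = np.asarray(perf.u, dtype=float)
        T_old = state.T

        adv = None
        if np.any(u != 0.0) and eps > 0.0:
            beta_elem = bq.mean(axis=1)
            coef = eps * self.blood.rho_c * beta_elem
            vel = coef[:, None] * u[None, :]
            adv = fem.assemble_advection(mesh.nodes, mesh.triangles, vel)
            adv = adv + self._supg(u, coef)
            K = K + adv

        def H(T):
            return (1 - eps) * self._enthalpy_node(T) + eps * self._blood_enthalpy_node(T)

        def Hp(T):
            return (1 - eps) * self._enthalpy_deriv_node(T) + eps * (
                self._blood_enthalpy_deriv_node(T)
            )

        rhs = fem.assemble_load(mesh.nodes, mesh.triangles, q + perf.Q_m)
        T_new = self._newton_step(T_old, dt, K, np.zeros(mesh.num_nodes), rhs, H, Hp)
        out = state.copy()
        out.T = T_new
        out.time = state.time + dt
        return out

    def _supg(self, u: np.ndarray, coef_elem: np.ndarray):
        """Streamline-upwind diffusion where the cell Peclet number exceeds 2."""
        mesh = self.mesh
        area, _ = fem.tri_geometry(mesh.nodes, mesh.triangles)
        h = np.sqrt(2.0 * area)
        speed = float(np.hypot(*u))
        k_ref = np.maximum(self.k_elem, 1e-12)
        peclet = coef_elem * speed * h / (2.0 * k_ref)
        tau = np.where(peclet > 2.0, h / (2.0 * max(speed, 1e-30)), 0.0)
        if not np.any(tau > 0):
            return sp.csr_matrix((mesh.num_nodes, mesh.num_nodes))
        vel = coef_elem[:, None] * u[None, :] / np.maximum(coef_elem, 1e-30)[:, None]
        return fem.assemble_streamline_diffusion(
            mesh.nodes, mesh.triangles, vel, tau * coef_elem
        )

    def step_ltne(self, state: ThermalState, dt: float, q_ext, beta=1.0) -> ThermalState:
        """One implicit step of the two-temperature (tissue/blood) model."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        mesh, perf = self.mesh, self.perfusion
        n = mesh.num_nodes
        eps = perf.porosity_eps
        q = self._q_elem(q_ext)
        bq = self._beta_quad(beta)
        T_old = state.T
        Tb_old = state.T_blood if state.T_blood is not None else np.full(n, T_BODY)

        exch = perf.h_c_a + bq * self.blood.density * perf.omega_b * self.blood.specific_heat
        X = fem.assemble_mass(mesh.nodes, mesh.triangles, exch, lumped=True)
        Kt = fem.assemble_stiffness(mesh.nodes, mesh.triangles, (1 - eps) * self.k_elem)
        Kb = fem.assemble_stiffness(
            mesh.nodes,
            mesh.triangles,
            np.full(len(mesh.triangles), eps * self.blood.thermal_conductivity),
        )
        F = fem.assemble_load(mesh.nodes, mesh.triangles, q)

        u = np.asarray(perf.u, dtype=float)
        adv = None
        if np.any(u != 0.0) and eps > 0.0:
            beta_elem = bq.mean(axis=1)
            coef = eps * self.blood.rho_c * beta_elem
            vel = coef[:, None] * u[None, :]
            adv = fem.assemble_advection(mesh.nodes, mesh.triangles, vel)
            adv = adv + self._supg(u, coef)

        blood_inert = eps == 0.0

        def build(guess):
            Tt_g, Tb_g = guess[:n], guess[n:]
            rc_t = self._tissue_rho_c_quad(Tt_g, T_old)
            Mt = fem.assemble_mass(
                mesh.nodes, mesh.triangles, (1 - eps) * rc_t / dt, lumped=True
            )
            A_tt = sp.diags(Mt + X) + Kt
            b_t = Mt * T_old + X * 0.0 + (1 - eps) * F + 0.0
            A_tb = -sp.diags(X)
            if blood_inert:
                A_bb = sp.identity(n, format="csr")
                A_bt = sp.csr_matrix((n, n))
                b_b = Tb_old.astype(float)
            else:
                rc_b = self._blood_rho_c_quad(Tb_g, Tb_old)
                Mb = fem.assemble_mass(
                    mesh.nodes, mesh.triangles, eps * rc_b / dt, lumped=True
                )
                A_bb = sp.diags(Mb + X) + Kb
                if adv is not None:
                    A_bb = A_bb + adv
                A_bt = -sp.diags(X)
                b_b = Mb * Tb_old + eps * F
            A = sp.bmat([[A_tt, A_tb], [A_bt, A_bb]], format="csr")
            return A, np.concatenate([b_t, b_b])

        def solve(guess):
            A, b = build(guess)
            dn = self.dirichlet_nodes
            dn2 = np.concatenate([dn, dn + n]) if len(dn) else dn
            A, b = fem.apply_dirichlet(A, b, dn2, self.dirichlet_value)
            return spla.spsolve(A.tocsc(), b)

        guess = np.concatenate([T_old, Tb_old])
        residual = np.inf
        for it in range(self.picard_max):
            new = solve(guess)
            residual = float(np.max(np.abs(new - guess)))
            if residual < self.picard_tol:
                self.last_picard = (it + 1, residual)
                guess = new
                break
            guess = new if it < 3 else 0.5 * (new + guess)
        else:
            self.last_picard = (self.picard_max, residual)
            if residual > 5.0:
                raise PicardNonConvergence(residual, self.picard_tol)

        out = state.copy()
        out.T = guess[:n]
        out.T_blood = guess[n:]
        out.time = state.time + dt
        return out

    def step(self, backend: str, state: ThermalState, dt: float, q_ext, beta=1.0):
        fn = {
            "pennes": self.step_pennes,
            "lte": self.step_lte,
            "ltne": self.step_ltne,
        }.get(backend)
        if fn is None:
            raise ValueError(f"unknown bioheat backend {backend!r}")
        return fn(state, dt, q_ext, beta)


def initial_state(mesh: Mesh, backend: str = "pennes", T0: float = T_BODY) -> ThermalState:
    """Uniform body-temperature state on the tissue submesh of ``mesh``."""
    if any(r not in THERMAL_REGIONS for r in np.unique(mesh.region)):
        mesh = mesh.submesh([r for r in THERMAL_REGIONS if r in mesh.region])
    n = mesh.num_nodes
    Tb = np.full(n, T0) if backend == "ltne" else None
    return ThermalState(np.full(n, T0), 0.0, Tb, np.zeros(n))
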