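"""Frequency-domain electromagnetic solve and SAR evaluation.

The coaxial applicator and tissue are axisymmetric, so the vector Helmholtz
problem reduces to a scalar equation for the azimuthal magnetic field
H_phi(r, z) (TM formulation). The discrete unknown is u = r * H_phi, which
represents the coaxial TEM mode (H_phi ~ 1/r) exactly on P1 elements. The
feed is a TEM coaxial port whose incident wave is normalized to the requested
time-averaged input power; the outer tissue boundary carries a first-order
absorbing condition and metal surfaces are perfect conductors (the natural
boundary condition of this formulation).

Phasor convention: peak amplitudes with exp(+j omega t), so the dissipated
power density is sigma |E|^2 / 2 and the complex permittivity is
eps0 (eps_r - j sigma / (omega eps0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import fem, properties
from .geometry import Mesh

EPS0 = 8.8541878128e-12
MU0 = 4.0e-7 * math.pi

#: regions that belong to the electromagnetic domain (metal is excluded)
EM_REGIONS = ("healthy_liver", "tumor", "antenna_dielectric", "slot", "catheter")


@dataclass
class EMField:
    """Complex TM field solution on the electromagnetic submesh.

    ``u`` is r * H_phi; use :attr:`H` for the physical azimuthal magnetic
    field (A/m). The solution scales with sqrt(input_power).
    """

    mesh: Mesh  # EM submesh (node_map points into the parent mesh, if any)
    u: np.ndarray  # (N,) complex, A
    frequency: float
    input_power: float
    port_reflection: complex
    eps_elem: np.ndarray  # (M,) complex permittivity used in the solve
    sigma_elem: np.ndarray
    rho_elem: np.ndarray

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    @property
    def H(self) -> np.ndarray:
        """Azimuthal magnetic field H_phi at the nodes (0 on the axis)."""
        r = self.mesh.nodes[:, 0]
        out = np.zeros_like(self.u)
        np.divide(self.u, r, out=out, where=r > 1e-12)
        return out


@dataclass
class SARField:
    """Absorbed-power fields derived from an EM solution."""

    mesh: Mesh
    q_elem: np.ndarray  # volumetric heat source W/m^3, per element
    sar_node: np.ndarray  # W/kg, projected to nodes
    q_node: np.ndarray  # W/m^3, projected to nodes


def _element_dielectric(mesh: Mesh, T_node: np.ndarray, omega: float):
    """Per-element (sigma, rho, eps_complex) from region + temperature."""
    T_elem = T_node[mesh.triangles].mean(axis=1)
    eps_r = np.empty(len(mesh.triangles))
    sigma = np.empty(len(mesh.triangles))
    rho = np.empty(len(mesh.triangles))
    for reg in np.unique(mesh.region):
        sel = mesh.region == reg
        e, s = properties.tissue_dielectric(reg, T_elem[sel])
        eps_r[sel] = e
        sigma[sel] = s
        mat = "antenna_dielectric" if reg == "slot" else reg
        rho[sel] = properties.material_lookup(mat).density
    eps_c = EPS0 * (eps_r - 1j * sigma / (omega * EPS0))
    return sigma, rho, eps_c


def solve_em(
    mesh: Mesh,
    T: np.ndarray | float = 37.0,
    frequency: float = 2.45e9,
    input_power: float = 13.0,
) -> EMField:
    """Solve the axisymmetric TM field problem at the given temperature state.

    ``mesh`` may be the full simulation mesh (the metal-free EM submesh is
    extracted automatically) or an already-extracted submesh with tagged
    ``port``/``outer`` boundaries. ``T`` is the nodal temperature (degC) on
    ``mesh``; dielectric coefficients are evaluated per element. The incident
    TEM-mode power at the port equals ``input_power`` (W).
    """
    if "antenna_metal" in mesh.region:
        sub = mesh.submesh([r for r in EM_REGIONS if r in mesh.region])
        if np.ndim(T) > 0:
            T = np.asarray(T)[sub.node_map]
    else:
        sub = mesh
    n = sub.num_nodes
    T_node = np.full(n, float(T)) if np.ndim(T) == 0 else np.asarray(T, dtype=float)
    if len(T_node) != n:
        raise ValueError("temperature field does not match the EM mesh")

    omega = 2.0 * math.pi * frequency
    sigma, rho, eps_c = _element_dielectric(sub, T_node, omega)

    A = fem.assemble_axisym_tm(sub.nodes, sub.triangles, 1.0 / eps_c, omega**2 * MU0)

    if "port" not in sub.boundary or len(sub.boundary["port"]) == 0:
        raise ValueError("mesh has no port boundary to excite")
    port = sub.boundary["port"]
    port_edges = port[:, :2]
    eps_d = eps_c[port[:, 2]].mean().real  # lossless coax filling
    k_d = omega * math.sqrt(MU0 * eps_d)
    z_d = math.sqrt(MU0 / eps_d)
    r_port = sub.nodes[np.unique(port_edges), 0]
    r_in, r_out = float(r_port.min()), float(r_port.max())
    ln_ba = math.log(r_out / r_in)
    amp = math.sqrt(input_power / (math.pi * z_d * ln_ba))  # u_inc = amp

    ne = len(port_edges)
    A = A + fem.edge_mass_invr(sub.nodes, port_edges, np.full(ne, 1j * k_d / eps_d), n)
    b = fem.edge_load_invr(
        sub.nodes, port_edges, np.full(ne, 2j * k_d * amp / eps_d), n
    )

    if "outer" in sub.boundary and len(sub.boundary["outer"]):
        outer = sub.boundary["outer"]
        eps_e = eps_c[outer[:, 2]]
        k_e = omega * np.sqrt(MU0 * eps_e)  # principal root: Im(k) < 0 in loss
        A = A + fem.edge_mass_invr(sub.nodes, outer[:, :2], 1j * k_e / eps_e, n)

    # symmetry axis: u = r H_phi vanishes at r = 0
    axis_nodes = np.flatnonzero(sub.nodes[:, 0] < 1e-12)
    A, b = fem.apply_dirichlet(A, b, axis_nodes, 0.0)

    u = spla.spsolve(A.tocsc(), b)
    if not np.all(np.isfinite(u.real) & np.isfinite(u.imag)):
        raise RuntimeError("electromagnetic solve produced non-finite field")

    s11 = _project_reflection(sub, u, amp, r_in, r_out)
    return EMField(sub, u, frequency, input_power, s11, eps_c, sigma, rho)


def _project_reflection(sub: Mesh, u: np.ndarray, amp: float, r_in, r_out) -> complex:
    """Project the scattered port field onto the TEM mode (u_mode = const)."""
    port = sub.boundary["port"]
    num = 0.0 + 0.0j
    for n1, n2, _ in port:
        r1, r2 = sub.nodes[n1, 0], sub.nodes[n2, 0]
        u1, u2 = u[n1], u[n2]
        if r2 < r1:
            r1, r2, u1, u2 = r2, r1, u2, u1
        for t in fem._EDGE_T:
            rt = r1 * (1 - t) + r2 * t
            ut = u1 * (1 - t) + u2 * t
            num += 0.5 * (r2 - r1) * (ut - amp) / rt
    return complex(num / (amp * math.log(r_out / r_in)))


def port_reflection(field: EMField) -> complex:
    """TEM reflection coefficient S11 at the coaxial feed (diagnostic)."""
    return field.port_reflection


def _gradients(field: EMField):
    sub = field.mesh
    _, grads = fem.tri_geometry(sub.nodes, sub.triangles)
    ue = field.u[sub.triangles]
    dudr = np.einsum("mi,mi->m", ue, grads[:, :, 0])
    dudz = np.einsum("mi,mi->m", ue, grads[:, :, 1])
    return dudr, dudz


def compute_sar(field: EMField) -> SARField:
    """SAR = sigma |E|^2 / (2 rho) and Q_ext = sigma |E|^2 / 2 from the field.

    E is evaluated at the interior quadrature points, where
    E_r = -u_z / (j omega eps r) and E_z = u_r / (j omega eps r); the element
    heat source is the quadrature average.
    """
    sub = field.mesh
    dudr, dudz = _gradients(field)
    rq = fem.quad_points(sub.nodes, sub.triangles)[:, :, 0]
    g2 = (np.abs(dudr) ** 2 + np.abs(dudz) ** 2)[:, None]
    inv = 1.0 / (field.omega * np.abs(field.eps_elem))[:, None] ** 2
    e2 = (g2 * inv / rq**2) @ fem.QW
    q_elem = 0.5 * field.sigma_elem * e2
    area, _ = fem.tri_geometry(sub.nodes, sub.triangles)
    w = area * sub.nodes[sub.triangles, 0].mean(axis=1)  # revolved element weight
    q_node = np.zeros(sub.num_nodes)
    sar_node = np.zeros(sub.num_nodes)
    wt = np.zeros(sub.num_nodes)
    for k in range(3):
        idx = sub.triangles[:, k]
        np.add.at(q_node, idx, w * q_elem)
        np.add.at(sar_node, idx, w * q_elem / field.rho_elem)
        np.add.at(wt, idx, w)
    q_node /= np.maximum(wt, 1e-300)
    sar_node /= np.maximum(wt, 1e-300)
    return SARField(sub, q_elem, sar_node, q_node)


def absorbed_power(field: EMField) -> float:
    """Total dissipated power int Q_ext dV (W), revolved."""
    sub = field.mesh
    sar = compute_sar(field)
    area, _ = fem.tri_geometry(sub.nodes, sub.triangles)
    r_cent = sub.nodes[sub.triangles, 0].mean(axis=1)
    return float(np.sum(sar.q_elem * 2.0 * math.pi * r_cent * area))


def boundary_flux(field: EMField, tag: str = "outer") -> float:
    """Time-averaged Poynting flux (W) leaving through the tagged boundary."""
    sub = field.mesh
    if tag not in sub.boundary:
        return 0.0
    edges = sub.boundary[tag]
    dudr, dudz = _gradients(field)
    total = 0.0
    for n1, n2, own in edges:
        p1, p2 = sub.nodes[n1], sub.nodes[n2]
        t = p2 - p1
        L = math.hypot(t[0], t[1])
        rm = 0.5 * (p1[0] + p2[0])
        if L == 0 or rm < 1e-12:
            continue
        nrm = np.array([t[1], -t[0]]) / L  # outward for CCW orientation
        Hm = 0.5 * (field.u[n1] + field.u[n2]) / rm
        jwer = 1j * field.omega * field.eps_elem[own] * rm
        Er = -dudz[own] / jwer
        Ez = dudr[own] / jwer
        s_n = 0.5 * np.real(Er * np.conj(Hm) * nrm[1] - Ez * np.conj(Hm) * nrm[0])
        total += s_n * 2.0 * math.pi * rm * L
    return float(total)


def power_balance(field: EMField) -> dict[str, float]:
    """Energy bookkeeping of one EM solve.

    Returns input, reflected, absorbed and radiated power (W) plus the
    relative closure error (absorbed + radiated vs net input).
    """
    p_in = field.input_power
    p_refl = float(abs(field.port_reflection) ** 2) * p_in
    p_abs = absorbed_power(field)
    p_rad = boundary_flux(field, "outer")
    err = abs(p_abs + p_rad - (p_in - p_refl)) / p_in
    return {
        "input": p_in,
        "reflected": p_refl,
        "absorbed": p_abs,
        "radiated": p_rad,
        "relative_error": err,
    }
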