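"""Axisymmetric P1 finite-element assembly on triangle meshes.

All bilinear forms carry the cylindrical weight r (volumes are understood per
radian x 2*pi). Element quadrature is the interior three-point rule, exact for
quadratics, whose points stay strictly off the symmetry axis so that 1/r
factors in the TM electromagnetic form remain finite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

# interior 3-point rule: barycentric points, weights sum to 1
QP = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3]])
QW = np.array([1 / 3, 1 / 3, 1 / 3])


def tri_geometry(nodes: np.ndarray, tris: np.ndarray):
    """Areas (M,) and constant P1 shape gradients (M, 3, 2) of each triangle."""
    p = nodes[tris]  # (M, 3, 2)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    area = 0.5 * det
    if np.any(area <= 0):
        raise ValueError("mesh contains inverted or degenerate triangles")
    grads = np.empty((len(tris), 3, 2))
    # grad lambda_i = rot of opposite edge / (2A)
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    for i, e in enumerate((e0, e1, e2)):
        grads[:, i, 0] = -e[:, 1]
        grads[:, i, 1] = e[:, 0]
    grads /= det[:, None, None]
    return area, grads


def quad_points(nodes: np.ndarray, tris: np.ndarray):
    """Physical coordinates of the quadrature points, (M, 3, 2)."""
    return np.einsum("qi,mid->mqd", QP, nodes[tris])


def at_quad(values_node: np.ndarray, tris: np.ndarray):
    """Interpolate a nodal field to the quadrature points, (M, 3)."""
    return np.einsum("qi,mi->mq", QP, values_node[tris])


def _scatter(ke: np.ndarray, tris: np.ndarray, n: int, dtype=None):
    m = len(tris)
    rows = np.repeat(tris, 3, axis=1).reshape(m, 9)
    cols = np.tile(tris, (1, 3)).reshape(m, 9)
    a = sp.coo_matrix(
        (ke.reshape(m, 9).ravel(), (rows.ravel(), cols.ravel())),
        shape=(n, n),
        dtype=dtype or ke.dtype,
    )
    return a.tocsr()


def assemble_stiffness(nodes, tris, coef_elem) -> sp.csr_matrix:
    """int coef * grad(u).grad(v) * r dr dz with piecewise-constant coef."""
    area, grads = tri_geometry(nodes, tris)
    r_cent = nodes[tris, 0].mean(axis=1)
    gg = np.einsum("mid,mjd->mij", grads, grads)
    ke = gg * (np.asarray(coef_elem) * area * r_cent)[:, None, None]
    return _scatter(ke, tris, len(nodes))


def assemble_mass(nodes, tris, coef_quad, lumped: bool = False):
    """int coef * u * v * r dr dz.

    ``coef_quad`` is either per-element (M,) or per-quadrature-point (M, 3).
    With ``lumped=True`` returns the row-sum diagonal as a 1-D array.
    """
    area, _ = tri_geometry(nodes, tris)
    rq = quad_points(nodes, tris)[:, :, 0]  # (M, 3)
    coef = np.asarray(coef_quad)
    if coef.ndim == 1:
        coef = coef[:, None] * np.ones((1, 3))
    w = area[:, None] * QW[None, :] * coef * rq  # (M, 3)
    ke = np.einsum("mq,qi,qj->mij", w, QP, QP)
    if lumped:
        diag = np.zeros(len(nodes))
        np.add.at(diag, tris.ravel(), ke.sum(axis=2).ravel())
        return diag
    return _scatter(ke, tris, len(nodes))


def assemble_load(nodes, tris, f_quad) -> np.ndarray:
    """int f * v * r dr dz; ``f_quad`` per-element (M,) or per-point (M, 3)."""
    area, _ = tri_geometry(nodes, tris)
    rq = quad_points(nodes, tris)[:, :, 0]
    f = np.asarray(f_quad)
    if f.ndim == 1:
        f = f[:, None] * np.ones((1, 3))
    w = area[:, None] * QW[None, :] * f * rq
    fe = np.einsum("mq,qi->mi", w, QP)
    out = np.zeros(len(nodes), dtype=fe.dtype)
    np.add.at(out, tris.ravel(), fe.ravel())
    return out


def assemble_advection(nodes, tris, vel_coef_elem) -> sp.csr_matrix:
    """int coef * (u . grad(w)) * v * r dr dz.

    ``vel_coef_elem`` is (M, 2): velocity already multiplied by its scalar
    coefficient, per element.
    """
    area, grads = tri_geometry(nodes, tris)
    rq = quad_points(nodes, tris)[:, :, 0]
    ug = np.einsum("md,mjd->mj", np.asarray(vel_coef_elem), grads)  # (M, 3)
    w = area[:, None] * QW[None, :] * rq  # (M, 3) quad weights
    ke = np.einsum("mq,qi,mj->mij", w, QP, ug)
    return _scatter(ke, tris, len(nodes))


def assemble_streamline_diffusion(nodes, tris, vel_elem, tau_elem) -> sp.csr_matrix:
    """Streamline-upwind stabilization tau * (u.grad u)(u.grad v), r-weighted."""
    area, grads = tri_geometry(nodes, tris)
    r_cent = nodes[tris, 0].mean(axis=1)
    ug = np.einsum("md,mjd->mj", np.asarray(vel_elem), grads)
    ke = np.einsum("m,mi,mj->mij", np.asarray(tau_elem) * area * r_cent, ug, ug)
    return _scatter(ke, tris, len(nodes))


def assemble_axisym_tm(nodes, tris, inv_eps_elem, om2mu0) -> sp.csr_matrix:
    """Interior bilinear form of the axisymmetric TM Helmholtz problem.

    The unknown is u = r * H_phi, which makes the coaxial TEM mode (H ~ 1/r)
    exactly representable by P1 elements:

    a(u, w) = int (1/(eps~ r)) grad(u).grad(w) dr dz
              - omega^2 mu0 int u w / r dr dz

    with eps~ the complex permittivity, constant per element. u = 0 on the
    symmetry axis; the interior quadrature keeps 1/r finite there.
    """
    area, grads = tri_geometry(nodes, tris)
    rq = quad_points(nodes, tris)[:, :, 0]  # (M, 3)
    inv_eps = np.asarray(inv_eps_elem)
    wq = area[:, None] * QW[None, :] / rq  # (M, 3): quadrature weight / r
    gg = np.einsum("mid,mjd->mij", grads, grads)
    ke = gg * (inv_eps * wq.sum(axis=1))[:, None, None]
    km = np.einsum("mq,qi,qj->mij", wq, QP, QP)
    return _scatter(ke.astype(complex) - om2mu0 * km, tris, len(nodes), dtype=complex)


# 2-point Gauss positions on [0, 1]; strictly interior, so 1/r stays finite
_EDGE_T = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])


def edge_mass_invr(nodes, edges, coef_edge, n: int) -> sp.csr_matrix:
    """Boundary form int coef * u * w * (1/r) ds over the given edges."""
    L = edge_lengths(nodes, edges)
    r1 = nodes[edges[:, 0], 0]
    r2 = nodes[edges[:, 1], 0]
    coef = np.asarray(coef_edge)
    ke = np.zeros((len(edges), 2, 2), dtype=complex)
    for t in _EDGE_T:
        lam = np.array([1.0 - t, t])
        rt = r1 * (1 - t) + r2 * t
        w = 0.5 * L / rt
        ke += np.einsum("e,i,j->eij", coef * w, lam, lam)
    rows = np.stack([edges[:, 0], edges[:, 0], edges[:, 1], edges[:, 1]], axis=1)
    cols = np.stack([edges[:, 0], edges[:, 1], edges[:, 0], edges[:, 1]], axis=1)
    vals = np.stack([ke[:, 0, 0], ke[:, 0, 1], ke[:, 1, 0], ke[:, 1, 1]], axis=1)
    return sp.coo_matrix(
        (vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
    ).tocsr()


def edge_load_invr(nodes, edges, g_edge, n: int) -> np.ndarray:
    """Boundary load int g * w * (1/r) ds, g constant per edge."""
    L = edge_lengths(nodes, edges)
    r1 = nodes[edges[:, 0], 0]
    r2 = nodes[edges[:, 1], 0]
    g = np.asarray(g_edge)
    out = np.zeros(n, dtype=complex)
    for t in _EDGE_T:
        rt = r1 * (1 - t) + r2 * t
        w = 0.5 * g * L / rt
        np.add.at(out, edges[:, 0], w * (1.0 - t))
        np.add.at(out, edges[:, 1], w * t)
    return out


def edge_lengths(nodes, edges):
    d = nodes[edges[:, 1]] - nodes[edges[:, 0]]
    return np.hypot(d[:, 0], d[:, 1])


def edge_mass_r(nodes, edges, coef_edge, n: int) -> sp.csr_matrix:
    """Boundary form int coef * u * v * r ds over the given edges."""
    L = edge_lengths(nodes, edges)
    r1 = nodes[edges[:, 0], 0]
    r2 = nodes[edges[:, 1], 0]
    c = np.asarray(coef_edge) * L / 12.0
    k11 = c * (3 * r1 + r2)
    k12 = c * (r1 + r2)
    k22 = c * (r1 + 3 * r2)
    rows = np.concatenate([edges[:, 0], edges[:, 0], edges[:, 1], edges[:, 1]])
    cols = np.concatenate([edges[:, 0], edges[:, 1], edges[:, 0], edges[:, 1]])
    vals = np.concatenate([k11, k12, k12, k22])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def edge_load(nodes, edges, g_edge, n: int, r_weight: bool = False) -> np.ndarray:
    """Boundary load int g * v ds (optionally r-weighted), g constant per edge."""
    L = edge_lengths(nodes, edges)
    g = np.asarray(g_edge)
    out = np.zeros(n, dtype=g.dtype if g.dtype.kind == "c" else float)
    if r_weight:
        r1 = nodes[edges[:, 0], 0]
        r2 = nodes[edges[:, 1], 0]
        f1 = g * L * (2 * r1 + r2) / 6.0
        f2 = g * L * (r1 + 2 * r2) / 6.0
    else:
        f1 = f2 = g * L / 2.0
    np.add.at(out, edges[:, 0], f1)
    if f1 is f2:
        np.add.at(out, edges[:, 1], f2)
    else:
        np.add.at(out, edges[:, 1], f2)
    return out


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, idx: np.ndarray, values):
    """Eliminate Dirichlet dofs in place-ish; returns modified (A, b)."""
    if len(idx) == 0:
        return A.tocsc().tocsr(), b
    n = A.shape[0]
    vals = np.broadcast_to(np.asarray(values, dtype=b.dtype), idx.shape)
    x = np.zeros(n, dtype=b.dtype)
    x[idx] = vals
    b = b - A @ x
    keep = np.ones(n, dtype=bool)
    keep[idx] = False
    D = sp.diags(keep.astype(float))
    A = D @ A @ D + sp.diags((~keep).astype(float))
    b[idx] = vals
    return A.tocsr(), b
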