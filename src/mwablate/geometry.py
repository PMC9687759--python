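"""Antenna/domain geometry, synthetic tumors, and axisymmetric meshing.

The computational domain is the (r, z) half-plane of a cylindrical domain:
z runs along the antenna axis with the tip at z = 0, the coaxial feed below
(z < 0, port at z = -insertion_depth), and tissue fills z > 0 together with
everything outside the catheter radius. Meshes are graded structured
triangulations whose grid lines are snapped to every material interface
(conductor radii, slot edges, tip), so each cell carries exactly one region.
All lengths are SI meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "AntennaGeometry",
    "TumorShape",
    "Mesh",
    "build_antenna",
    "make_ellipsoid_tumor",
    "load_tumor_surface",
    "generate_mesh",
    "rectangle_mesh",
]


@dataclass(frozen=True)
class AntennaGeometry:
    """Parametric multi-slot coaxial applicator.

    Slots of width ``slot_width`` at pitch ``slot_width + slot_spacing`` are
    cut in the outer conductor starting ``tip_offset`` behind the shorted
    metal tip. Radii: inner conductor a, dielectric outer b, thin outer
    conductor of thickness ``outer_conductor_thickness``, catheter jacket out
    to ``catheter_outer_radius``. The default radii give ~50 ohm with PTFE.
    """

    slot_count: int = 10
    slot_width: float = 0.6e-3
    slot_spacing: float = 0.8e-3
    inner_conductor_radius: float = 0.14e-3
    dielectric_outer_radius: float = 0.47e-3
    outer_conductor_thickness: float = 0.10e-3
    catheter_outer_radius: float = 0.895e-3
    tip_offset: float = 1.0e-3
    insertion_depth: float = 40.0e-3

    def __post_init__(self) -> None:
        if self.slot_count < 1:
            raise ValueError("slot_count must be >= 1")
        a, b = self.inner_conductor_radius, self.dielectric_outer_radius
        b2 = b + self.outer_conductor_thickness
        rc = self.catheter_outer_radius
        if not (0 < a < b < b2 < rc):
            raise ValueError("antenna radii must be strictly increasing")
        if min(self.slot_width, self.slot_spacing, self.tip_offset) <= 0:
            raise ValueError("slot dimensions and tip offset must be positive")
        if self.tip_offset + self.slotted_span > self.insertion_depth:
            raise ValueError(
                f"slotted span {self.slotted_span * 1e3:.1f} mm + tip offset does "
                f"not fit within insertion depth {self.insertion_depth * 1e3:.1f} mm"
            )

    @property
    def slotted_span(self) -> float:
        """Axial extent n*w + (n-1)*s covered by the slots."""
        n = self.slot_count
        return n * self.slot_width + (n - 1) * self.slot_spacing

    @property
    def outer_conductor_radius(self) -> float:
        return self.dielectric_outer_radius + self.outer_conductor_thickness

    @property
    def slot_intervals(self) -> list[tuple[float, float]]:
        """(z_lo, z_hi) of each slot aperture, nearest the tip first."""
        out = []
        pitch = self.slot_width + self.slot_spacing
        for k in range(self.slot_count):
            hi = -(self.tip_offset + k * pitch)
            out.append((hi - self.slot_width, hi))
        return out

    @property
    def slot_region(self) -> tuple[float, float]:
        """(z_lo, z_hi) spanned by all slots."""
        iv = self.slot_intervals
        return iv[-1][0], iv[0][1]


def build_antenna(
    slot_count: int = 10,
    slot_width: float = 0.6e-3,
    slot_spacing: float = 0.8e-3,
    **radii,
) -> AntennaGeometry:
    """Construct a validated multi-slot antenna geometry."""
    return AntennaGeometry(
        slot_count=slot_count,
        slot_width=slot_width,
        slot_spacing=slot_spacing,
        **radii,
    )


# ---------------------------------------------------------------------------
# Tumors
# ---------------------------------------------------------------------------


@dataclass
class TumorShape:
    """Tumor geometry: analytic ellipsoid or an imported closed surface.

    ``semi_axes`` are the (x, y, z) half-extents; ``center`` is in 3-D with z
    along the antenna axis. For axisymmetric runs the triaxial shape is
    reduced to its volume-preserving ellipsoid of revolution: semi-axes
    (sqrt(ax*ay), az) about the z axis.
    """

    kind: str
    semi_axes: np.ndarray
    center: np.ndarray
    surface: trimesh.Trimesh | None = None

    @property
    def volume(self) -> float:
        if self.kind == "surface_mesh":
            return float(abs(self.surface.volume))
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def revolved_semi_axes(self) -> tuple[float, float]:
        """(radial, axial) semi-axes of the equivalent ellipsoid of revolution."""
        a, b, c = self.semi_axes
        return math.sqrt(a * b), float(c)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside-test for (P, 3) points (used by 3-D coverage)."""
        points = np.atleast_2d(points)
        if self.kind == "ellipsoid":
            q = (points - self.center) / self.semi_axes
            return (q**2).sum(axis=1) <= 1.0
        return _ray_contains(self.surface, points)


def make_ellipsoid_tumor(semi_axes, center=(0.0, 0.0, 0.0)) -> TumorShape:
    """Analytic ellipsoidal tumor with the given semi-axes (m)."""
    semi_axes = np.asarray(semi_axes, dtype=float)
    if semi_axes.shape != (3,) or np.any(semi_axes <= 0):
        raise ValueError("semi_axes must be three strictly positive lengths")
    return TumorShape("ellipsoid", semi_axes, np.asarray(center, dtype=float))


def ellipsoid_surface(
    semi_axes, center=(0.0, 0.0, 0.0), subdivisions: int = 3
) -> trimesh.Trimesh:
    """Triangulated ellipsoid surface (icosphere scaled along its axes)."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    m.apply_scale(np.asarray(semi_axes, dtype=float))
    m.apply_translation(np.asarray(center, dtype=float))
    return m


def load_tumor_surface(path) -> TumorShape:
    """Load a closed triangulated tumor surface (STL/OFF/PLY).

    Validates that the surface is a closed manifold with positive volume and
    records the volume and bounding box.
    """
    try:
        m = trimesh.load(path, force="mesh")
    except Exception as exc:  # unreadable / unknown format
        raise ValueError(f"could not read surface mesh {path!r}: {exc}") from exc
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise ValueError(f"{path!r} contains no triangulated surface")
    if not m.is_watertight:
        raise ValueError(f"{path!r} is not a closed (watertight) surface")
    if m.volume < 0:
        m.invert()
    if m.volume <= 0:
        raise ValueError(f"{path!r} encloses no volume")
    lo, hi = m.bounds
    semi = (hi - lo) / 2.0
    center = (hi + lo) / 2.0
    return TumorShape("surface_mesh", semi, center, surface=m)


def _ray_contains(surface: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Point-in-mesh by +z ray-crossing parity (no spatial index needed)."""
    tri = surface.triangles  # (F, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    out = np.zeros(len(points), dtype=bool)
    # deterministic sub-micron ray offset avoids vertex/edge parity errors
    scale = float(np.max(surface.extents))
    jitter = np.array([0.7390851, 0.3678794]) * 1e-7 * scale
    for i, p in enumerate(points):
        p = p + np.array([jitter[0], jitter[1], 0.0])
        # 2-D (x, y) barycentric test, then z-crossing above the point
        v0 = (b - a)[:, :2]
        v1 = (c - a)[:, :2]
        v2 = p[:2] - a[:, :2]
        den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
        ok = np.abs(den) > 1e-30
        safe = np.where(ok, den, 1.0)
        u = np.where(ok, (v2[:, 0] * v1[:, 1] - v2[:, 1] * v1[:, 0]) / safe, -1)
        v = np.where(ok, (v0[:, 0] * v2[:, 1] - v0[:, 1] * v2[:, 0]) / safe, -1)
        hit = (u >= 0) & (v >= 0) & (u + v <= 1) & ok
        if not hit.any():
            continue
        zhit = a[hit, 2] + u[hit] * (b - a)[hit, 2] + v[hit] * (c - a)[hit, 2]
        out[i] = (zhit > p[2]).sum() % 2 == 1
    return out


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


class Mesh:
    """Axisymmetric triangle mesh with per-cell region and tagged boundaries.

    Attributes:
        nodes: (N, 2) float array of (r, z) coordinates, r >= 0.
        triangles: (M, 3) int connectivity, counter-clockwise.
        region: (M,) array of region labels (numpy string array).
        boundary: dict tag -> (E, 3) int array of (node1, node2, owner_tri).
    """

    def __init__(self, nodes, triangles, region, tagger=None):
        self.nodes = np.asarray(nodes, dtype=float)
        self.triangles = np.asarray(triangles, dtype=np.int64)
        self.region = np.asarray(region)
        if np.any(self.nodes[:, 0] < -1e-12):
            raise ValueError("mesh nodes must have r >= 0")
        if len(self.region) != len(self.triangles):
            raise ValueError("every triangle needs a region tag")
        self.tagger = tagger if tagger is not None else (lambda r, z: "outer")
        self.boundary = self._tag_boundary()
        self.node_map = None  # set on submeshes: local -> parent node index

    def _tag_boundary(self) -> dict[str, np.ndarray]:
        edges, owner = boundary_edge_list(self.triangles)
        mids = 0.5 * (self.nodes[edges[:, 0]] + self.nodes[edges[:, 1]])
        out: dict[str, list] = {}
        for (n1, n2), o, (rm, zm) in zip(edges, owner, mids):
            tag = self.tagger(rm, zm)
            out.setdefault(tag, []).append((n1, n2, o))
        return {k: np.array(v, dtype=np.int64) for k, v in out.items()}

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    def cell_mask(self, regions) -> np.ndarray:
        regions = {regions} if isinstance(regions, str) else set(regions)
        return np.isin(self.region, sorted(regions))

    def submesh(self, regions) -> "Mesh":
        """Extract the cells of the given regions with compacted node numbering."""
        mask = self.cell_mask(regions)
        tris = self.triangles[mask]
        used = np.unique(tris)
        remap = -np.ones(self.num_nodes, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = Mesh(self.nodes[used], remap[tris], self.region[mask], self.tagger)
        sub.node_map = used
        return sub

    def region_volume(self, regions) -> float:
        """Revolved volume (m^3) of the cells in the given regions."""
        mask = self.cell_mask(regions)
        return float(np.sum(2.0 * math.pi * _tri_r_moment(self.nodes, self.triangles[mask])))

    def total_volume(self) -> float:
        return float(np.sum(2.0 * math.pi * _tri_r_moment(self.nodes, self.triangles)))


def _tri_r_moment(nodes, tris):
    """int r dA per triangle (= area * centroid radius, exact for P1)."""
    p = nodes[tris]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    return area * p[:, :, 0].mean(axis=1)


def boundary_edge_list(tris: np.ndarray):
    """Edges on the boundary of a triangulation, with their owning triangle."""
    m = len(tris)
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    owner = np.tile(np.arange(m), 3)
    key = np.sort(e, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key_sorted = key[order]
    new = np.ones(len(key_sorted), dtype=bool)
    new[1:] = np.any(key_sorted[1:] != key_sorted[:-1], axis=1)
    grp = np.cumsum(new) - 1
    counts = np.bincount(grp)
    single = counts[grp] == 1
    sel = order[single]
    return e[sel], owner[sel]


# ---------------------------------------------------------------------------
# Structured graded meshing
# ---------------------------------------------------------------------------


def _fill(points: np.ndarray, size_fn) -> np.ndarray:
    """Subdivide each interval between mandatory points per a local size target."""
    out = [points[0]]
    for x0, x1 in zip(points[:-1], points[1:]):
        gap = x1 - x0
        if gap <= 1e-12:
            continue
        h = min(size_fn(x0), size_fn(x1), size_fn(0.5 * (x0 + x1)))
        n = max(1, int(math.ceil(gap / h - 1e-9)))
        out.extend(x0 + gap * (np.arange(1, n + 1) / n))
    return np.array(out)


def _tensor_triangulation(rl: np.ndarray, zl: np.ndarray):
    nr, nz = len(rl), len(zl)
    rr, zz = np.meshgrid(rl, zl, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])
    idx = np.arange(nr * nz).reshape(nr, nz)
    i, j = np.meshgrid(np.arange(nr - 1), np.arange(nz - 1), indexing="ij")
    n00 = idx[i, j].ravel()
    n10 = idx[i + 1, j].ravel()
    n11 = idx[i + 1, j + 1].ravel()
    n01 = idx[i, j + 1].ravel()
    alt = ((i + j) % 2 == 0).ravel()
    t1 = np.where(alt[:, None], np.column_stack([n00, n10, n11]), np.column_stack([n00, n10, n01]))
    t2 = np.where(alt[:, None], np.column_stack([n00, n11, n01]), np.column_stack([n10, n11, n01]))
    tris = np.vstack([t1, t2])
    cell = np.tile(np.arange(len(n00)), 2)
    centers = np.column_stack(
        [
            0.5 * (rl[i.ravel()] + rl[i.ravel() + 1]),
            0.5 * (zl[j.ravel()] + zl[j.ravel() + 1]),
        ]
    )
    return nodes, tris, centers[cell]


def rectangle_mesh(
    r0: float,
    r1: float,
    z0: float,
    z1: float,
    nr: int,
    nz: int,
    region: str = "healthy_liver",
    tagger=None,
) -> Mesh:
    """Uniform structured mesh of [r0, r1] x [z0, z1]; used by the oracle suite."""
    rl = np.linspace(r0, r1, nr + 1)
    zl = np.linspace(z0, z1, nz + 1)
    nodes, tris, _ = _tensor_triangulation(rl, zl)
    return Mesh(nodes, tris, np.full(len(tris), region, dtype=object), tagger)


def generate_mesh(
    antenna: AntennaGeometry,
    tumor: TumorShape | None,
    domain_radius: float = 35.0e-3,
    z_max: float = 25.0e-3,
    h_fine: float = 0.35e-3,
    h_coarse: float = 3.0e-3,
    h_coax: float = 0.11e-3,
    growth: float = 0.25,
) -> Mesh:
    """Graded structured mesh of the antenna + tissue half-plane.

    Grid lines are snapped to the conductor radii, the slot edges, the tip
    and the feed plane; cells are classified by their centers, which is
    exact because every material interface lies on a grid line except the
    curved tumor boundary (midpoint classification there; the tumor volume
    converges quadratically with h).
    """
    a = antenna.inner_conductor_radius
    b = antenna.dielectric_outer_radius
    b2 = antenna.outer_conductor_radius
    rc = antenna.catheter_outer_radius
    z_bot = -antenna.insertion_depth
    slot_lo, slot_hi = antenna.slot_region

    ar = az = zc = None
    if tumor is not None:
        ar, az = tumor.revolved_semi_axes
        zc = float(tumor.center[2])
        if ar <= rc:
            raise ValueError("tumor lies entirely within the antenna bore")
        if ar >= domain_radius or zc + az >= z_max or zc - az <= z_bot:
            raise ValueError("tumor does not fit inside the computational domain")

    # fine window covers the slotted span and the tumor
    r_fine = max(6.0e-3, (ar or 0) + 1.5e-3)
    z_fine_lo = min(slot_lo, (zc - az) if tumor else 0.0) - 1.5e-3
    z_fine_hi = max(2.0e-3, ((zc + az) if tumor else 0.0) + 1.5e-3)

    def size_r(r):
        if r < rc:
            return h_coax
        d = max(0.0, r - r_fine)
        return min(h_coarse, h_fine + growth * d)

    def size_z(z):
        d = max(0.0, z_fine_lo - z, z - z_fine_hi)
        return min(h_coarse, h_fine + growth * d)

    r_break = [0.0, a, b, b2, rc, min(r_fine, domain_radius), domain_radius]
    z_break = {z_bot, -antenna.tip_offset, 0.0, z_max, z_fine_lo, z_fine_hi}
    for lo, hi in antenna.slot_intervals:
        z_break.update((lo, hi))
    rl = _fill(np.unique(np.round(np.array(sorted(set(r_break))), 12)), size_r)
    zl = _fill(np.unique(np.round(np.array(sorted(z_break)), 12)), size_z)

    nodes, tris, centers = _tensor_triangulation(rl, zl)

    region = _classify(centers, antenna, tumor)

    tol = 1e-9

    def tagger(rm, zm):
        if abs(zm - z_bot) < tol and a - tol <= rm <= b + tol:
            return "port"
        if rm < tol:
            return "axis"
        if rm > domain_radius - tol or zm > z_max - tol or zm < z_bot + tol:
            return "outer"
        return "conductor"

    return Mesh(nodes, tris, region, tagger)


def _classify(centers: np.ndarray, antenna: AntennaGeometry, tumor) -> np.ndarray:
    a = antenna.inner_conductor_radius
    b = antenna.dielectric_outer_radius
    b2 = antenna.outer_conductor_radius
    rc = antenna.catheter_outer_radius
    r, z = centers[:, 0], centers[:, 1]

    region = np.full(len(centers), "healthy_liver", dtype=object)
    in_ant = (z < 0) & (r < rc)
    # shorted metal tip closes both the coax and the catheter channel
    tip_plug = in_ant & (z > -antenna.tip_offset)
    inner = in_ant & (r < a) & ~tip_plug
    diel = in_ant & (r >= a) & (r < b) & ~tip_plug
    sheath = in_ant & (r >= b) & (r < b2) & ~tip_plug
    cath = in_ant & (r >= b2) & ~tip_plug
    in_slot = np.zeros(len(centers), dtype=bool)
    for lo, hi in antenna.slot_intervals:
        in_slot |= (z > lo) & (z < hi)
    region[cath] = "catheter"
    region[diel] = "antenna_dielectric"
    region[inner | tip_plug | (sheath & ~in_slot)] = "antenna_metal"
    region[sheath & in_slot] = "slot"

    if tumor is not None:
        ar, az = tumor.revolved_semi_axes
        zc = float(tumor.center[2])
        tissue = ~in_ant & ~tip_plug
        in_tum = tissue & ((r / ar) ** 2 + ((z - zc) / az) ** 2 <= 1.0)
        region[in_tum] = "tumor"
    return region
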