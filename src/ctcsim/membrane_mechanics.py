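"""Coarse-grained spectrin-link membrane model for deformable blood cells.

A cell is a closed triangulated surface whose deformation is resisted by
four restoring-force channels, each derived as the negative gradient of an
elastic energy:

* **links** - every mesh edge acts as a nonlinear spring.  The tension is
  linear in the strain ``x = l/l0 - 1`` for small deformations and is
  multiplied by the diverging factor ``1/(1 - (x/x_max)^2)`` as the strain
  approaches the saturation ratio ``x_max``, mimicking the finite
  extensibility of the spectrin network.
* **bending** - a harmonic spring on each edge's dihedral angle resists
  curvature changes relative to the rest shape.
* **area** - per-triangle and whole-surface quadratic penalties resist local
  and global dilation of the membrane.
* **volume** - a quadratic penalty on the enclosed volume models the
  incompressible cytosol.

Because every channel is the gradient of a translation- and
rotation-invariant energy, all channels are automatically momentum- and
torque-free; the test suite verifies both this and the analytic gradients
against numerical differentiation.

The module also provides the quasi-static optical-tweezers-style stretch
test used to characterise whole-cell stiffness: opposite tensions are
applied to the extreme 5% of vertices on each side and the mesh is relaxed
to equilibrium at each force level with a FIRE (fast inertial relaxation
engine) pseudo-time integrator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .errors import ConvergenceError, DegenerateGeometryError, ParameterError

__all__ = [
    "CellMesh",
    "ReferenceState",
    "MaterialModel",
    "StretchCurve",
    "build_icosphere_mesh",
    "build_oblate_mesh",
    "build_biconcave_mesh",
    "link_forces",
    "bending_forces",
    "area_forces",
    "volume_forces",
    "total_membrane_force",
    "membrane_energy",
    "relax_to_equilibrium",
    "stretch_test",
]

_MIN_TRIANGLE_AREA = 1e-6  # um^2


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross dispatch overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

class CellMesh:
    """Lagrangian triangulated membrane.

    Vertices are in micrometres unless the caller works in another
    consistent unit.  Faces must be consistently outward-oriented; the
    constructor verifies the mesh is a closed orientable 2-manifold and
    builds the edge tables used by the force channels:

    ``edges[e] = (i, j)`` and ``edge_opposite[e] = (k, l)`` where ``(i,j,k)``
    and ``(j,i,l)`` are the two incident triangles.
    """

    def __init__(self, vertices, faces, kind: str = "ctc", cell_id: int = 0):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        self.kind = kind
        self.cell_id = cell_id
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DegenerateGeometryError("vertices must have shape (n, 3)")
        self._build_edges()

    def _build_edges(self) -> None:
        half = {}
        for fi, (a, b, c) in enumerate(self.faces):
            for u, v, opp in ((a, b, c), (b, c, a), (c, a, b)):
                if (u, v) in half:
                    raise DegenerateGeometryError("duplicate half-edge: mesh not a manifold")
                half[(u, v)] = opp
        edges, edge_opp = [], []
        for (u, v), k in half.items():
            if u < v:
                if (v, u) not in half:
                    raise DegenerateGeometryError("open mesh: boundary edge found")
                edges.append((u, v))
                edge_opp.append((k, half[(v, u)]))
        self.edges = np.array(edges, dtype=np.int64)
        self.edge_opposite = np.array(edge_opp, dtype=np.int64)
        if self.euler_characteristic != 2:
            raise DegenerateGeometryError(
                f"mesh is not a topological sphere (chi={self.euler_characteristic})"
            )
        if np.any(self.triangle_areas() < _MIN_TRIANGLE_AREA):
            raise DegenerateGeometryError("degenerate triangle (area < 1e-6)")

    # -- topology ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.faces)

    # -- geometry ---------------------------------------------------------
    def edge_vectors(self) -> np.ndarray:
        return self.vertices[self.edges[:, 1]] - self.vertices[self.edges[:, 0]]

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def face_normals_raw(self) -> np.ndarray:
        """Unnormalized outward normals, |n| = 2 * area."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return _cross(b - a, c - a)

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals_raw(), axis=1)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def volume(self) -> float:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, _cross(b, c)).sum() / 6.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def dihedral_angles(self) -> np.ndarray:
        theta, _ = _dihedrals_and_gradients(self.vertices, self.edges, self.edge_opposite, grads=False)
        return theta

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex surface patch (one third of incident triangle areas)."""
        areas = self.triangle_areas()
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.faces.reshape(-1), np.repeat(areas / 3.0, 3))
        return va

    def diameter(self) -> float:
        """Max pairwise vertex distance (exact via convex-hull points)."""
        from scipy.spatial import ConvexHull

        pts = self.vertices[ConvexHull(self.vertices).vertices]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    def copy(self) -> "CellMesh":
        return CellMesh(self.vertices.copy(), self.faces, kind=self.kind, cell_id=self.cell_id)

    def transformed(self, rotation=None, translation=None) -> "CellMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        if translation is not None:
            v = v + np.asarray(translation)
        return CellMesh(v, self.faces, kind=self.kind, cell_id=self.cell_id)


@dataclass
class ReferenceState:
    """Rest geometry captured from the undeformed mesh."""

    rest_lengths: np.ndarray
    rest_tri_areas: np.ndarray
    rest_total_area: float
    rest_volume: float
    rest_dihedrals: np.ndarray

    @classmethod
    def from_mesh(cls, mesh: CellMesh) -> "ReferenceState":
        tri = mesh.triangle_areas()
        return cls(
            rest_lengths=mesh.edge_lengths(),
            rest_tri_areas=tri,
            rest_total_area=float(tri.sum()),
            rest_volume=mesh.volume(),
            rest_dihedrals=mesh.dihedral_angles(),
        )


@dataclass
class MaterialModel:
    """Stiffnesses of the four force channels.

    Units assume vertex positions in micrometres; forces come out in pN.

    k_link : pN
        Edge tension per unit strain in the linear regime.
    k_bend : pN um
        Dihedral-angle spring constant.
    k_area_local, k_area_global : pN / um
        Local / global area-dilation penalties.
    k_volume : pN / um^2
        Volume-restoration penalty.
    strain_max : dimensionless
        Saturation strain ratio of the diverging link nonlinearity.
    link_force_cap : pN
        Hard cap on a single link tension (numerical guard near saturation).
    scale : dimensionless
        Global stiffness multiplier (0.7 / 1.3 for the +-30% studies).
    """

    k_link: float = 60.0
    k_bend: float = 3.0
    k_area_local: float = 50.0
    k_area_global: float = 100.0
    k_volume: float = 250.0
    strain_max: float = 1.0
    link_force_cap: float = 1e4
    scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_link", "k_bend", "k_area_local", "k_area_global", "k_volume"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.scale <= 0:
            raise ParameterError("stiffness scale factor must be positive")
        if self.strain_max <= 0:
            raise ParameterError("strain_max must be positive")

    def scaled(self, s: float) -> "MaterialModel":
        return replace(self, scale=self.scale * s)


# ---------------------------------------------------------------------------
# Force channels (each the exact negative gradient of an energy)
# ---------------------------------------------------------------------------

def _check_topology(mesh: CellMesh, ref: ReferenceState) -> None:
    if len(mesh.edges) != len(ref.rest_lengths):
        raise DegenerateGeometryError("mesh and reference state topology differ")


def _link_tension(strain: np.ndarray, mat: MaterialModel) -> np.ndarray:
    """Signed tension (pN) on each edge; positive = contracting."""
    x = strain / mat.strain_max
    denom = 1.0 - np.clip(x * x, 0.0, None)
    k = mat.k_link * mat.scale
    with np.errstate(divide="ignore"):
        t = k * strain / denom
    cap = mat.link_force_cap * mat.scale
    over = ~np.isfinite(t) | (np.abs(t) > cap)
    if np.any(over):
        warnings.warn("link extension at saturation; capping force", RuntimeWarning, stacklevel=2)
        t = np.where(over, np.sign(strain) * cap, t)
    return t


def link_forces(mesh: CellMesh, ref: ReferenceState, mat: MaterialModel) -> np.ndarray:
    """In-plane spectrin-link forces; equal and opposite on edge endpoints."""
    _check_topology(mesh, ref)
    d = mesh.edge_vectors()
    l = np.linalg.norm(d, axis=1)
    strain = l / ref.rest_lengths - 1.0
    tension = _link_tension(strain, mat)
    fvec = (tension / l)[:, None] * d  # force on first endpoint, toward second
    out = np.zeros_like(mesh.vertices)
    np.add.at(out, mesh.edges[:, 0], fvec)
    np.add.at(out, mesh.edges[:, 1], -fvec)
    return out


def _dihedrals_and_gradients(verts, edges, edge_opp, grads: bool = True):
    """Signed dihedral angle per edge and, optionally, its vertex gradients.

    Convention: theta = 0 for coplanar faces, positive for a convex fold
    (outward normals opening away from each other).
    """
    x0 = verts[edges[:, 0]]
    x1 = verts[edges[:, 1]]
    x2 = verts[edge_opp[:, 0]]
    x3 = verts[edge_opp[:, 1]]
    e = x1 - x0
    le = np.linalg.norm(e, axis=1)
    n1 = _cross(x1 - x0, x2 - x0)
    n2 = _cross(x3 - x0, x1 - x0)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    cosarg = np.einsum("ij,ij->i", n1, n2)
    sinarg = np.einsum("ij,ij->i", _cross(n1, n2), e) / le
    theta = np.arctan2(sinarg, cosarg)
    if not grads:
        return theta, None
    g1 = -n1 / n1sq[:, None]
    g2 = -n2 / n2sq[:, None]
    d2 = le[:, None] * g1
    d3 = le[:, None] * g2
    a0 = np.einsum("ij,ij->i", x2 - x1, e) / le
    b0 = np.einsum("ij,ij->i", x3 - x1, e) / le
    a1 = np.einsum("ij,ij->i", x0 - x2, e) / le
    b1 = np.einsum("ij,ij->i", x0 - x3, e) / le
    d0 = a0[:, None] * g1 + b0[:, None] * g2
    d1 = a1[:, None] * g1 + b1[:, None] * g2
    return theta, (d0, d1, d2, d3)


def bending_forces(mesh: CellMesh, ref: ReferenceState, mat: MaterialModel) -> np.ndarray:
    """Dihedral restoring forces, zero at the rest angles."""
    _check_topology(mesh, ref)
    theta, grads = _dihedrals_and_gradients(mesh.vertices, mesh.edges, mesh.edge_opposite)
    coeff = -mat.k_bend * mat.scale * (theta - ref.rest_dihedrals)
    out = np.zeros_like(mesh.vertices)
    idx = (mesh.edges[:, 0], mesh.edges[:, 1], mesh.edge_opposite[:, 0], mesh.edge_opposite[:, 1])
    for vid, g in zip(idx, grads):
        np.add.at(out, vid, coeff[:, None] * g)
    return out


def _triangle_area_gradients(mesh: CellMesh):
    """Per-face areas and dA/dx for each of the three corners."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    n = _cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    nhat = n / nn[:, None]
    area = 0.5 * nn
    ga = 0.5 * _cross(nhat, c - b)
    gb = 0.5 * _cross(nhat, a - c)
    gc = 0.5 * _cross(nhat, b - a)
    return area, (ga, gb, gc)


def area_forces(mesh: CellMesh, ref: ReferenceState, mat: MaterialModel) -> np.ndarray:
    """Local + global area restoration forces."""
    _check_topology(mesh, ref)
    area, (ga, gb, gc) = _triangle_area_gradients(mesh)
    total = area.sum()
    s = mat.scale
    local = -mat.k_area_local * s * (area - ref.rest_tri_areas) / ref.rest_tri_areas
    glob = -mat.k_area_global * s * (total - ref.rest_total_area) / ref.rest_total_area
    coeff = (local + glob)[:, None]
    out = np.zeros_like(mesh.vertices)
    np.add.at(out, mesh.faces[:, 0], coeff * ga)
    np.add.at(out, mesh.faces[:, 1], coeff * gb)
    np.add.at(out, mesh.faces[:, 2], coeff * gc)
    return out


def volume_forces(mesh: CellMesh, ref: ReferenceState, mat: MaterialModel) -> np.ndarray:
    """Enclosed-volume restoration via per-triangle normal contributions."""
    _check_topology(mesh, ref)
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    vol = mesh.volume()
    coeff = -mat.k_volume * mat.scale * (vol - ref.rest_volume) / ref.rest_volume
    out = np.zeros_like(mesh.vertices)
    np.add.at(out, mesh.faces[:, 0], coeff * _cross(b, c) / 6.0)
    np.add.at(out, mesh.faces[:, 1], coeff * _cross(c, a) / 6.0)
    np.add.at(out, mesh.faces[:, 2], coeff * _cross(a, b) / 6.0)
    return out


def total_membrane_force(mesh: CellMesh, ref: ReferenceState, mat: MaterialModel):
    """Sum of the four channels (single fused pass over edges and faces).

    Numerically identical to summing the individual channel functions; the
    shared geometry gathers just make the evaluation cheap enough for the
    inner simulation loop.

    Returns
    -------
    forces : (n, 3) ndarray, pN
    magnitudes : (n,) ndarray, pN
    magnitude_integral : float, pN um^2 weighted by vertex surface patches
        (divide by 1e3 for the nN-scale summaries when vertex areas are
        normalized out; see :func:`ctcsim.metrics_analysis.membrane_force_summary`).
    """
    _check_topology(mesh, ref)
    v = mesh.vertices
    s = mat.scale
    out = np.zeros_like(v)

    # --- edge channels: link + bending --------------------------------
    e0, e1 = mesh.edges[:, 0], mesh.edges[:, 1]
    d = v[e1] - v[e0]
    l = np.sqrt(np.einsum("ij,ij->i", d, d))
    tension = _link_tension(l / ref.rest_lengths - 1.0, mat)
    fvec = (tension / l)[:, None] * d
    theta, grads = _dihedrals_and_gradients(v, mesh.edges, mesh.edge_opposite)
    coeff = (-mat.k_bend * s * (theta - ref.rest_dihedrals))[:, None]
    np.add.at(out, e0, fvec + coeff * grads[0])
    np.add.at(out, e1, -fvec + coeff * grads[1])
    np.add.at(out, mesh.edge_opposite[:, 0], coeff * grads[2])
    np.add.at(out, mesh.edge_opposite[:, 1], coeff * grads[3])

    # --- face channels: area (local+global) + volume -------------------
    fa, fb, fc = mesh.faces[:, 0], mesh.faces[:, 1], mesh.faces[:, 2]
    a, b, c = v[fa], v[fb], v[fc]
    n = _cross(b - a, c - a)
    nn = np.sqrt(np.einsum("ij,ij->i", n, n))
    area = 0.5 * nn
    nhat = n / nn[:, None]
    total_area = area.sum()
    acoeff = (
        -mat.k_area_local * s * (area - ref.rest_tri_areas) / ref.rest_tri_areas
        - mat.k_area_global * s * (total_area - ref.rest_total_area) / ref.rest_total_area
    )[:, None]
    vol = float(np.einsum("ij,ij->i", a, _cross(b, c)).sum() / 6.0)
    vcoeff = -mat.k_volume * s * (vol - ref.rest_volume) / ref.rest_volume
    np.add.at(out, fa, acoeff * (0.5 * _cross(nhat, c - b)) + vcoeff * _cross(b, c) / 6.0)
    np.add.at(out, fb, acoeff * (0.5 * _cross(nhat, a - c)) + vcoeff * _cross(c, a) / 6.0)
    np.add.at(out, fc, acoeff * (0.5 * _cross(nhat, b - a)) + vcoeff * _cross(a, b) / 6.0)

    mag = np.sqrt(np.einsum("ij,ij->i", out, out))
    vertex_areas = np.zeros(mesh.n_vertices)
    np.add.at(vertex_areas, mesh.faces.reshape(-1), np.repeat(area / 3.0, 3))
    integral = float((mag * vertex_areas / total_area).sum() * mesh.n_vertices)
    return out, mag, integral


def membrane_energy(mesh: CellMesh, ref: ReferenceState, mat: MaterialModel) -> float:
    """Total elastic energy (pN um); the channels above are its -gradient."""
    _check_topology(mesh, ref)
    s = mat.scale
    l = mesh.edge_lengths()
    x = l / ref.rest_lengths - 1.0
    xm = mat.strain_max
    arg = np.clip(1.0 - (x / xm) ** 2, 1e-12, None)
    e_link = (mat.k_link * s * xm**2 / 2.0) * (-np.log(arg)) * ref.rest_lengths
    theta = mesh.dihedral_angles()
    e_bend = 0.5 * mat.k_bend * s * (theta - ref.rest_dihedrals) ** 2
    area = mesh.triangle_areas()
    e_al = 0.5 * mat.k_area_local * s * (area - ref.rest_tri_areas) ** 2 / ref.rest_tri_areas
    tot = area.sum()
    e_ag = 0.5 * mat.k_area_global * s * (tot - ref.rest_total_area) ** 2 / ref.rest_total_area
    vol = mesh.volume()
    e_v = 0.5 * mat.k_volume * s * (vol - ref.rest_volume) ** 2 / ref.rest_volume
    return float(e_link.sum() + e_bend.sum() + e_al.sum() + e_ag + e_v)


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

def _icosphere(subdivisions: int, radius: float):
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)


def _collapse_shortest_edges(verts: np.ndarray, faces: np.ndarray, target: int, radius: float):
    """Collapse shortest valid edges until the vertex count equals target.

    Each collapse merges an edge's endpoints at their midpoint (reprojected
    onto the sphere) provided the link condition holds (the endpoints share
    exactly two neighbours), which preserves the closed-manifold topology.
    """
    verts = verts.copy()
    faces = faces.copy()
    while len(verts) > target:
        pairs = np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
        )
        edges = np.unique(pairs, axis=0)
        lengths = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
        nbr = [set() for _ in range(len(verts))]
        for u, v in edges:
            nbr[u].add(v)
            nbr[v].add(u)
        # one pass: collapse vertex-disjoint valid short edges in bulk
        budget = len(verts) - target
        touched = np.zeros(len(verts), dtype=bool)
        removals = []
        for ei in np.argsort(lengths, kind="stable"):
            if len(removals) >= budget:
                break
            u, v = int(edges[ei, 0]), int(edges[ei, 1])
            if touched[u] or touched[v]:
                continue
            if len(nbr[u] & nbr[v]) != 2:
                continue
            # freeze the whole 1-ring so collapses cannot interact
            ring = nbr[u] | nbr[v] | {u, v}
            if any(touched[w] for w in ring):
                continue
            for w in ring:
                touched[w] = True
            mid = 0.5 * (verts[u] + verts[v])
            verts[u] = mid * (radius / np.linalg.norm(mid))
            removals.append((u, v))
        if not removals:
            raise ParameterError("edge collapse stalled before reaching target vertex count")
        gone = np.array([v for _, v in removals], dtype=np.int64)
        for u, v in removals:
            keep = ~((faces == u).any(axis=1) & (faces == v).any(axis=1))
            faces = faces[keep]
            faces[faces == v] = u
        remap = np.cumsum(~np.isin(np.arange(len(verts)), gone)) - 1
        faces = remap[faces]
        verts = np.delete(verts, gone, axis=0)
    return verts, faces


def build_icosphere_mesh(
    diameter: float, target_vertices: int, kind: str = "ctc", cell_id: int = 0
) -> CellMesh:
    """Subdivided icosphere with exactly ``target_vertices`` vertices.

    Subdivision levels give 12, 42, 162, 642, 2562, ... vertices; any other
    count is reached by collapsing shortest edges from the next level up, so
    e.g. the 1382-vertex tumor-cell mesh and the 1148-vertex platelet mesh
    are both constructible.  All vertices lie exactly on the sphere.
    """
    if diameter <= 0:
        raise ParameterError("diameter must be positive")
    if target_vertices < 12:
        raise ParameterError("icosphere needs at least 12 vertices")
    radius = diameter / 2.0
    counts = {0: 12, 1: 42, 2: 162, 3: 642, 4: 2562, 5: 10242, 6: 40962}
    level = next((lv for lv, c in counts.items() if c >= target_vertices), None)
    if level is None:
        raise ParameterError(f"target vertex count {target_vertices} too large")
    verts, faces = _icosphere(level, radius)
    if len(verts) != target_vertices:
        verts, faces = _collapse_shortest_edges(verts, faces, target_vertices, radius)
    return CellMesh(verts, faces, kind=kind, cell_id=cell_id)


def build_oblate_mesh(
    diameter: float,
    aspect: float = 0.5,
    target_vertices: int = 162,
    kind: str = "platelet",
    cell_id: int = 0,
) -> CellMesh:
    """Oblate ellipsoid (platelet rest shape): z-axis scaled by ``aspect``."""
    sphere = build_icosphere_mesh(diameter, target_vertices, kind=kind, cell_id=cell_id)
    v = sphere.vertices.copy()
    v[:, 2] *= aspect
    return CellMesh(v, sphere.faces, kind=kind, cell_id=cell_id)


def build_biconcave_mesh(
    diameter: float = 7.82, target_vertices: int = 162, cell_id: int = 0
) -> CellMesh:
    """Biconcave discocyte (red-blood-cell rest shape), Evans-Fung profile."""
    sphere = build_icosphere_mesh(2.0, target_vertices, kind="rbc", cell_id=cell_id)
    u = sphere.vertices / 1.0  # unit sphere
    r0 = diameter / 2.0
    rxy = np.sqrt(u[:, 0] ** 2 + u[:, 1] ** 2)
    r2 = np.clip(rxy, 0, 1.0) ** 2
    profile = 0.5 * np.sqrt(np.clip(1.0 - r2, 0.0, None)) * (0.207 + 2.003 * r2 - 1.123 * r2**2)
    v = np.empty_like(u)
    v[:, 0] = u[:, 0] * r0
    v[:, 1] = u[:, 1] * r0
    v[:, 2] = np.sign(u[:, 2]) * profile * r0
    # keep triangles non-degenerate at the rim by blending a small sphere height
    v[:, 2] += 0.08 * r0 * u[:, 2]
    return CellMesh(v, sphere.faces, kind="rbc", cell_id=cell_id)


# ---------------------------------------------------------------------------
# Quasi-static relaxation (FIRE) and the stretch test
# ---------------------------------------------------------------------------

def relax_to_equilibrium(
    mesh: CellMesh,
    ref: ReferenceState,
    mat: MaterialModel,
    external_forces: np.ndarray | None = None,
    residual_tol: float = 0.1,
    max_iter: int = 60000,
    dt_init: float | None = None,
) -> int:
    """Damped pseudo-time relaxation to mechanical equilibrium (in place).

    FIRE integration: velocities are mixed toward the force direction and
    the pseudo-timestep grows while the power F.v stays positive, giving
    near-critically-damped convergence.  Converged when the max nodal
    residual force drops below ``residual_tol`` (pN).

    Returns the number of iterations used.
    """
    n = mesh.n_vertices
    ext = np.zeros((n, 3)) if external_forces is None else external_forces
    k_scale = max(
        mat.scale * (mat.k_link + mat.k_area_local + mat.k_area_global + mat.k_volume), 1e-9
    )
    dt = dt_init if dt_init is not None else 0.04 / np.sqrt(k_scale)
    dt_max, dt_min = 25.0 * dt, 0.02 * dt
    alpha0, f_inc, f_dec, f_alpha, n_min = 0.1, 1.1, 0.5, 0.99, 5
    alpha = alpha0
    vel = np.zeros((n, 3))
    good_steps = 0
    for it in range(1, max_iter + 1):
        force, _, _ = total_membrane_force(mesh, ref, mat)
        force += ext
        res = float(np.abs(force).max())
        if not np.isfinite(res):
            raise ConvergenceError("relaxation diverged (non-finite forces)", residual=res)
        if res < residual_tol:
            return it
        power = float((force * vel).sum())
        if power > 0.0:
            fn = np.linalg.norm(force)
            vn = np.linalg.norm(vel)
            vel = (1.0 - alpha) * vel + alpha * (vn / max(fn, 1e-300)) * force
            good_steps += 1
            if good_steps > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            vel[:] = 0.0
            dt = max(dt * f_dec, dt_min)
            alpha = alpha0
            good_steps = 0
        vel += dt * force
        mesh.vertices += dt * vel
    raise ConvergenceError(
        f"relaxation did not converge in {max_iter} iterations (residual {res:.3g} pN)",
        residual=res,
    )


@dataclass
class StretchCurve:
    """Force-deformation record of a quasi-static stretch test."""

    forces: np.ndarray  # pN, applied total tension per side
    major_axis: np.ndarray  # um
    minor_axis: np.ndarray  # um
    aspect_ratio: np.ndarray  # Taylor (L-B)/(L+B)
    max_nodal_force: np.ndarray  # pN, internal membrane response
    iterations: np.ndarray = dc_field(default=None)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tension_pN": self.forces,
                "major_um": self.major_axis,
                "minor_um": self.minor_axis,
                "aspect_ratio": self.aspect_ratio,
                "max_nodal_force_pN": self.max_nodal_force,
            }
        )


def stretch_test(
    mesh: CellMesh,
    mat: MaterialModel,
    max_force: float = 2000.0,
    n_levels: int = 10,
    axis: int = 0,
    grip_fraction: float = 0.05,
    solver_opts: dict | None = None,
) -> StretchCurve:
    """Quasi-static tension ramp mimicking an optical-tweezers stretch test.

    Opposite total forces +-F along ``axis`` are distributed over the
    ``grip_fraction`` of vertices with extreme axial coordinates on each
    side; at every force level the mesh relaxes to equilibrium and the
    equivalent-ellipsoid axes and Taylor ratio are recorded.  Levels are
    ramped with warm starts, so the curve is monotone in the tension.
    """
    from .metrics_analysis import inertia_ellipsoid_axes, taylor_aspect_ratio

    if max_force <= 0:
        raise ParameterError("max_force must be positive")
    opts = dict(solver_opts or {})
    work = mesh.copy()
    ref = ReferenceState.from_mesh(work)
    n = work.n_vertices
    n_grip = max(1, int(round(grip_fraction * n)))
    order = np.argsort(work.vertices[:, axis])
    lo, hi = order[:n_grip], order[-n_grip:]
    levels = np.linspace(0.0, max_force, n_levels + 1)
    out = {k: [] for k in ("L", "B", "ar", "fmax", "iters")}
    for f_level in levels:
        ext = np.zeros((n, 3))
        ext[lo, axis] = -f_level / n_grip
        ext[hi, axis] = +f_level / n_grip
        iters = relax_to_equilibrium(work, ref, mat, external_forces=ext, **opts)
        big, small = inertia_ellipsoid_axes(work)
        _, mag, _ = total_membrane_force(work, ref, mat)
        out["L"].append(big)
        out["B"].append(small)
        out["ar"].append(taylor_aspect_ratio(big, small))
        out["fmax"].append(float(mag.max()))
        out["iters"].append(iters)
    return StretchCurve(
        forces=levels,
        major_axis=np.array(out["L"]),
        minor_axis=np.array(out["B"]),
        aspect_ratio=np.array(out["ar"]),
        max_nodal_force=np.array(out["fmax"]),
        iterations=np.array(out["iters"]),
    )
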