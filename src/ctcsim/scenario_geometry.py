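"""Declarative construction of microvessel scenarios.

The standard domain is a straight cylindrical microvessel (20 um diameter,
40 um long by default) discretized on a cubic lattice (0.5 um spacing by
default) with axial (z) periodicity.  The wall is a rigid stair-case
voxelization; ligand sites for the adhesive dynamics are placed on the
analytic cylinder surface in a deterministic staggered ring pattern.

A tumor cell is placed near the bottom wall (the upstream margination phase
is deliberately skipped), platelets are pre-attached to its wall-facing
hemisphere at bond distance, and red blood cells can be seeded in the
remaining lumen by rejection sampling.  Everything is deterministic given
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np

from .errors import ConfigurationError, PlacementError
from .lattice_fluid import EXTERIOR, FLUID, WALL, D3Q19
from .membrane_mechanics import (
    CellMesh,
    build_biconcave_mesh,
    build_icosphere_mesh,
    build_oblate_mesh,
)

__all__ = [
    "VesselGeometry",
    "Vessel",
    "ScenarioConfig",
    "build_vessel",
    "place_ctc_near_wall",
    "attach_platelets",
    "seed_rbcs",
    "scenario_hash",
]


@dataclass
class VesselGeometry:
    """Cylindrical vessel: diameter/length in um, lattice spacing dx in um."""

    diameter: float = 20.0
    length: float = 40.0
    dx: float = 0.5
    wall_site_spacing: float = 0.5  # um between ligand sites on the wall

    def __post_init__(self) -> None:
        for name in ("diameter", "length"):
            v = getattr(self, name)
            if v <= 0 or abs(v / self.dx - round(v / self.dx)) > 1e-9:
                raise ConfigurationError(f"{name}={v} must be a positive multiple of dx={self.dx}")

    @property
    def radius_nodes(self) -> float:
        return self.diameter / self.dx / 2.0

    @property
    def nz(self) -> int:
        return int(round(self.length / self.dx))


class Vessel:
    """Voxelized vessel: node flags, wall ligand sites, coordinate helpers.

    All coordinates are lattice units; the axis is parallel to z at
    ``axis_xy``.  ``wall_sites`` lie on the analytic surface r = R.
    """

    def __init__(self, geom: VesselGeometry):
        self.geom = geom
        r = geom.radius_nodes
        n_cross = int(2 * r) + 5  # fluid + >=1 wall shell + exterior margin
        nz = geom.nz
        ax = (n_cross - 1) / 2.0
        self.axis_xy = (ax, ax)
        self.radius_nodes = r
        x, y = np.meshgrid(np.arange(n_cross), np.arange(n_cross), indexing="ij")
        r2 = (x - ax) ** 2 + (y - ax) ** 2
        fluid2d = r2 < r**2
        flags2d = np.full((n_cross, n_cross), EXTERIOR, dtype=np.uint8)
        flags2d[fluid2d] = FLUID
        # wall shell: non-fluid nodes reachable by one lattice link from fluid
        wall2d = np.zeros_like(fluid2d)
        for ex, ey, ez in D3Q19.e[1:]:
            if ez != 0 and ex == 0 and ey == 0:
                continue
            wall2d |= np.roll(fluid2d, (ex, ey), axis=(0, 1))
        wall2d &= ~fluid2d
        flags2d[wall2d] = WALL
        self.flags = np.ascontiguousarray(np.repeat(flags2d[:, :, None], nz, axis=2))
        self._wall_sites = self._make_wall_sites()

    def node_coordinates(self):
        nx, ny, nz = self.flags.shape
        return np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")

    def wall_adjacent_mask(self) -> np.ndarray:
        """Fluid nodes with at least one wall neighbour (WSS sampling shell)."""
        fluid = self.flags == FLUID
        wall = self.flags == WALL
        near = np.zeros_like(fluid)
        for ex, ey, ez in D3Q19.e[1:]:
            near |= np.roll(wall, (-ex, -ey, -ez), axis=(0, 1, 2))
        return fluid & near

    def _make_wall_sites(self) -> np.ndarray:
        g = self.geom
        ds = g.wall_site_spacing / g.dx  # lattice units
        n_theta = max(3, int(round(2.0 * np.pi * self.radius_nodes / ds)))
        n_axial = max(1, int(round(self.flags.shape[2] / ds)))
        zs = (np.arange(n_axial) + 0.5) * self.flags.shape[2] / n_axial
        sites = []
        for k, z in enumerate(zs):
            offset = 0.5 * (k % 2)  # staggered rings
            theta = 2.0 * np.pi * (np.arange(n_theta) + offset) / n_theta
            ring = np.column_stack(
                [
                    self.axis_xy[0] + self.radius_nodes * np.cos(theta),
                    self.axis_xy[1] + self.radius_nodes * np.sin(theta),
                    np.full(n_theta, z),
                ]
            )
            sites.append(ring)
        return np.vstack(sites)

    @property
    def wall_sites(self) -> np.ndarray:
        """Ligand site positions on the analytic wall surface, lattice units."""
        return self._wall_sites

    def wall_sites_um(self) -> np.ndarray:
        return self._wall_sites * self.geom.dx

    def radial_distance(self, points) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.sqrt((p[:, 0] - self.axis_xy[0]) ** 2 + (p[:, 1] - self.axis_xy[1]) ** 2)


def build_vessel(geom: VesselGeometry) -> Vessel:
    """Voxelize the cylinder and generate wall ligand sites."""
    return Vessel(geom)


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Full declarative description of one simulation run."""

    vessel: dict = dc_field(default_factory=dict)  # VesselGeometry kwargs
    n_platelets: int = 0
    ctc_diameter: float = 8.0
    ctc_vertices: int = 642
    platelet_diameter: float = 2.0
    platelet_aspect: float = 0.5
    platelet_vertices: int = 42
    ctc_stiffness_scale: float = 1.0
    platelet_stiffness_scale: float = 1.0
    n_rbc: int = 0
    rbc_vertices: int = 162
    wall_gap: float = 0.5  # um, initial CTC clearance from the wall
    material: dict = dc_field(default_factory=dict)  # MaterialModel kwargs (CTC)
    adhesion: dict = dc_field(default_factory=dict)  # AdhesionParams kwargs
    tau: float = 1.0
    re: float = 0.025
    nu_phys: float = 1.2e-6
    n_steps: int = 10000
    output_every: int = 200
    neighbor_every: int = 25
    scheme: str = "effective_force"
    seed: int = 0
    duration: float | None = None  # seconds; overrides n_steps when set
    contact_cutoff: float = 0.3  # um, short-range cell/cell and cell/wall repulsion
    k_contact: float = 500.0  # pN at full overlap
    arrest_window: float | None = None  # s; defaults to a quarter of the run
    arrest_tol: float = 5.0  # um, firm-adhesion displacement tolerance
    platelet_placement: str = "wall_biased"
    vtk_every: int = 0  # fluid/membrane VTK snapshot cadence (0 = off)
    velocity_smoothing: float = 0.25  # sub-grid vertex-velocity filter strength
    force_clamp: float = 2500.0  # pN per vertex entering the fluid (CFL guard)

    def __post_init__(self) -> None:
        if self.n_platelets < 0 or self.n_rbc < 0:
            raise ConfigurationError("cell counts must be non-negative")
        geom = self.vessel_geometry()
        if not 0 < self.ctc_diameter < geom.diameter:
            raise ConfigurationError(
                f"CTC diameter {self.ctc_diameter} must lie in (0, vessel diameter)"
            )

    def vessel_geometry(self) -> VesselGeometry:
        return VesselGeometry(**self.vessel)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Cell placement
# ---------------------------------------------------------------------------

def place_ctc_near_wall(config: ScenarioConfig, vessel: Vessel) -> CellMesh:
    """Position the tumor cell just above the bottom wall (y minimal).

    The cell surface clears the analytic wall by ``config.wall_gap`` um; a
    configuration error is raised when the cell cannot fit.
    """
    geom = vessel.geom
    radius_um = config.ctc_diameter / 2.0
    if config.ctc_diameter >= geom.diameter:
        raise ConfigurationError("CTC does not fit in the vessel")
    mesh = build_icosphere_mesh(config.ctc_diameter, config.ctc_vertices, kind="ctc", cell_id=0)
    # lattice-unit centre: on the vertical through the axis, near the bottom
    r_centre = (geom.diameter / 2.0 - config.wall_gap - radius_um) / geom.dx
    centre = np.array(
        [vessel.axis_xy[0], vessel.axis_xy[1] - r_centre, vessel.flags.shape[2] / 2.0]
    )
    mesh.vertices = mesh.vertices / geom.dx + centre
    return mesh


def _fibonacci_directions(n: int, hemisphere: bool, rng: np.random.Generator) -> np.ndarray:
    """Low-discrepancy unit vectors; optionally wall-facing (-y) hemisphere."""
    i = np.arange(n, dtype=float) + 0.5
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * i / golden + rng.uniform(0, 2 * np.pi)
    if hemisphere:
        cosang = -(1.0 - i / n)  # from the -y (wall-facing) pole up to the equator
        sinang = np.sqrt(1.0 - cosang**2)
        dirs = np.column_stack([sinang * np.cos(phi), cosang, sinang * np.sin(phi)])
    else:
        cosang = 1.0 - 2.0 * i / n
        sinang = np.sqrt(1.0 - cosang**2)
        dirs = np.column_stack([sinang * np.cos(phi), cosang, sinang * np.sin(phi)])
    return dirs


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the given unit direction."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def attach_platelets(
    ctc: CellMesh,
    n: int,
    config: ScenarioConfig,
    vessel: Vessel,
    params,
    seed: int = 0,
    placement: str = "wall_biased",
):
    """Place n platelets on the tumor-cell surface and pre-bond them.

    Platelets are oblate discs laid tangentially on the CTC at bond
    distance, sampled by a seeded Fibonacci spiral biased toward the
    wall-facing hemisphere (or uniformly).  Returns (platelet meshes,
    list of (platelet_index, pairs) pre-formed CTC-platelet bond pairs).
    """
    from .adhesion_dynamics import candidate_pairs

    if n == 0:
        return [], []
    if placement not in ("wall_biased", "uniform"):
        raise ConfigurationError(f"unknown placement {placement!r}")
    rng = np.random.default_rng(seed)
    dx = vessel.geom.dx
    centre = ctc.centroid()
    r_ctc = config.ctc_diameter / 2.0 / dx
    half_thick = config.platelet_diameter * config.platelet_aspect / 2.0 / dx
    stand_off = r_ctc + half_thick + params.l0 / dx
    proto = build_oblate_mesh(
        config.platelet_diameter, config.platelet_aspect, config.platelet_vertices
    )
    min_sep = config.platelet_diameter / dx  # centre separation to avoid overlap
    # oversample a fixed spiral so placements nest: the first k accepted
    # positions are identical for every platelet count (scenarios differ
    # only by how many platelets are attached)
    dirs = _fibonacci_directions(128, placement == "wall_biased", rng)
    chosen: list[np.ndarray] = []
    for d in dirs:
        pos = centre + stand_off * d
        if vessel.radial_distance(pos[None])[0] + half_thick > vessel.radius_nodes - 0.2:
            continue  # would intersect the wall
        if all(np.linalg.norm(pos - q) >= min_sep for q in chosen):
            chosen.append(pos)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise PlacementError(
            f"could only place {len(chosen)} of {n} platelets without overlap; "
            "reduce n or relax spacing"
        )
    platelets, bonds = [], []
    for k, pos in enumerate(chosen):
        d = (pos - centre) / np.linalg.norm(pos - centre)
        rot = _rotation_to(d)  # disc symmetry axis along the radial direction
        mesh = proto.transformed(rotation=rot)
        mesh = CellMesh(mesh.vertices / dx + pos, mesh.faces, kind="platelet", cell_id=k + 1)
        pairs = candidate_pairs(
            ctc.vertices * dx,
            mesh.vertices * dx,
            params.cutoff,
            max_per_a=params.max_bonds_per_vertex,
            max_per_b=params.max_bonds_per_vertex,
        )
        platelets.append(mesh)
        bonds.append((k, pairs))
    return platelets, bonds


def seed_rbcs(
    count: int,
    config: ScenarioConfig,
    vessel: Vessel,
    existing: list[CellMesh],
    seed: int = 0,
    max_attempts: int = 2000,
) -> list[CellMesh]:
    """Seed biconcave red cells collision-free by rejection sampling."""
    if count == 0:
        return []
    rng = np.random.default_rng(seed)
    dx = vessel.geom.dx
    proto = build_biconcave_mesh(target_vertices=config.rbc_vertices)
    r_rbc = proto.diameter() / 2.0 / dx
    nz = vessel.flags.shape[2]
    placed: list[CellMesh] = []
    others = [(c.centroid(), c.diameter() / 2.0) for c in existing]
    for attempt in range(max_attempts):
        if len(placed) == count:
            break
        rho = vessel.radius_nodes * np.sqrt(rng.random()) * 0.8
        ang = rng.uniform(0, 2 * np.pi)
        pos = np.array(
            [
                vessel.axis_xy[0] + rho * np.cos(ang),
                vessel.axis_xy[1] + rho * np.sin(ang),
                rng.uniform(0, nz),
            ]
        )
        if vessel.radial_distance(pos[None])[0] + r_rbc > vessel.radius_nodes - 1.0:
            continue
        clear = True
        for c, r in others + [(p.centroid(), r_rbc) for p in placed]:
            dz = pos[2] - c[2]
            dz -= nz * round(dz / nz)
            if np.sqrt((pos[0] - c[0]) ** 2 + (pos[1] - c[1]) ** 2 + dz**2) < r_rbc + r + 0.5:
                clear = False
                break
        if not clear:
            continue
        axis = rng.standard_normal(3)
        rot = _rotation_to(axis / np.linalg.norm(axis))
        mesh = proto.transformed(rotation=rot)
        mesh = CellMesh(
            mesh.vertices / dx + pos, mesh.faces, kind="rbc", cell_id=1000 + len(placed)
        )
        placed.append(mesh)
    if len(placed) < count:
        raise PlacementError(f"placed only {len(placed)} of {count} RBCs in {max_attempts} tries")
    return placed


def scenario_hash(config: ScenarioConfig, cells: list[CellMesh]) -> str:
    """Deterministic digest of the configuration and all vertex coordinates."""
    h = hashlib.sha256()
    h.update(json.dumps(config.to_dict(), sort_keys=True).encode())
    for c in cells:
        h.update(np.ascontiguousarray(c.vertices).tobytes())
        h.update(np.ascontiguousarray(c.faces).tobytes())
    return h.hexdigest()
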