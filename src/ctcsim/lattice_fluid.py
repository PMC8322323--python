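"""Incompressible plasma flow on a D3Q19 BGK lattice.

The plasma inside a microvessel is modelled as an incompressible Newtonian
fluid with the single-relaxation-time (BGK) lattice-Boltzmann method on the
D3Q19 velocity set.  Populations ``f_i`` relax toward the low-Mach
equilibrium

    f_i^eq = w_i rho [1 + 3 (e_i.u) + 9/2 (e_i.u)^2 - 3/2 u^2]

and the macroscopic fields are the first two moments, ``rho = sum_i f_i`` and
``u = (1/rho) sum_i f_i e_i``.  The Chapman-Enskog limit of the scheme is the
incompressible Navier-Stokes equation with kinematic viscosity
``nu = c_s^2 (tau - 1/2)`` (lattice units, ``c_s^2 = 1/3``) and ideal
equation of state ``p = rho c_s^2``.

Walls are represented by a stair-case voxelization with halfway bounce-back
(no slip); the axial direction (z) is periodic.  A sustained Poiseuille flow
is driven by a uniform body force using a first-order forcing term
``3 w_i rho (e_i.g)``, which injects exactly ``rho g`` of momentum per step
and is accurate in the Stokes regime relevant here (Re ~ 0.025).

All operations mutate and return the passed :class:`FluidField` unless noted
otherwise.  A fused numba kernel (:mod:`ctcsim._kernels`) implements the same
collide/stream/bounce-back update for production runs and is cross-checked
against the reference numpy operations in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .errors import InvalidStateError, StabilityError

__all__ = [
    "D3Q19",
    "VelocitySet",
    "LatticeConfig",
    "FluidField",
    "FLUID",
    "WALL",
    "EXTERIOR",
    "equilibrium_distribution",
    "compute_moments",
    "bgk_collide",
    "stream_periodic",
    "bounce_back_walls",
    "apply_body_force",
    "initialize_poiseuille",
    "fluid_step",
]

# Node flags
FLUID = 0
WALL = 1
EXTERIOR = 2

#: Maximum lattice velocity considered safe for the low-Mach expansion.
MAX_LATTICE_SPEED = 0.05


@dataclass(frozen=True)
class VelocitySet:
    """Discrete velocity set: directions, weights and speed of sound."""

    e: np.ndarray  # (q, 3) int
    w: np.ndarray  # (q,) float
    cs2: float  # speed of sound squared
    opposite: np.ndarray  # (q,) int, index of -e_i

    @property
    def q(self) -> int:
        return self.e.shape[0]


def _make_d3q19() -> VelocitySet:
    e = [(0, 0, 0)]
    # axis-aligned
    for a in range(3):
        for s in (1, -1):
            v = [0, 0, 0]
            v[a] = s
            e.append(tuple(v))
    # face diagonals
    for a in range(3):
        b = (a + 1) % 3
        for sa in (1, -1):
            for sb in (1, -1):
                v = [0, 0, 0]
                v[a], v[b] = sa, sb
                e.append(tuple(v))
    e = np.array(sorted(e, key=lambda v: (sum(abs(c) for c in v), v)), dtype=np.int64)
    w = np.empty(19)
    for i, v in enumerate(e):
        n = int(np.abs(v).sum())
        w[i] = {0: 1.0 / 3.0, 1: 1.0 / 18.0, 2: 1.0 / 36.0}[n]
    opp = np.array([int(np.where((e == -v).all(axis=1))[0][0]) for v in e], dtype=np.int64)
    return VelocitySet(e=e, w=w, cs2=1.0 / 3.0, opposite=opp)


D3Q19 = _make_d3q19()


@dataclass
class LatticeConfig:
    """Physical/lattice unit bridge for one simulation.

    The timestep follows the diffusive scaling
    ``dt = c_s^2 (tau - 1/2) dx^2 / nu_phys``, so the lattice viscosity
    ``c_s^2 (tau - 1/2)`` maps exactly onto the physical plasma viscosity.

    Parameters
    ----------
    shape : tuple of int
        Lattice nodes per axis (nx, ny, nz); z is the periodic axis.
    dx : float
        Lattice spacing in micrometres (default 0.5).
    tau : float
        BGK relaxation time in lattice units; must exceed 1/2.
    nu_phys : float
        Plasma kinematic viscosity in m^2/s (default 1.2e-6).
    rho_phys : float
        Plasma mass density in kg/m^3 (default 1025).
    re : float
        Target tube Reynolds number u_max D / nu (default 0.025).
    """

    shape: tuple[int, int, int]
    dx: float = 0.5
    tau: float = 1.0
    nu_phys: float = 1.2e-6
    rho_phys: float = 1025.0
    re: float = 0.025

    def __post_init__(self) -> None:
        if self.tau <= 0.5:
            raise StabilityError(f"relaxation time tau={self.tau} must exceed 1/2")
        if self.dx <= 0:
            raise InvalidStateError("lattice spacing must be positive")

    # -- lattice quantities ------------------------------------------------
    @property
    def nu_lattice(self) -> float:
        """Kinematic viscosity in lattice units, c_s^2 (tau - 1/2)."""
        return D3Q19.cs2 * (self.tau - 0.5)

    @property
    def dx_m(self) -> float:
        return self.dx * 1e-6

    @property
    def dt(self) -> float:
        """Physical timestep in seconds (diffusive scaling)."""
        return self.nu_lattice * self.dx_m**2 / self.nu_phys

    # -- unit conversions --------------------------------------------------
    @property
    def velocity_scale(self) -> float:
        """Physical velocity (m/s) of one lattice unit of velocity."""
        return self.dx_m / self.dt

    @property
    def force_scale(self) -> float:
        """Physical force (N) of one lattice unit of force."""
        return self.rho_phys * self.dx_m**4 / self.dt**2

    @property
    def stress_scale(self) -> float:
        """Physical stress (Pa) of one lattice unit of stress."""
        return self.rho_phys * self.dx_m**2 / self.dt**2

    @property
    def mu_phys(self) -> float:
        """Dynamic viscosity of the plasma in Pa s."""
        return self.rho_phys * self.nu_phys

    def force_pn_to_lattice(self, f_pn):
        return np.asarray(f_pn) * 1e-12 / self.force_scale

    def velocity_lattice_to_phys(self, u_lat):
        return np.asarray(u_lat) * self.velocity_scale

    def metadata(self) -> dict:
        return {
            "shape": list(self.shape),
            "dx_um": self.dx,
            "dt_s": self.dt,
            "tau": self.tau,
            "nu_phys_m2_s": self.nu_phys,
            "nu_lattice": self.nu_lattice,
            "rho_phys_kg_m3": self.rho_phys,
            "re": self.re,
        }


class FluidField:
    """D3Q19 populations plus node flags on an (nx, ny, nz) lattice.

    Attributes
    ----------
    f : ndarray, shape (19, nx, ny, nz)
        Populations.
    flags : ndarray of uint8, shape (nx, ny, nz)
        FLUID / WALL / EXTERIOR per node.
    """

    def __init__(self, shape: tuple[int, int, int], flags: np.ndarray | None = None):
        self.shape = tuple(shape)
        self.f = np.zeros((D3Q19.q, *self.shape))
        if flags is None:
            flags = np.full(self.shape, FLUID, dtype=np.uint8)
        self.flags = np.ascontiguousarray(flags, dtype=np.uint8)
        self._bb_links: list[tuple[np.ndarray, np.ndarray]] | None = None

    # ------------------------------------------------------------------
    @property
    def fluid_mask(self) -> np.ndarray:
        return self.flags == FLUID

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Density and velocity at every node (garbage at non-fluid nodes)."""
        return compute_moments(self.f, check=False)

    def total_mass(self) -> float:
        return float(self.f[:, self.fluid_mask].sum())

    def set_equilibrium(self, rho, u) -> "FluidField":
        """Initialize fluid-node populations to equilibrium of (rho, u)."""
        rho = np.broadcast_to(np.asarray(rho, dtype=float), self.shape)
        u = np.broadcast_to(np.asarray(u, dtype=float), (3, *self.shape))
        self.f = equilibrium_distribution(rho, u)
        self.f[:, ~self.fluid_mask] = 0.0
        return self

    def copy(self) -> "FluidField":
        out = FluidField(self.shape, self.flags.copy())
        out.f = self.f.copy()
        return out

    # -- cached halfway bounce-back link table --------------------------
    def bounce_links(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-direction flat indices (fluid node, adjacent wall node)."""
        if self._bb_links is None:
            links = []
            flat_flags = self.flags.reshape(-1)
            n = np.prod(self.shape)
            idx = np.arange(n).reshape(self.shape)
            for i in range(D3Q19.q):
                ex, ey, ez = D3Q19.e[i]
                if ex == 0 and ey == 0 and ez == 0:
                    links.append((np.empty(0, np.int64), np.empty(0, np.int64)))
                    continue
                nbr = np.roll(idx, shift=(-ex, -ey, -ez), axis=(0, 1, 2)).reshape(-1)
                src = np.where((flat_flags == FLUID) & (flat_flags[nbr] == WALL))[0]
                links.append((src, nbr[src]))
            self._bb_links = links
        return self._bb_links


# ---------------------------------------------------------------------------
# Reference operations (numpy)
# ---------------------------------------------------------------------------

def equilibrium_distribution(rho, u, vs: VelocitySet = D3Q19) -> np.ndarray:
    """Second-order low-Mach equilibrium populations.

    Parameters
    ----------
    rho : scalar or ndarray (...,)
    u : ndarray (3, ...) or (..., 3) for a single point (3,)

    Returns
    -------
    ndarray, shape (19, ...) matching rho's shape.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise InvalidStateError("density must be positive")
    if u.shape[0] != 3:
        u = np.moveaxis(u, -1, 0)
    eu = np.tensordot(vs.e.astype(float), u, axes=(1, 0))  # (19, ...)
    usq = (u * u).sum(axis=0)
    w = vs.w.reshape((vs.q,) + (1,) * rho.ndim)
    return w * rho * (1.0 + 3.0 * eu + 4.5 * eu**2 - 1.5 * usq)


def compute_moments(f, vs: VelocitySet = D3Q19, check: bool = True):
    """Density ``rho = sum_i f_i`` and velocity ``u = sum_i f_i e_i / rho``."""
    f = np.asarray(f, dtype=float)
    rho = f.sum(axis=0)
    if check and np.any(rho <= 0):
        raise InvalidStateError("non-positive density encountered")
    mom = np.tensordot(vs.e.astype(float).T, f, axes=(1, 0))  # (3, ...)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(rho != 0, mom / rho, 0.0)
    return rho, u


def bgk_collide(field: FluidField, tau: float, force: np.ndarray | None = None) -> FluidField:
    """BGK relaxation ``f_i <- f_i + (f_i^eq - f_i)/tau`` at fluid nodes.

    ``force`` is an optional lattice force-density field of shape
    (3, nx, ny, nz); it contributes the first-order forcing term
    ``3 w_i (e_i . F)`` which adds exactly F of momentum per step.
    """
    if tau <= 0.5:
        raise StabilityError(f"tau={tau} must exceed 1/2")
    mask = field.fluid_mask
    f = field.f[:, mask]
    rho, u = compute_moments(f)
    feq = equilibrium_distribution(rho, u)
    f += (feq - f) / tau
    if force is not None:
        fm = np.asarray(force)[:, mask]
        f += 3.0 * D3Q19.w[:, None] * (D3Q19.e.astype(float) @ fm)
    field.f[:, mask] = f
    return field


def apply_body_force(field: FluidField, g, rho: np.ndarray | None = None) -> FluidField:
    """Add a uniform acceleration ``g`` (lattice units) to the fluid.

    Injects momentum ``rho g`` per node via the first-order forcing term.
    Used to sustain Poiseuille flow in the periodic vessel.
    """
    g = np.asarray(g, dtype=float)
    if np.all(g == 0):
        return field
    mask = field.fluid_mask
    f = field.f[:, mask]
    if rho is None:
        rho = f.sum(axis=0)
    eg = D3Q19.e.astype(float) @ g  # (19,)
    f += 3.0 * D3Q19.w[:, None] * eg[:, None] * rho
    field.f[:, mask] = f
    return field


def stream_periodic(field: FluidField) -> FluidField:
    """Propagate each population one lattice link, wrapping all axes."""
    f = field.f
    for i in range(1, D3Q19.q):
        ex, ey, ez = D3Q19.e[i]
        f[i] = np.roll(f[i], shift=(ex, ey, ez), axis=(0, 1, 2))
    return field


def bounce_back_walls(field: FluidField) -> FluidField:
    """Halfway bounce-back after streaming.

    Populations that streamed into wall nodes are returned to the fluid node
    they came from, in the opposite direction.  Wall/exterior populations are
    then cleared so stale values never re-enter the fluid.
    """
    links = field.bounce_links()
    flat = field.f.reshape(D3Q19.q, -1)
    # gather all reflections before scattering (directions are independent
    # because each (i, fluid-node) target slot is unique)
    for i in range(1, D3Q19.q):
        src, wall = links[i]
        if src.size:
            flat[D3Q19.opposite[i], src] = flat[i, wall]
    nonfluid = (field.flags != FLUID).reshape(-1)
    flat[:, nonfluid] = 0.0
    return field


def fluid_step(
    field: FluidField,
    tau: float,
    force: np.ndarray | None = None,
    body_accel=None,
) -> FluidField:
    """One reference collide -> stream -> bounce-back update."""
    if body_accel is not None:
        g = np.asarray(body_accel, dtype=float)
        mask = field.fluid_mask
        rho = field.f[:, mask].sum(axis=0)
        dens_force = np.zeros((3, *field.shape))
        dens_force[:, mask] = g[:, None] * rho
        force = dens_force if force is None else force + dens_force
    bgk_collide(field, tau, force=force)
    stream_periodic(field)
    bounce_back_walls(field)
    return field


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def poiseuille_umax_lattice(config: LatticeConfig, diameter_nodes: float) -> float:
    """Centreline lattice velocity for the target Reynolds number."""
    return config.re * config.nu_lattice / diameter_nodes


def initialize_poiseuille(config: LatticeConfig, geom) -> FluidField:
    """Equilibrium populations of the analytic Poiseuille profile.

    ``geom`` is a :class:`ctcsim.scenario_geometry.VesselGeometry`; the
    profile is ``u_z(r) = u_max (1 - (r/R)^2)`` with ``u_max`` chosen so the
    tube Reynolds number ``u_max D / nu`` matches ``config.re``.
    """
    from .scenario_geometry import build_vessel

    vessel = build_vessel(geom)
    radius_nodes = geom.diameter / geom.dx / 2.0
    u_max = poiseuille_umax_lattice(config, 2.0 * radius_nodes)
    if u_max > MAX_LATTICE_SPEED:
        raise StabilityError(
            f"Re={config.re} implies lattice u_max={u_max:.3g} > {MAX_LATTICE_SPEED}; "
            "increase tau or refine the timestep"
        )
    field = FluidField(vessel.flags.shape, vessel.flags)
    x, y, _ = vessel.node_coordinates()
    r2 = (x - vessel.axis_xy[0]) ** 2 + (y - vessel.axis_xy[1]) ** 2
    uz = u_max * np.clip(1.0 - r2 / radius_nodes**2, 0.0, None)
    u = np.zeros((3, *field.shape))
    u[2] = uz
    field.set_equilibrium(1.0, u)
    return field
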