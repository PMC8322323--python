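"""Quantitative observables: deformation, arrest, wall shear stress, vorticity.

The cell deformation measure is Taylor's aspect ratio
``sigma = (L - B) / (L + B)`` where L and B are the major and minor axes of
the ellipsoid with the same second moments as the membrane vertex cloud;
it is 0 for a perfect sphere and grows with elongation.  Because the
vertices sample the membrane *surface*, the shell calibration
``semi-axis = sqrt(3 lambda)`` (exact for a spherical shell) maps the
covariance eigenvalues ``lambda`` to axes, so an undeformed sphere mesh
returns its true diameter; the ratio is insensitive to this factor.

Firm adhesion (arrest) is detected from the unwrapped axial centroid
trajectory: the earliest time after which the axial displacement within
every subsequent time window stays below a tolerance.

Wall shear stress is the tangential viscous traction on the vessel wall,
estimated per wall surface element by a one-sided finite difference of the
tangential velocity along the inward wall normal (the wall itself is
no-slip), in pascals.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DegenerateGeometryError, ParameterError

__all__ = [
    "TrajectoryRecord",
    "WSSField",
    "inertia_ellipsoid_axes",
    "taylor_aspect_ratio",
    "detect_firm_adhesion",
    "wall_shear_stress",
    "elevated_wss_area",
    "vorticity_field",
    "membrane_force_summary",
]


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def inertia_ellipsoid_axes(mesh_or_points) -> tuple[float, float]:
    """Full major/minor axes (L, B) of the moment-equivalent ellipsoid.

    Accepts a CellMesh or an (n, 3) point cloud.  Second moments are taken
    about the centroid with uniform vertex weights; eigenvalues map to
    semi-axes with the thin-shell factor sqrt(3).
    """
    pts = getattr(mesh_or_points, "vertices", mesh_or_points)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points in 3-D")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1e-30):
        raise DegenerateGeometryError("degenerate (rank < 3) vertex cloud")
    semi = np.sqrt(3.0 * evals)
    return float(2.0 * semi[-1]), float(2.0 * semi[0])


def taylor_aspect_ratio(major: float, minor: float) -> float:
    """Taylor deformation parameter (L - B)/(L + B); 0 for a sphere."""
    if minor <= 0 or major < minor:
        raise ParameterError("axes must satisfy L >= B > 0")
    return (major - minor) / (major + minor)


# ---------------------------------------------------------------------------
# Trajectory / arrest
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Per-output-step time series for one cell."""

    time: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    centroid: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 3)))  # um, z unwrapped
    velocity: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 3)))  # um/s
    aspect_ratio: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    max_nodal_force: np.ndarray = dc_field(default_factory=lambda: np.empty(0))  # pN
    force_integral: np.ndarray = dc_field(default_factory=lambda: np.empty(0))  # pN-scale sum
    bond_count: np.ndarray = dc_field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.time,
                "x_um": self.centroid[:, 0],
                "y_um": self.centroid[:, 1],
                "z_um": self.centroid[:, 2],
                "vx_um_s": self.velocity[:, 0],
                "vy_um_s": self.velocity[:, 1],
                "vz_um_s": self.velocity[:, 2],
                "aspect_ratio": self.aspect_ratio,
                "max_nodal_force_pN": self.max_nodal_force,
                "force_integral_pN": self.force_integral,
                "bond_count": self.bond_count,
            }
        )

    @classmethod
    def from_dataframe(cls, df) -> "TrajectoryRecord":
        return cls(
            time=df["t_s"].to_numpy(),
            centroid=df[["x_um", "y_um", "z_um"]].to_numpy(),
            velocity=df[["vx_um_s", "vy_um_s", "vz_um_s"]].to_numpy(),
            aspect_ratio=df["aspect_ratio"].to_numpy(),
            max_nodal_force=df["max_nodal_force_pN"].to_numpy(),
            force_integral=df["force_integral_pN"].to_numpy(),
            bond_count=df["bond_count"].to_numpy(),
        )


def detect_firm_adhesion(
    traj: TrajectoryRecord, window: float, displacement_tol: float = 5.0
) -> float | None:
    """Earliest time after which the cell stays put (firm adhesion).

    Scans the unwrapped axial centroid trajectory for the earliest sample
    time t* such that within every window ``[t, t + window]`` with
    ``t >= t*`` the axial position range stays below ``displacement_tol``
    (um).  Returns None if the trajectory never settles.
    """
    t = np.asarray(traj.time, dtype=float)
    if len(t) < 2:
        return None
    if window >= t[-1] - t[0]:
        raise ParameterError("window must be shorter than the trajectory")
    z = np.asarray(traj.centroid[:, 2], dtype=float)
    # only starts whose window fits in the trajectory carry evidence; later
    # partial windows are sub-intervals of the last full one
    n_eval = int(np.searchsorted(t, t[-1] - window, side="right"))
    if n_eval == 0:
        return None
    ends = np.searchsorted(t, t[:n_eval] + window, side="right")
    ok = np.empty(n_eval, dtype=bool)
    for i in range(n_eval):
        seg = z[i : max(ends[i], i + 1)]
        ok[i] = (seg.max() - seg.min()) < displacement_tol
    quiet_from = n_eval
    for i in range(n_eval - 1, -1, -1):
        if ok[i]:
            quiet_from = i
        else:
            break
    if quiet_from == n_eval:
        return None
    return float(t[quiet_from])


# ---------------------------------------------------------------------------
# Wall shear stress and vorticity
# ---------------------------------------------------------------------------

@dataclass
class WSSField:
    """Per-wall-element shear stress (Pa) and element area (um^2)."""

    stress: np.ndarray
    area: np.ndarray
    positions: np.ndarray = None  # (n, 3) lattice coords of the sampling nodes

    def max(self) -> float:
        return float(self.stress.max()) if len(self.stress) else 0.0

    def total_force(self) -> float:
        """Integral of WSS over the wall, Pa um^2 (1 Pa um^2 = 1 pN)."""
        return float((self.stress * self.area).sum())


def wall_shear_stress(field, vessel, config, method: str = "one_sided") -> WSSField:
    """Tangential viscous traction on the cylindrical vessel wall.

    The wall is sampled at the ligand-site lattice (uniform elements on the
    analytic surface, element area = site spacing squared).  At each site
    the tangential velocity is interpolated at one and two lattice spacings
    along the inward wall normal and the wall-normal gradient is evaluated
    with the second-order one-sided difference that uses the no-slip zero
    at the surface:

        du_t/dr |_wall ~= (4 u_t(h) - u_t(2h)) / (2h)

    times the dynamic viscosity mu, reported in pascals.  ``method`` is
    kept for config switching; only the velocity-gradient estimator is
    implemented.

    Parameters
    ----------
    field : FluidField
    vessel : Vessel (from scenario_geometry.build_vessel)
    config : LatticeConfig (unit conversions)
    """
    from .immersed_boundary import interpolate_velocity

    if method != "one_sided":
        raise ParameterError(f"unknown WSS method {method!r}")
    _, u = field.moments()
    u = np.where(field.fluid_mask[None], u, 0.0)
    sites = vessel.wall_sites  # lattice units, on r = R
    ax, ay = vessel.axis_xy
    radial = sites.copy()
    radial[:, 0] -= ax
    radial[:, 1] -= ay
    radial[:, 2] = 0.0
    nhat = radial / np.linalg.norm(radial, axis=1)[:, None]  # outward
    u1 = interpolate_velocity(sites - 1.0 * nhat, u)
    u2 = interpolate_velocity(sites - 2.0 * nhat, u)

    def tangential(vec):
        return vec - (np.einsum("ij,ij->i", vec, nhat))[:, None] * nhat

    du_lat = (4.0 * tangential(u1) - tangential(u2)) / 2.0  # per lattice unit
    stress_pa = config.mu_phys * np.linalg.norm(du_lat, axis=1) / config.dt
    area = np.full(len(sites), vessel.geom.wall_site_spacing**2)
    return WSSField(stress=stress_pa, area=area, positions=sites)


def elevated_wss_area(wss: WSSField, threshold: float) -> float:
    """Total wall area (um^2) with stress above the threshold (Pa)."""
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    return float(wss.area[wss.stress > threshold].sum())


def vorticity_field(field, config=None) -> np.ndarray:
    """Central-difference curl of the velocity, shape (3, nx, ny, nz).

    Wall and exterior nodes carry zero velocity (no slip), which makes the
    differences one-sided in effect at the staircase boundary.  With a
    LatticeConfig the result is in physical 1/s; otherwise lattice units.
    """
    _, u = field.moments()
    u = np.where(field.fluid_mask[None], u, 0.0)
    dudx = [np.gradient(u[c], axis=a) for c in range(3) for a in range(3)]

    def d(c, a):
        return dudx[3 * c + a]

    curl = np.stack([d(2, 1) - d(1, 2), d(0, 2) - d(2, 0), d(1, 0) - d(0, 1)])
    if config is not None:
        curl = curl / config.dt  # lattice gradient (per node) -> 1/s
    return curl


# ---------------------------------------------------------------------------
# Membrane force summaries
# ---------------------------------------------------------------------------

def membrane_force_summary(mesh, vertex_forces) -> tuple[float, float]:
    """(max nodal force pN, node-weighted surface integral of |F| in nN).

    The integral weights each vertex magnitude by its share of the surface
    (one third of incident triangle areas, normalized), times the vertex
    count -- i.e. an area-corrected sum over nodes, reported in nN.
    """
    f = np.asarray(vertex_forces, dtype=float)
    if len(f) != mesh.n_vertices:
        raise ParameterError("force array does not match mesh vertex count")
    mag = np.linalg.norm(f, axis=1)
    weights = mesh.vertex_areas() / mesh.total_area() * mesh.n_vertices
    return float(mag.max(initial=0.0)), float((mag * weights).sum() / 1e3)
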