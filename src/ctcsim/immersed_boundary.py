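"""Immersed-boundary coupling between Lagrangian vertices and the lattice.

The membrane vertices do not coincide with lattice nodes, so forces and
velocities are exchanged through a discrete delta kernel.  The kernel is the
compact 2-point tent function

    phi(r) = 1 - |r|   for |r| <= 1,   0 otherwise

with the 3-D product form ``delta(r) = phi(x) phi(y) phi(z)``.  The tent
kernel is an exact partition of unity over the two bracketing integers of
any coordinate, which makes force spreading exactly conservative and makes
velocity interpolation reproduce constant and linear fields exactly.

All positions and velocities here are in lattice units; the axial (z)
coordinate is periodic.  Spreading and interpolation use the same weights,
so the two operators are exact adjoints of one another.
"""

from __future__ import annotations

import numpy as np

from .errors import CFLViolationError, OutOfDomainError

__all__ = [
    "kernel_phi",
    "compute_stencil",
    "spread_forces",
    "spread_with_stencil",
    "interpolate_velocity",
    "interpolate_with_stencil",
    "advect_vertices",
]


def kernel_phi(r):
    """1-D tent kernel: 1 - |r| inside the unit support, 0 outside."""
    r = np.abs(np.asarray(r, dtype=float))
    return np.where(r <= 1.0, 1.0 - r, 0.0)


def _stencil(vertices, shape):
    """8-node stencil indices and tent weights for each vertex.

    Returns (idx, weights): idx is (n, 8, 3) int node indices (z wrapped),
    weights is (n, 8) with rows summing to 1.
    """
    pos = np.asarray(vertices, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise OutOfDomainError("vertex array must have shape (n, 3)")
    nx, ny, nz = shape
    base = np.floor(pos).astype(np.int64)  # (n, 3)
    frac = pos - base
    if np.any(base[:, 0] < 0) or np.any(base[:, 0] + 1 >= nx) or np.any(
        base[:, 1] < 0
    ) or np.any(base[:, 1] + 1 >= ny):
        bad = np.where(
            (base[:, 0] < 0) | (base[:, 0] + 1 >= nx) | (base[:, 1] < 0) | (base[:, 1] + 1 >= ny)
        )[0][0]
        raise OutOfDomainError(f"vertex {bad} at {pos[bad]} outside the lattice cross-section")
    offs = np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
    )  # (8, 3)
    idx = base[:, None, :] + offs[None, :, :]
    idx[:, :, 2] %= nz  # axial wrap
    w1d = np.where(offs[None, :, :] == 0, 1.0 - frac[:, None, :], frac[:, None, :])
    weights = w1d.prod(axis=2)
    return idx, weights


def compute_stencil(vertices, shape):
    """Precompute the 8-node stencil (flat indices, weights) for reuse.

    Spreading and interpolation at the same vertex positions share one
    stencil; this is also what makes the two operators exact adjoints.
    """
    idx, w = _stencil(vertices, shape)
    flat = np.ravel_multi_index((idx[:, :, 0], idx[:, :, 1], idx[:, :, 2]), shape)
    return flat, w


def spread_with_stencil(stencil, vertex_forces, target) -> np.ndarray:
    flat, w = stencil
    forces = np.asarray(vertex_forces, dtype=float)
    for ax in range(3):
        np.add.at(
            target[ax].reshape(-1), flat.reshape(-1), (w * forces[:, ax : ax + 1]).reshape(-1)
        )
    return target


def interpolate_with_stencil(stencil, u_field) -> np.ndarray:
    flat, w = stencil
    out = np.empty((len(w), 3))
    for ax in range(3):
        out[:, ax] = (u_field[ax].reshape(-1)[flat] * w).sum(axis=1)
    return out


def spread_forces(vertices, vertex_forces, target, shape=None) -> np.ndarray:
    """Deposit Lagrangian forces onto the lattice: f(X) = sum_i F_i delta(X - x_i).

    Parameters
    ----------
    vertices : (n, 3) lattice-unit positions
    vertex_forces : (n, 3) lattice-unit forces
    target : ndarray (3, nx, ny, nz) accumulated in place, or None
    shape : lattice shape, required when target is None

    The total deposited force equals the total Lagrangian force exactly
    (partition of unity).
    """
    if target is None:
        target = np.zeros((3, *shape))
    return spread_with_stencil(
        compute_stencil(vertices, target.shape[1:]), vertex_forces, target
    )


def interpolate_velocity(vertices, u_field) -> np.ndarray:
    """Sample the lattice velocity at each vertex with the tent kernel."""
    u_field = np.asarray(u_field)
    return interpolate_with_stencil(compute_stencil(vertices, u_field.shape[1:]), u_field)


def advect_vertices(vertices, vertex_velocities, dt: float = 1.0, nz: int | None = None):
    """Explicit Euler update x <- x + u dt with axial periodic wrap.

    Returns (new_vertices, wrap_increments) where wrap_increments counts the
    +-1 axial wraps applied to each vertex (used to keep unwrapped centroid
    trajectories for the arrest metrics).
    """
    if dt <= 0:
        raise CFLViolationError("timestep must be positive")
    v = np.asarray(vertex_velocities, dtype=float)
    disp = v * dt
    maxdisp = float(np.abs(disp).max()) if disp.size else 0.0
    if maxdisp > 0.5:
        raise CFLViolationError(
            f"vertex displacement {maxdisp:.3g} lattice units exceeds 0.5 in one step"
        )
    out = np.asarray(vertices, dtype=float) + disp
    wraps = np.zeros(len(out), dtype=np.int64)
    if nz is not None:
        wraps = np.floor(out[:, 2] / nz).astype(np.int64)
        out[:, 2] -= wraps * nz
    return out, wraps
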