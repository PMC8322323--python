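"""Numba-compiled fused collide/stream/bounce-back kernel.

Functionally identical to the reference numpy operations in
:mod:`ctcsim.lattice_fluid` (same collision, first-order forcing, halfway
bounce-back, fully periodic wrap); the equivalence is asserted in the test
suite.  Single-threaded and deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .lattice_fluid import D3Q19, FLUID

_E = np.ascontiguousarray(D3Q19.e)
_EF = np.ascontiguousarray(D3Q19.e.astype(np.float64))
_W = np.ascontiguousarray(D3Q19.w)
_OPP = np.ascontiguousarray(D3Q19.opposite)


@njit(cache=True)
def _fused_step(f, fnew, flags, tau, force, gx, gy, gz, e, ef, w, opp):
    q, nx, ny, nz = f.shape
    fnew[:] = 0.0
    inv_tau = 1.0 / tau
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if flags[x, y, z] != FLUID:
                    continue
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(q):
                    fi = f[i, x, y, z]
                    rho += fi
                    mx += fi * ef[i, 0]
                    my += fi * ef[i, 1]
                    mz += fi * ef[i, 2]
                ux = mx / rho
                uy = my / rho
                uz = mz / rho
                usq = ux * ux + uy * uy + uz * uz
                fx = force[0, x, y, z] + gx * rho
                fy = force[1, x, y, z] + gy * rho
                fz = force[2, x, y, z] + gz * rho
                for i in range(q):
                    eu = ef[i, 0] * ux + ef[i, 1] * uy + ef[i, 2] * uz
                    feq = w[i] * rho * (1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq)
                    ForceTerm = 3.0 * w[i] * (ef[i, 0] * fx + ef[i, 1] * fy + ef[i, 2] * fz)
                    fpost = f[i, x, y, z] + inv_tau * (feq - f[i, x, y, z]) + ForceTerm
                    tx = x + e[i, 0]
                    ty = y + e[i, 1]
                    tz = z + e[i, 2]
                    if tx == nx:
                        tx = 0
                    elif tx < 0:
                        tx = nx - 1
                    if ty == ny:
                        ty = 0
                    elif ty < 0:
                        ty = ny - 1
                    if tz == nz:
                        tz = 0
                    elif tz < 0:
                        tz = nz - 1
                    if flags[tx, ty, tz] == FLUID:
                        fnew[i, tx, ty, tz] = fpost
                    else:
                        fnew[opp[i], x, y, z] = fpost


def fused_fluid_step(field, tau: float, force=None, body_accel=None, buffer=None):
    """One collide/stream/bounce-back step via the compiled kernel.

    ``force`` is a (3, nx, ny, nz) lattice force-density field (or None);
    ``body_accel`` a uniform acceleration 3-vector.  Returns the field with
    its population array swapped against ``buffer`` (allocated on demand).
    """
    if force is None:
        force = np.zeros((3, *field.shape))
    g = (0.0, 0.0, 0.0) if body_accel is None else tuple(float(c) for c in body_accel)
    if buffer is None:
        buffer = np.empty_like(field.f)
    _fused_step(field.f, buffer, field.flags, float(tau), force, g[0], g[1], g[2],
                _E, _EF, _W, _OPP)
    field.f, buffer = buffer, field.f
    return field, buffer
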