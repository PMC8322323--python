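"""Receptor-ligand adhesive dynamics with the effective-force scheme.

Bonds between adhesion molecules (mesh vertices on cells, generated ligand
sites on the vessel wall) follow distance-dependent Dembo kinetics:

    k_f = k_f0 exp[- sigma_ts (l - l0)^2 / (2 kB T)]
    k_r = k_r0 exp[+(sigma_b - sigma_ts) (l - l0)^2 / (2 kB T)]

so that ``sigma_b > sigma_ts`` gives a slip bond whose rupture rate grows
with stretch.  Over a short probability interval ``dt`` the formation and
rupture probabilities are ``P = 1 - exp(-k dt)``.

The classical reference scheme (Hammer & Apte) draws discrete formation and
rupture events from these probabilities and lets surviving bonds exert the
full Hookean force ``F_bond = sigma_b (l - l0) e_hat``.  The deterministic
*effective-force* scheme instead lets every candidate pair continuously
exert

    F_eff = P_f (1 - P_r) F_bond

which equals the expected per-interval bond force of the stochastic
reference when each interval is treated independently (quasi-static
probabilities); the equivalence is verified statistically in the tests.

Positions are micrometres; spring constants N/m; forces are returned in pN.
The thermal energy defaults to kB * 310 K but is configurable: coarse-
grained runs use a larger effective value so that the Boltzmann interaction
range sqrt(2 kB T / sigma) matches the mesh discretization scale instead of
the nanometre scale of a single molecular bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DegenerateGeometryError, ParameterError

__all__ = [
    "BOLTZMANN_K",
    "AdhesionParams",
    "BondEndpoint",
    "Bond",
    "BondRegistry",
    "forward_rate",
    "reverse_rate",
    "formation_probability",
    "rupture_probability",
    "effective_probability",
    "bond_force",
    "bond_force_vectors",
    "effective_force",
    "find_candidate_pairs",
    "candidate_pairs",
    "update_bonds",
]

BOLTZMANN_K = 1.380649e-23  # J/K

_UM = 1e-6  # metres per micrometre
_PN = 1e12  # pN per newton


@dataclass
class AdhesionParams:
    """Kinetic and mechanical constants of the receptor-ligand model.

    Attributes
    ----------
    kf0, kr0 : float
        Unstressed forward / reverse rates, 1/s.
    sigma_ts : float
        Transition-state spring constant, N/m ("small": formation stays
        possible at considerable separation).
    sigma_b : float
        Bonded-state spring constant, N/m; must exceed sigma_ts (slip bond).
    l0 : float
        Equilibrium bond length, um.
    temperature : float
        Absolute temperature, K (used when thermal_energy is None).
    thermal_energy : float or None
        Override for kB*T in joules; coarse-grained runs set this so the
        Boltzmann range matches the discretization scale.
    dt_prob : float
        Probability interval, s (default 0.1 us).
    cutoff : float
        Candidate-pair search radius, um.
    max_bonds_per_vertex : int
        Cap on simultaneous bonds per adhesion site.
    break_stretch_ratio : float
        Pairs with l > ratio * l0 are dropped in effective-force mode
        (numerical guard; P_eff is negligible there for slip bonds).
    """

    kf0: float = 1000.0
    kr0: float = 1.0
    sigma_ts: float = 5e-7
    sigma_b: float = 5e-6
    l0: float = 0.25
    temperature: float = 310.0
    thermal_energy: float | None = None
    dt_prob: float = 1e-7
    cutoff: float = 0.75
    max_bonds_per_vertex: int = 16
    break_stretch_ratio: float = 3.0

    def __post_init__(self) -> None:
        if min(self.kf0, self.kr0, self.sigma_ts, self.sigma_b) < 0:
            raise ParameterError("rates and spring constants must be non-negative")
        if self.sigma_b <= self.sigma_ts:
            raise ParameterError("slip-bond regime requires sigma_b > sigma_ts")
        if self.dt_prob <= 0:
            raise ParameterError("probability interval must be positive")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in joules."""
        if self.thermal_energy is not None:
            return self.thermal_energy
        return BOLTZMANN_K * self.temperature


@dataclass(frozen=True)
class BondEndpoint:
    """One end of a bond: (cell_id, vertex_id); cell_id = -1 is a wall site."""

    cell_id: int
    vertex_id: int

    @property
    def is_wall(self) -> bool:
        return self.cell_id < 0


@dataclass
class Bond:
    """A single receptor-ligand bond with its kinetic state (diagnostics)."""

    a: BondEndpoint
    b: BondEndpoint
    length: float = 0.0  # um
    direction: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    kf: float = 0.0
    kr: float = 0.0
    pf: float = 0.0
    pr: float = 0.0
    peff: float = 0.0
    f_bond: float = 0.0  # pN
    f_eff: float = 0.0  # pN


# ---------------------------------------------------------------------------
# Closed-form kinetics
# ---------------------------------------------------------------------------

def forward_rate(l, params: AdhesionParams):
    """Dembo forward rate at bond length l (um)."""
    dl = (np.asarray(l, dtype=float) - params.l0) * _UM
    return params.kf0 * np.exp(-params.sigma_ts * dl**2 / (2.0 * params.kbt))


def reverse_rate(l, params: AdhesionParams):
    """Dembo reverse (slip) rate at bond length l (um)."""
    dl = (np.asarray(l, dtype=float) - params.l0) * _UM
    arg = (params.sigma_b - params.sigma_ts) * dl**2 / (2.0 * params.kbt)
    return params.kr0 * np.exp(np.minimum(arg, 700.0))


def formation_probability(kf, dt):
    return -np.expm1(-np.asarray(kf, dtype=float) * dt)


def rupture_probability(kr, dt):
    return -np.expm1(-np.asarray(kr, dtype=float) * dt)


def effective_probability(pf, pr):
    """P_eff = P_f (1 - P_r)."""
    return np.asarray(pf, dtype=float) * (1.0 - np.asarray(pr, dtype=float))


def bond_force_vectors(pa, pb, params: AdhesionParams):
    """Hookean bond force on endpoint A for each (pa, pb) pair (pN).

    The force on A points toward B when the bond is stretched and away when
    compressed; B receives the opposite force.
    """
    pa = np.atleast_2d(np.asarray(pa, dtype=float))
    pb = np.atleast_2d(np.asarray(pb, dtype=float))
    d = pb - pa
    l = np.linalg.norm(d, axis=1)
    if np.any(l == 0):
        raise DegenerateGeometryError("coincident bond endpoints: direction undefined")
    ehat = d / l[:, None]
    fmag = params.sigma_b * (l - params.l0) * _UM * _PN  # pN
    return fmag[:, None] * ehat, l, ehat


def bond_force(bond: Bond, pa, pb, params: AdhesionParams):
    """Force on each endpoint of a single bond: (F_a, F_b), pN."""
    fa, l, ehat = bond_force_vectors(pa, pb, params)
    bond.length = float(l[0])
    bond.direction = ehat[0]
    bond.f_bond = float(params.sigma_b * (l[0] - params.l0) * _UM * _PN)
    return fa[0], -fa[0]


def effective_force(bond: Bond, pa, pb, params: AdhesionParams):
    """F_eff = P_eff * F_bond for a single bond: (F_a, F_b), pN."""
    fa, fb = bond_force(bond, pa, pb, params)
    bond.kf = float(forward_rate(bond.length, params))
    bond.kr = float(reverse_rate(bond.length, params))
    bond.pf = float(formation_probability(bond.kf, params.dt_prob))
    bond.pr = float(rupture_probability(bond.kr, params.dt_prob))
    bond.peff = float(effective_probability(bond.pf, bond.pr))
    bond.f_eff = bond.peff * bond.f_bond
    return bond.peff * fa, bond.peff * fb


# ---------------------------------------------------------------------------
# Candidate search
# ---------------------------------------------------------------------------

def candidate_pairs(
    points_a,
    points_b,
    cutoff: float,
    period_z: float | None = None,
    max_per_a: int | None = None,
    max_per_b: int | None = None,
) -> np.ndarray:
    """Index pairs (i, j) with |points_a[i] - points_b[j]| <= cutoff.

    Distances respect minimum-image wrapping along z when ``period_z`` is
    given.  Per-point caps keep only the nearest partners, deterministically.
    Returns an (n, 2) int array.
    """
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if pa.size == 0 or pb.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if period_z is not None:
        allp = np.vstack([pa, pb]).copy()
        allp[:, 2] %= period_z
        shift = allp[:, :2].min(axis=0) - 2.0 * cutoff
        allp[:, :2] -= shift
        span = allp[:, :2].max(axis=0) + 2.0 * cutoff
        box = [float(span[0]), float(span[1]), float(period_z)]
        qa, qb = allp[: len(pa)], allp[len(pa):]
        tree = cKDTree(qb, boxsize=box)
        neighbours = tree.query_ball_point(qa, r=cutoff)
        dist_fn = lambda i, js: _min_image_dist(qa[i], qb[js], period_z)
    else:
        tree = cKDTree(pb)
        neighbours = tree.query_ball_point(pa, r=cutoff)
        dist_fn = lambda i, js: np.linalg.norm(pb[js] - pa[i], axis=1)
    out_i, out_j, out_d = [], [], []
    for i, js in enumerate(neighbours):
        if not js:
            continue
        js = np.asarray(js, dtype=np.int64)
        d = dist_fn(i, js)
        order = np.argsort(d, kind="stable")
        if max_per_a is not None:
            order = order[:max_per_a]
        out_i.append(np.full(len(order), i, dtype=np.int64))
        out_j.append(js[order])
        out_d.append(d[order])
    if not out_i:
        return np.empty((0, 2), dtype=np.int64)
    ii = np.concatenate(out_i)
    jj = np.concatenate(out_j)
    dd = np.concatenate(out_d)
    if max_per_b is not None:
        keep = np.zeros(len(ii), dtype=bool)
        order = np.argsort(dd, kind="stable")
        counts: dict[int, int] = {}
        for k in order:
            c = counts.get(jj[k], 0)
            if c < max_per_b:
                counts[jj[k]] = c + 1
                keep[k] = True
        ii, jj = ii[keep], jj[keep]
    return np.column_stack([ii, jj])


def _min_image_dist(p, qs, period_z):
    d = qs - p
    d[:, 2] -= period_z * np.round(d[:, 2] / period_z)
    return np.linalg.norm(d, axis=1)


def find_candidate_pairs(cells, wall_sites, params: AdhesionParams, period_z=None):
    """Candidate endpoint pairs among cell vertices and wall ligand sites.

    ``cells`` maps cell_id -> (n_i, 3) vertex positions (um); ``wall_sites``
    is an (m, 3) array (um).  Returns a list of
    ``(cell_a, cell_b, pairs)`` tuples where cell id -1 denotes the wall and
    ``pairs`` is an (k, 2) vertex/site index array.  Per-vertex caps are
    enforced on both endpoints; each unordered cell pair appears once.
    """
    ids = sorted(cells)
    cap = params.max_bonds_per_vertex
    out = []
    for idx, ca in enumerate(ids):
        pw = candidate_pairs(
            cells[ca], wall_sites, params.cutoff, period_z=period_z,
            max_per_a=cap, max_per_b=cap,
        )
        if len(pw):
            out.append((ca, -1, pw))
        for cb in ids[idx + 1:]:
            p = candidate_pairs(
                cells[ca], cells[cb], params.cutoff, period_z=period_z,
                max_per_a=cap, max_per_b=cap,
            )
            if len(p):
                out.append((ca, cb, p))
    return out


# ---------------------------------------------------------------------------
# Registry and per-interval update
# ---------------------------------------------------------------------------

class BondRegistry:
    """Active candidate pairs / bonds between two endpoint groups.

    Array-of-pairs layout: ``pairs[k] = (ia, ib)`` indexes into the caller's
    endpoint position arrays.  ``scheme`` selects the deterministic
    effective-force update, the memoryless Monte-Carlo reference, or the
    persistent-bond Monte-Carlo variant (``bound`` carries its state).
    """

    SCHEMES = ("effective_force", "monte_carlo", "monte_carlo_persistent")

    def __init__(self, pairs=None, scheme: str = "effective_force"):
        if scheme not in self.SCHEMES:
            raise ConfigurationError(f"unknown adhesion scheme {scheme!r}")
        self.scheme = scheme
        self.pairs = (
            np.empty((0, 2), dtype=np.int64) if pairs is None else np.asarray(pairs, dtype=np.int64)
        )
        if len(self.pairs) and len(np.unique(self.pairs, axis=0)) != len(self.pairs):
            raise ConfigurationError("duplicate bonds on the same endpoint pair")
        self.bound = np.zeros(len(self.pairs), dtype=bool)

    def __len__(self) -> int:
        return len(self.pairs)

    def set_pairs(self, pairs) -> None:
        pairs = np.asarray(pairs, dtype=np.int64)
        # carry persistent bound-state across registry rebuilds
        if self.scheme == "monte_carlo_persistent" and len(self.pairs):
            old = {tuple(p): b for p, b in zip(self.pairs, self.bound)}
            self.bound = np.array([old.get(tuple(p), False) for p in pairs], dtype=bool)
        else:
            self.bound = np.zeros(len(pairs), dtype=bool)
        self.pairs = pairs


@dataclass
class BondUpdate:
    """Result of one adhesion interval: per-pair state and endpoint forces."""

    lengths: np.ndarray  # um
    pf: np.ndarray
    pr: np.ndarray
    peff: np.ndarray
    force_a: np.ndarray  # (n, 2? no: n,3) pN on the A endpoints (B gets -force_a)
    active: np.ndarray  # bool, pairs contributing force this interval

    @property
    def total_force(self) -> np.ndarray:
        return self.force_a.sum(axis=0)


def update_bonds(
    registry: BondRegistry,
    params: AdhesionParams,
    pos_a,
    pos_b,
    rng: np.random.Generator | None = None,
) -> BondUpdate:
    """One probability interval for all pairs in the registry.

    ``pos_a``/``pos_b`` are the endpoint positions (um) for each pair (the
    caller resolves indices and applies minimum-image wrapping).  In
    effective-force mode every pair contributes ``F_eff`` continuously; in
    the Monte-Carlo modes formation/rupture are drawn from ``rng``.
    """
    n = len(registry)
    if n == 0:
        z = np.empty((0,))
        return BondUpdate(z, z, z, z, np.empty((0, 3)), np.empty(0, dtype=bool))
    if registry.scheme != "effective_force" and rng is None:
        raise ConfigurationError("Monte-Carlo adhesion schemes require an explicit RNG")
    fa, l, _ = bond_force_vectors(pos_a, pos_b, params)
    pf = formation_probability(forward_rate(l, params), params.dt_prob)
    pr = rupture_probability(reverse_rate(l, params), params.dt_prob)
    peff = effective_probability(pf, pr)
    if registry.scheme == "effective_force":
        active = l <= params.break_stretch_ratio * params.l0
        force_a = fa * (peff * active)[:, None]
    elif registry.scheme == "monte_carlo":
        # memoryless reference: each interval draws formation then rupture
        active = (rng.random(n) < pf) & (rng.random(n) >= pr)
        force_a = fa * active[:, None]
    else:  # monte_carlo_persistent
        formed = ~registry.bound & (rng.random(n) < pf)
        broken = registry.bound & (rng.random(n) < pr)
        registry.bound = (registry.bound & ~broken) | formed
        active = registry.bound.copy()
        force_a = fa * active[:, None]
    return BondUpdate(lengths=l, pf=pf, pr=pr, peff=peff, force_a=force_a, active=active)
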