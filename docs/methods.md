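# Methods

`ctcsim` simulates a single circulating tumor cell (CTC), optionally
decorated with platelets and accompanied by red blood cells, moving through
plasma in a straight cylindrical microvessel, and resolves its receptor-
ligand adhesion to the vessel wall.  This note records the model equations,
the numerical choices, the calibrated parameters, and what the reduced
(desk-scale) scenarios can and cannot show.

## Plasma flow

The plasma is an incompressible Newtonian fluid solved with the D3Q19
single-relaxation-time (BGK) lattice-Boltzmann method:

    f_i(x + e_i, t+1) = f_i(x, t) + (1/tau) [f_i^eq(x, t) - f_i(x, t)],
    f_i^eq = w_i rho [1 + 3 (e_i.u) + 9/2 (e_i.u)^2 - 3/2 u^2],
    rho = sum_i f_i,  u = (1/rho) sum_i f_i e_i,

with speed of sound `c_s^2 = 1/3`, kinematic viscosity
`nu = c_s^2 (tau - 1/2)` (lattice units) and equation of state
`p = rho c_s^2`.  Walls are a stair-case voxelization of the cylinder with
halfway bounce-back; the axial direction is periodic.  Flow is initialized
as, and sustained at, a Poiseuille profile with tube Reynolds number
`Re = u_max D / nu = 0.025` by a uniform body force implemented as the
first-order forcing term `3 w_i rho (e_i.g)` (exactly `rho g` momentum per
step; higher-order force corrections are negligible in this Stokes regime).

**Units.** The lattice spacing is `dx = 0.5 um` for single-physics studies
and `1 um` for the coupled desk-scale scenarios.  The timestep follows the
diffusive scaling `dt = c_s^2 (tau - 1/2) dx^2 / nu_phys` with plasma
kinematic viscosity `nu_phys = 1.2e-6 m^2/s` and density 1025 kg/m^3, e.g.
`dt = 3.47e-8 s` at `dx = 0.5 um`, `tau = 1`.  Both are recorded in every
run manifest.

**Wall accuracy convention.**  A stair-case cylinder places the effective
no-slip surface a fraction of a lattice spacing inside the geometric
radius.  Accuracy statements therefore identify the wall with the
*effective* radius obtained from a least-squares parabola fit of the
steady profile; against the Hagen-Poiseuille law at that radius the
profile agrees to well under 3% (relative L2) at 40 nodes across, and the
fitted viscosity matches `c_s^2 (tau - 1/2)` to ~0.4% for
`tau in {0.8, 1.0, 1.2}`.  Against the geometric radius the worst-node
error is 3-4.4%, which is the well-known O(dx) stair-case boundary effect,
not a property of the collision operator.

## Cell membranes

Cells are closed triangulated surfaces (subdivided icospheres; any vertex
count >= 12 is reachable by collapsing shortest edges from the next
subdivision level, e.g. the 1382-vertex tumor-cell and 1148-vertex platelet
resolutions).  Platelets are oblate discs (2 um diameter, aspect 0.5 by
default), red cells biconcave discocytes (Evans-Fung profile, 7.82 um).

Deformation is resisted by four conservative force channels, each the
exact negative gradient of an elastic energy (verified against numerical
differentiation in the tests):

* link (in-plane): per-edge tension `k_link * x / (1 - (x/x_max)^2)` with
  strain `x = l/l0 - 1`; linear for small strain, diverging toward the
  saturation strain `x_max` (finite spectrin extensibility);
* bending: harmonic spring on each edge's dihedral angle;
* area: quadratic penalties on per-triangle and total area;
* volume: quadratic penalty on the enclosed volume.

Being gradients of rigid-motion-invariant energies, all channels are
momentum- and torque-free by construction.

**Calibration.**  The whole-cell stiffness is characterised by a
quasi-static stretch test: opposite total forces are distributed over the
5% of vertices with extreme axial coordinates on each side, and the mesh
is relaxed to equilibrium at each force level (FIRE pseudo-time
relaxation, residual tolerance 0.1-0.5 pN).  The shipped tumor-cell
constants

    k_link = 166 pN, k_bend = 8 pN um, k_area_local = 20 pN/um,
    k_area_global = 20 pN/um, k_volume = 300 pN/um^2, x_max = 2.0

were fitted so that an 8 um, 642-vertex cell reaches Taylor aspect ratio
0.31 at 2000 pN tension.  Within this constitutive family the equal-moment
axis sum L+B at that ratio is ~18.5 um; axis pairs with a larger sum (which
imply ~25% surface growth at nearly unchanged transverse width) are not
reachable without a softer-than-quadratic area response, so the calibration
targets the dimensionless Taylor ratio, the quantity the analyses use.
Stiffness-scale factors (0.7/1.3 for +-30% soft/stiff studies) multiply all
four constants exactly.

**Shape metric.**  `L` and `B` are the extreme full axes of the ellipsoid
with the same second moments as the membrane vertex cloud; since the cloud
samples the surface, eigenvalues map to semi-axes with the thin-shell
factor `sqrt(3 lambda)` (exact for a spherical shell), and the Taylor
ratio `(L-B)/(L+B)` is insensitive to that factor.

## Fluid-structure coupling

Vertices couple to the lattice through the compact 2-point tent kernel
`phi(r) = 1 - |r|`, product form in 3-D.  Forces are spread as
`f(X) = sum_i F_i delta(X - x_i)` (exactly conservative, partition of
unity) and velocities interpolated with the same weights (the two
operators are exact adjoints); positions advance by explicit Euler with
axial wrap.  Two numerical details matter for stability:

* the advection velocity includes the half-force correction
  `u + F/(2 rho)`: without it the membrane-fluid feedback loop lags the
  applied force by half a step and slowly pumps membrane oscillation modes
  (observed e-folding over a few hundred steps in near-wall shear);
* membrane modes with wavelength below the kernel support are invisible to
  the lattice (their spread forces cancel), so vertex velocities are
  smoothed toward the edge-neighbour mean with strength 0.25 per step -- a
  sub-grid filter acting only on modes the fluid cannot damp.  Rigid
  translations are unaffected.

## Adhesive dynamics

Bonds between adhesion sites (all cell vertices; wall ligand sites placed
on the analytic cylinder surface in staggered rings, default spacing
0.5 um; 0.25 um in the arrest preset) follow Dembo kinetics

    k_f = k_f0 exp[-sigma_ts (l-l0)^2 / (2 kB T)],
    k_r = k_r0 exp[+(sigma_b - sigma_ts)(l-l0)^2 / (2 kB T)],

with formation/rupture probabilities `P = 1 - exp(-k dt)` over the
probability interval `dt = 0.1 us`, Hookean bond force
`F_bond = sigma_b (l - l0) e_hat`, and the deterministic effective-force
scheme

    F_eff = P_f (1 - P_r) F_bond

applied continuously to every candidate pair within the cutoff.  The
unstressed forward rate is `k_f0 = 1000 /s`; `sigma_ts` is small, so
formation remains possible at considerable separation (integrin-mediated
adhesion; the selectin tethering phase is not modelled).

A stochastic reference scheme is provided: per interval, candidate pairs
form with probability `P_f` and are immediately subject to rupture with
`P_r`, surviving bonds exerting the full `F_bond` for that interval.  Each
interval is independent, which makes the expected per-interval force
exactly `F_eff` (the equivalence the deterministic scheme relies on; it is
verified statistically in the tests).  A `monte_carlo_persistent` variant
with bond memory is also available; its stationary bound fraction is
`P_f/(P_f + P_r)`, which is *not* `P_f (1 - P_r)` -- the effective-force
scheme corresponds to the memoryless reference, not to the persistent
chain.

**Coarse-grained thermal energy.**  With the molecular thermal energy
`kB * 310 K`, the Boltzmann factors confine appreciable `P_eff` to
`|l - l0| <~ sqrt(32 kB T / sigma_b)`, i.e. a few nanometres for any
spring constant stiff enough to matter -- far below the 0.5-1 um mesh and
lattice scales of this model (and of any cell-resolved simulation).  The
thermal energy is therefore config-exposed: closed-form kinetics keep the
physical value, while coupled scenarios use an effective value chosen so
the interaction range matches the discretization scale (`7.5e-14 J` with
`sigma_b = 0.75 N/m` gives a ~0.5 um working range).  This rescaling is a
standard coarse-graining device; the functional forms and the probability
algebra are unchanged.

Candidate pairs are found with a KD-tree over all endpoints (axial
minimum-image), refreshed every 50 steps with a 0.3 um search margin, with
a per-endpoint cap (16) keeping the nearest partners.  Pairs stretched
beyond `3 l0` are dropped in effective-force mode (P_eff is negligible
there for slip bonds).  Short-range contact repulsion
(`F = k_c (1 - d/d_c)^2`, `k_c = 100 pN`, `d_c = 0.3-0.4 um`) prevents
cell-cell and cell-wall interpenetration.

## Coupled step and scenarios

Per fluid step: membrane forces -> contact forces -> adhesion update (the
probability cadence `round(dt_prob/dt)` is 1 at the desk-scale lattice) ->
spread -> collide/stream/bounce-back -> interpolate -> advect.  Everything
is deterministic given (config, seed); checkpoints (HDF5) restore
bit-identical continuations including RNG state.

The standard geometry is a 20 um diameter, 40 um long periodic vessel at
`dx = 0.5 um`.  The *desk-scale arrest scenario* (`arrest_reduced` preset)
shortens the segment to 20 um, coarsens to `dx = 1 um`, uses a 162-vertex
CTC and 42-vertex platelets, and runs 1.4e4 coupled steps (~1.9 ms of
physical time; full-scale studies of arrest integrate ~0.2 s on cluster hardware).
The tumor cell starts near the wall (margination is deliberately skipped)
with a 2 um clearance so that wall-biased platelets fit between cell and
wall; platelets are laid tangentially on the wall-facing hemisphere at
bond distance along a seeded Fibonacci spiral and pre-bonded to the cell.

Because the run is ~100x shorter than a full-scale arrest simulation, the
firm-adhesion criterion is applied at a proportionally reduced scale: the
axial displacement within every 0.4 ms window must stay below 0.5 um
(the full-scale criterion is < 5 um over the whole observation).  At this
scale a freely advected cell covers several micrometres per window, so the
criterion still separates arrest from rolling/advection unambiguously.

Platelet placements nest: the spiral of candidate positions is fixed, so
the 10-platelet layout contains the 5-platelet one and scenarios differ
only by how many platelets are attached.  What the reduced scenario shows:
with the same initial conditions except platelet count, the bare cell
never satisfies the arrest criterion (it advects outside the adhesive
range of the wall -- platelet mediation is required for wall contact), while platelet-decorated cells pin to
the wall during the initial transient and stay arrested; with more
platelets the arrest is at least as fast and the residual motion smaller.
Because the run is short, the graded rolling phase of a full-scale simulation
collapses to this arrested-versus-free contrast.  What it does not show: quantitative arrest times or distances
at physiological duration, RBC-crowding effects at physiological
hematocrit (the preset seeds at most a few RBCs), or selectin-phase
rolling.

## Known limitations

* Stair-case walls limit near-wall stress accuracy to a few percent at
  D = 40 nodes; interpolated (sub-grid) bounce-back is out of scope.
* The membrane model has no viscosity or thermal fluctuations; the
  quasi-static stretch test and the sub-grid velocity filter are the only
  dissipation mechanisms beyond the fluid itself.
* Adhesion spring constants, rest length, rupture prefactor and site
  density are coarse-grained effective parameters (the literature
  molecular values act on nanometre scales unresolvable here); the arrest
  preset uses sigma_b = 0.75 N/m, sigma_ts = sigma_b/50, k_r0 = 10/s,
  site spacing 0.25 um.  Conclusions should be read qualitatively, at the
  level of orderings and trends.
* Rare force spikes (bond snap, squeezed contacts) are clamped at
  2500 pN per vertex before spreading so the local flow response stays
  inside the advection CFL bound; the clamp is inactive in normal
  dynamics.
* The effective-force scheme matches the memoryless stochastic reference;
  long-lived discrete bonds (persistent chain) carry larger mean forces.
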