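"""Coupled time-stepping of fluid, membranes, coupling and adhesion.

One step advances the whole system in this order:

1. membrane internal forces (four-channel model, pN);
2. short-range contact repulsion (cell-cell and cell-wall);
3. adhesive dynamics at the probability cadence (``dt_prob`` pinned to
   0.1 us; candidate pairs are refreshed every ``neighbor_every`` steps
   with a search margin so intermediate motion cannot miss partners);
4. total Lagrangian forces spread to the lattice (tent kernel);
5. fused BGK collide + stream + halfway bounce-back with the sustaining
   body force;
6. velocities interpolated back to the vertices (with the half-force
   correction that keeps the membrane-fluid feedback loop phase-accurate);
7. explicit Euler advection with axial wrap.

All adhesion endpoints (cell vertices and wall ligand sites) share one
global numbering, so each probability interval is a single vectorized
registry update.  Everything is deterministic given (config, seed);
Monte-Carlo draws come from a generator derived from the scenario seed.
Checkpoints are lossless (populations, vertices, registry, RNG state) so a
restored run continues bitwise identically.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .adhesion_dynamics import AdhesionParams, BondRegistry, candidate_pairs, update_bonds
from .errors import CheckpointError, InvalidStateError
from .immersed_boundary import (
    advect_vertices,
    compute_stencil,
    interpolate_with_stencil,
    spread_with_stencil,
)
from ._kernels import fused_fluid_step
from .lattice_fluid import (
    FluidField,
    LatticeConfig,
    initialize_poiseuille,
    poiseuille_umax_lattice,
)
from .membrane_mechanics import CellMesh, MaterialModel, ReferenceState, total_membrane_force
from .metrics_analysis import (
    TrajectoryRecord,
    detect_firm_adhesion,
    membrane_force_summary,
)
from .scenario_geometry import (
    ScenarioConfig,
    attach_platelets,
    build_vessel,
    place_ctc_near_wall,
    scenario_hash,
    seed_rbcs,
)

__all__ = ["Simulation", "RunResult", "step", "run", "checkpoint", "restore"]

CHECKPOINT_VERSION = 2


@dataclass
class RunResult:
    """Outputs of a completed run."""

    config: ScenarioConfig
    trajectory: TrajectoryRecord
    manifest: dict
    firm_adhesion_time: float | None
    outdir: Path | None


class Simulation:
    """Fully-assembled scenario ready for time stepping.

    Cell vertices are kept in micrometres in the lattice frame (lattice
    coordinate = position / dx); cell 0 is the tumor cell, then platelets,
    then red cells.  Adhesion endpoints use a global numbering: cell
    vertices first (concatenated in cell order), wall ligand sites after.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config
        geom = config.vessel_geometry()
        self.vessel = build_vessel(geom)
        self.lattice = LatticeConfig(
            shape=self.vessel.flags.shape,
            dx=geom.dx,
            tau=config.tau,
            nu_phys=config.nu_phys,
            re=config.re,
        )
        self.adhesion = AdhesionParams(**config.adhesion)
        self.dx = geom.dx
        self.period_um = self.vessel.flags.shape[2] * self.dx
        self.field = initialize_poiseuille(self.lattice, geom)
        self._buffer = np.empty_like(self.field.f)

        # sustaining body force: u_max = g R^2 / (4 nu)
        r_nodes = self.vessel.radius_nodes
        u_max = poiseuille_umax_lattice(self.lattice, 2.0 * r_nodes)
        self.body_accel = np.array([0.0, 0.0, 4.0 * self.lattice.nu_lattice * u_max / r_nodes**2])
        self.u_max_lattice = u_max

        # cells ---------------------------------------------------------
        seeds = np.random.SeedSequence(config.seed).spawn(3)
        ctc = place_ctc_near_wall(config, self.vessel)
        platelets, _prebonds = attach_platelets(
            ctc,
            config.n_platelets,
            config,
            self.vessel,
            self.adhesion,
            seed=int(seeds[0].generate_state(1)[0] % 2**31),
            placement=config.platelet_placement,
        )
        rbcs = seed_rbcs(
            config.n_rbc,
            config,
            self.vessel,
            [ctc] + platelets,
            seed=int(seeds[1].generate_state(1)[0] % 2**31),
        )
        self.cells: list[CellMesh] = [ctc] + platelets + rbcs
        for c in self.cells:  # lattice -> um frame
            c.vertices = c.vertices * self.dx
        self.refs = [ReferenceState.from_mesh(c) for c in self.cells]
        base = MaterialModel(**config.material)
        self.materials: list[MaterialModel] = []
        for c in self.cells:
            scale = {
                "ctc": config.ctc_stiffness_scale,
                "platelet": config.platelet_stiffness_scale,
                "rbc": 0.1,
            }[c.kind]
            self.materials.append(base.scaled(scale))
        self.scenario_hash = scenario_hash(config, self.cells)

        # global endpoint numbering
        self._counts = [c.n_vertices for c in self.cells]
        self._offsets = np.concatenate([[0], np.cumsum(self._counts)])
        self._n_verts = int(self._offsets[-1])
        self._wall_um = self.vessel.wall_sites_um()

        self.rng = np.random.default_rng(seeds[2])
        self.step_count = 0
        self.time = 0.0
        self.axial_travel = np.zeros(len(self.cells))
        self._z0 = np.array([c.centroid()[2] for c in self.cells])
        self.adh_every = max(1, int(round(self.adhesion.dt_prob / self.lattice.dt)))
        self.registry = BondRegistry(scheme=config.scheme)
        self._contact_pairs = np.empty((0, 2), dtype=np.int64)
        self._adh_forces: np.ndarray | None = None  # flat (n_verts, 3)
        self._bond_count = 0
        self.records = TrajectoryRecord(
            time=np.empty(0),
            centroid=np.empty((0, 3)),
            velocity=np.empty((0, 3)),
            aspect_ratio=np.empty(0),
            max_nodal_force=np.empty(0),
            force_integral=np.empty(0),
            bond_count=np.empty(0, dtype=np.int64),
        )
        self._last_velocity = np.zeros(3)
        # per-cell vertex adjacency (for the sub-grid velocity filter):
        # membrane modes with wavelength below the kernel support receive no
        # restoring flow from the lattice, so their velocities are smoothed
        # toward the neighbour mean each step
        self._adjacency = []
        for c in self.cells:
            rows = np.concatenate([c.edges[:, 0], c.edges[:, 1]])
            cols = np.concatenate([c.edges[:, 1], c.edges[:, 0]])
            deg = np.bincount(rows, minlength=c.n_vertices).astype(float)
            self._adjacency.append((rows, cols, deg))
        self._rebuild_neighbors()

    # ------------------------------------------------------------------
    def _all_vertices(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 3))
        return np.concatenate([c.vertices for c in self.cells])

    def _min_image(self, disp: np.ndarray) -> np.ndarray:
        disp = disp.copy()
        disp[:, 2] -= self.period_um * np.round(disp[:, 2] / self.period_um)
        return disp

    def _owner_cells(self, global_ids: np.ndarray) -> np.ndarray:
        """Cell index per global endpoint id; -1 for wall sites."""
        out = np.searchsorted(self._offsets, global_ids, side="right") - 1
        out[global_ids >= self._n_verts] = -1
        return out

    def _rebuild_neighbors(self) -> None:
        """Refresh adhesion candidate pairs and contact pairs (with margin).

        Pairs are expressed in global endpoint ids (vertices then wall
        sites); within-cell pairs are excluded.
        """
        margin = 0.3  # um of free motion tolerated before the next rebuild
        cutoff = self.adhesion.cutoff + margin
        cap = self.adhesion.max_bonds_per_vertex
        verts = self._all_vertices()
        points = np.vstack([verts, self._wall_um]) if len(verts) else self._wall_um
        raw = candidate_pairs(verts, points, cutoff, period_z=self.period_um)
        if len(raw):
            owner_a = self._owner_cells(raw[:, 0])
            owner_b = self._owner_cells(raw[:, 1])
            # drop within-cell pairs; count each vertex-vertex pair once
            keep = (owner_a != owner_b) & ((raw[:, 1] >= self._n_verts) | (raw[:, 0] < raw[:, 1]))
            raw = raw[keep]
        if len(raw):
            # per-endpoint caps, nearest partners first
            pa, pb = self._endpoint_positions(raw, verts)
            dist = np.linalg.norm(pb - pa, axis=1)
            order = np.argsort(dist, kind="stable")
            counts: dict[int, int] = {}
            keep_idx = []
            for k in order:
                a, b = int(raw[k, 0]), int(raw[k, 1])
                if counts.get(a, 0) < cap and counts.get(b, 0) < cap:
                    counts[a] = counts.get(a, 0) + 1
                    counts[b] = counts.get(b, 0) + 1
                    keep_idx.append(k)
            raw = raw[np.sort(np.asarray(keep_idx, dtype=np.int64))]
        self.registry.set_pairs(raw)
        # contact pairs between distinct cells (vertex-vertex only)
        ccut = self.config.contact_cutoff + margin
        if len(verts):
            craw = candidate_pairs(verts, verts, ccut, period_z=self.period_um)
            if len(craw):
                co = self._owner_cells(craw[:, 0])
                co2 = self._owner_cells(craw[:, 1])
                craw = craw[(co != co2) & (craw[:, 0] < craw[:, 1])]
            self._contact_pairs = craw
        else:
            self._contact_pairs = np.empty((0, 2), dtype=np.int64)

    def _endpoint_positions(self, pairs: np.ndarray, verts: np.ndarray):
        points = np.vstack([verts, self._wall_um])
        pa = points[pairs[:, 0]]
        pb_raw = points[pairs[:, 1]]
        return pa, pa + self._min_image(pb_raw - pa)

    def _update_adhesion(self, verts: np.ndarray) -> None:
        forces = np.zeros((self._n_verts, 3))
        pairs = self.registry.pairs
        if len(pairs):
            pa, pb = self._endpoint_positions(pairs, verts)
            upd = update_bonds(self.registry, self.adhesion, pa, pb, rng=self.rng)
            a_is_vert = pairs[:, 0] < self._n_verts
            b_is_vert = pairs[:, 1] < self._n_verts
            np.add.at(forces, pairs[a_is_vert, 0], upd.force_a[a_is_vert])
            np.add.at(forces, pairs[b_is_vert, 1], -upd.force_a[b_is_vert])
            ctc_hi = self._counts[0]
            involves_ctc = (pairs[:, 0] < ctc_hi) | (pairs[:, 1] < ctc_hi)
            self._bond_count = int((upd.active & involves_ctc).sum())
        else:
            self._bond_count = 0
        self._adh_forces = forces

    def _contact_forces(self, verts: np.ndarray) -> np.ndarray:
        dc = self.config.contact_cutoff
        k = self.config.k_contact
        forces = np.zeros((self._n_verts, 3))
        pairs = self._contact_pairs
        if len(pairs):
            d = self._min_image(verts[pairs[:, 1]] - verts[pairs[:, 0]])
            dist = np.linalg.norm(d, axis=1)
            mask = (dist < dc) & (dist > 1e-12)
            if mask.any():
                mag = k * (1.0 - dist[mask] / dc) ** 2
                push = -(mag / dist[mask])[:, None] * d[mask]  # on a, away from b
                np.add.at(forces, pairs[mask, 0], push)
                np.add.at(forces, pairs[mask, 1], -push)
        # cell-wall: push vertices off the cylinder surface
        lat = verts / self.dx
        r = self.vessel.radial_distance(lat)
        gap = (self.vessel.radius_nodes - r) * self.dx  # um to the wall surface
        mask = gap < dc
        if mask.any():
            mag = k * (1.0 - np.clip(gap[mask], 0, None) / dc) ** 2
            nhat = np.zeros((int(mask.sum()), 3))
            nhat[:, 0] = (lat[mask, 0] - self.vessel.axis_xy[0]) / r[mask]
            nhat[:, 1] = (lat[mask, 1] - self.vessel.axis_xy[1]) / r[mask]
            forces[mask] -= mag[:, None] * nhat
        return forces

    # ------------------------------------------------------------------
    def step(self) -> "Simulation":
        """Advance the coupled system by one fluid timestep."""
        if not self.cells:  # pure fluid evolution
            self.field, self._buffer = fused_fluid_step(
                self.field, self.lattice.tau, body_accel=self.body_accel,
                buffer=self._buffer,
            )
            self.step_count += 1
            self.time += self.lattice.dt
            return self
        if self.step_count % self.config.neighbor_every == 0:
            self._rebuild_neighbors()
        verts = self._all_vertices()
        forces = self._contact_forces(verts)
        splits = self._offsets[1:-1]
        for i, c in enumerate(self.cells):
            f, _, _ = total_membrane_force(c, self.refs[i], self.materials[i])
            forces[self._offsets[i] : self._offsets[i + 1]] += f
        if self.step_count % self.adh_every == 0 or self._adh_forces is None:
            self._update_adhesion(verts)
        forces += self._adh_forces

        # clamp extreme per-vertex forces before they reach the fluid: a
        # rare-event guard (bond snap, squeezed contact) keeping the local
        # flow response inside the advection CFL bound
        clamp = self.config.force_clamp
        if clamp > 0.0:
            mag = np.linalg.norm(forces, axis=1)
            over = mag > clamp
            if over.any():
                forces[over] *= (clamp / mag[over])[:, None]
        # spread to the lattice (pN -> lattice force units), all cells at once
        all_lat = verts / self.dx
        stencil = compute_stencil(all_lat, self.field.shape)
        lat_force = np.zeros((3, *self.field.shape))
        spread_with_stencil(stencil, forces * (1e-12 / self.lattice.force_scale), lat_force)
        self.field, self._buffer = fused_fluid_step(
            self.field, self.lattice.tau, force=lat_force,
            body_accel=self.body_accel, buffer=self._buffer,
        )
        # move the membranes with the flow (velocities sampled at x_i(t));
        # the half-force term makes the advection velocity consistent with
        # the forcing scheme (second-moment correction), which keeps the
        # membrane-fluid feedback loop phase-accurate and stable
        nz = self.field.shape[2]
        rho, u = self.field.moments()
        with np.errstate(invalid="ignore", divide="ignore"):
            u = u + 0.5 * lat_force / np.where(rho > 0, rho, 1.0)
        u = np.where(self.field.fluid_mask[None], u, 0.0)
        vel = interpolate_with_stencil(stencil, u)
        lam = self.config.velocity_smoothing
        if lam > 0.0:
            parts = np.split(vel, splits)
            for i, (rows, cols, deg) in enumerate(self._adjacency):
                nbr = np.zeros_like(parts[i])
                np.add.at(nbr, rows, parts[i][cols])
                parts[i] += lam * (nbr / deg[:, None] - parts[i])
            vel = np.concatenate(parts)
        newlat, _ = advect_vertices(all_lat, vel, dt=1.0, nz=nz)
        for i, (v, nl) in enumerate(zip(np.split(vel, splits), np.split(newlat, splits))):
            if i == 0:
                self._last_velocity = v.mean(axis=0) * self.lattice.velocity_scale * 1e6
            self.axial_travel[i] += float(v[:, 2].mean()) * self.dx
            self.cells[i].vertices = nl * self.dx
        self.step_count += 1
        self.time += self.lattice.dt
        return self

    def record(self) -> None:
        """Append the tumor cell's state to the trajectory record."""
        from .metrics_analysis import inertia_ellipsoid_axes, taylor_aspect_ratio

        c = self.cells[0]
        f, _, _ = total_membrane_force(c, self.refs[0], self.materials[0])
        if self._adh_forces is not None:
            f = f + self._adh_forces[: self._counts[0]]
        fmax, fint = membrane_force_summary(c, f)
        big, small = inertia_ellipsoid_axes(c)
        cen = c.centroid()
        cen[2] = self._z0[0] + self.axial_travel[0]
        r = self.records
        r.time = np.append(r.time, self.time)
        r.centroid = np.vstack([r.centroid, cen])
        r.velocity = np.vstack([r.velocity, self._last_velocity])
        r.aspect_ratio = np.append(r.aspect_ratio, taylor_aspect_ratio(big, small))
        r.max_nodal_force = np.append(r.max_nodal_force, fmax)
        r.force_integral = np.append(r.force_integral, fint)
        r.bond_count = np.append(r.bond_count, self._bond_count)

    # ------------------------------------------------------------------
    def run(self, outdir=None, progress: bool = False) -> RunResult:
        """Execute the configured number of steps, recording and writing."""
        cfg = self.config
        n_steps = cfg.n_steps
        if cfg.duration is not None:
            n_steps = int(round(cfg.duration / self.lattice.dt))
        outdir = Path(outdir) if outdir is not None else None
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)
        t0 = _time.time()
        if self.step_count == 0:
            self.record()
        try:
            while self.step_count < n_steps:
                self.step()
                if self.step_count % cfg.output_every == 0 or self.step_count == n_steps:
                    if not np.isfinite(self.field.f[:, self.field.fluid_mask]).all():
                        raise InvalidStateError(
                            f"populations diverged (NaN) at step {self.step_count}"
                        )
                    self.record()
                    if progress:
                        print(
                            f"step {self.step_count}/{n_steps} t={self.time:.3e}s "
                            f"z={self._z0[0] + self.axial_travel[0]:.2f}um "
                            f"bonds={self._bond_count} "
                            f"[{_time.time() - t0:.0f}s]",
                            flush=True,
                        )
                    if cfg.vtk_every and outdir is not None and (
                        self.step_count % cfg.vtk_every == 0
                    ):
                        self._write_vtk(outdir)
        finally:
            if outdir is not None:
                self._write_outputs(outdir)
        window = cfg.arrest_window
        if window is None:
            window = max(self.time / 4.0, self.lattice.dt)
        firm = None
        if len(self.records.time) > 2 and window < self.records.time[-1]:
            firm = detect_firm_adhesion(self.records, window, cfg.arrest_tol)
        manifest = self._manifest()
        if outdir is not None:
            with open(outdir / "metrics.json", "w") as fh:
                json.dump(
                    {
                        "firm_adhesion_time_s": firm,
                        "final_aspect_ratio": float(self.records.aspect_ratio[-1])
                        if len(self.records.aspect_ratio)
                        else None,
                        "final_axial_position_um": float(self.records.centroid[-1, 2])
                        if len(self.records.time)
                        else None,
                    },
                    fh,
                    indent=1,
                )
        return RunResult(
            config=cfg,
            trajectory=self.records,
            manifest=manifest,
            firm_adhesion_time=firm,
            outdir=outdir,
        )

    def _manifest(self) -> dict:
        return {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "scenario_hash": self.scenario_hash,
            "lattice": self.lattice.metadata(),
            "adhesion_interval_steps": self.adh_every,
            "u_max_lattice": self.u_max_lattice,
        }

    def _write_outputs(self, outdir: Path) -> None:
        self.records.to_dataframe().to_csv(outdir / "trajectory.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self._manifest(), fh, indent=1, sort_keys=True)
        self._write_bond_snapshot(outdir / "bonds.csv")

    def _write_bond_snapshot(self, path: Path) -> None:
        import pandas as pd

        pairs = self.registry.pairs
        if len(pairs) and self.cells:
            verts = self._all_vertices()
            pa, pb = self._endpoint_positions(pairs, verts)
            snap_reg = BondRegistry(pairs=pairs, scheme="effective_force")
            upd = update_bonds(snap_reg, self.adhesion, pa, pb)
            owner_a = self._owner_cells(pairs[:, 0])
            owner_b = self._owner_cells(pairs[:, 1])
            local_a = pairs[:, 0] - np.where(owner_a >= 0, self._offsets[np.clip(owner_a, 0, None)], self._n_verts)
            local_b = pairs[:, 1] - np.where(owner_b >= 0, self._offsets[np.clip(owner_b, 0, None)], self._n_verts)
            df = pd.DataFrame(
                {
                    "cell_a": owner_a,
                    "vertex_a": local_a,
                    "cell_b": owner_b,
                    "vertex_b": local_b,
                    "length_um": upd.lengths,
                    "P_f": upd.pf,
                    "P_r": upd.pr,
                    "P_eff": upd.peff,
                    "force_pN": np.linalg.norm(upd.force_a, axis=1),
                }
            )
        else:
            df = pd.DataFrame(
                columns=[
                    "cell_a", "vertex_a", "cell_b", "vertex_b",
                    "length_um", "P_f", "P_r", "P_eff", "force_pN",
                ]
            )
        df.to_csv(path, index=False)

    def _write_vtk(self, outdir: Path) -> None:
        from .io_formats import write_vtk_polydata, write_vtk_structured
        from .metrics_analysis import vorticity_field

        rho, u = self.field.moments()
        u = np.where(self.field.fluid_mask[None], u, 0.0)
        write_vtk_structured(
            outdir / f"fluid_{self.step_count:08d}.vtk",
            scalars={
                "density": np.where(self.field.fluid_mask, rho, 0.0),
                "flags": self.field.flags.astype(float),
                "vorticity_mag": np.linalg.norm(
                    vorticity_field(self.field, self.lattice), axis=0
                ),
            },
            vectors={"velocity": u * self.lattice.velocity_scale},
            spacing=self.dx,
        )
        for i, c in enumerate(self.cells):
            f, mag, _ = total_membrane_force(c, self.refs[i], self.materials[i])
            write_vtk_polydata(
                outdir / f"cell{i}_{self.step_count:08d}.vtk",
                c.vertices,
                c.faces,
                point_data={"force": f, "force_mag": mag},
            )

    # ------------------------------------------------------------------
    # Checkpointing
    # ------------------------------------------------------------------
    def checkpoint(self, path) -> None:
        """Lossless state snapshot (HDF5) including RNG and the registry."""
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["version"] = CHECKPOINT_VERSION
            h5.attrs["step"] = self.step_count
            h5.attrs["time"] = self.time
            h5.attrs["config"] = json.dumps(self.config.to_dict(), sort_keys=True)
            h5.attrs["scenario_hash"] = self.scenario_hash
            h5.attrs["rng_state"] = json.dumps(self.rng.bit_generator.state)
            h5.attrs["bond_count"] = self._bond_count
            h5.create_dataset("f", data=self.field.f)
            h5.create_dataset("axial_travel", data=self.axial_travel)
            h5.create_dataset("z0", data=self._z0)
            h5.create_dataset("last_velocity", data=self._last_velocity)
            cells = h5.create_group("cells")
            for i, c in enumerate(self.cells):
                cells.create_dataset(str(i), data=c.vertices)
            reg = h5.create_group("registry")
            reg.create_dataset("pairs", data=self.registry.pairs)
            reg.create_dataset("bound", data=self.registry.bound)
            h5.create_dataset("contact_pairs", data=self._contact_pairs)
            if self._adh_forces is not None:
                h5.create_dataset("adh_forces", data=self._adh_forces)
            rec = h5.create_group("records")
            for name in ("time", "aspect_ratio", "max_nodal_force", "force_integral"):
                rec.create_dataset(name, data=getattr(self.records, name))
            rec.create_dataset("centroid", data=self.records.centroid)
            rec.create_dataset("velocity", data=self.records.velocity)
            rec.create_dataset("bond_count", data=self.records.bond_count)

    @classmethod
    def restore(cls, path) -> "Simulation":
        """Rebuild a simulation from a checkpoint; continues bitwise."""
        import h5py

        try:
            h5 = h5py.File(path, "r")
        except OSError as exc:
            raise CheckpointError(f"cannot open checkpoint {path}: {exc}") from exc
        with h5:
            if int(h5.attrs["version"]) != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {h5.attrs['version']} != {CHECKPOINT_VERSION}"
                )
            config = ScenarioConfig.from_dict(json.loads(h5.attrs["config"]))
            sim = cls(config)
            if h5.attrs["scenario_hash"] != sim.scenario_hash:
                # the same config must regenerate the same scenario
                raise CheckpointError("scenario hash mismatch on restore")
            sim.field.f[...] = h5["f"][...]
            sim.step_count = int(h5.attrs["step"])
            sim.time = float(h5.attrs["time"])
            sim.axial_travel[...] = h5["axial_travel"][...]
            sim._z0[...] = h5["z0"][...]
            sim.rng.bit_generator.state = json.loads(h5.attrs["rng_state"])
            for i in range(len(sim.cells)):
                sim.cells[i].vertices = h5[f"cells/{i}"][...]
            sim.registry = BondRegistry(scheme=config.scheme)
            sim.registry.pairs = h5["registry/pairs"][...]
            sim.registry.bound = h5["registry/bound"][...].astype(bool)
            sim._contact_pairs = h5["contact_pairs"][...]
            sim._adh_forces = h5["adh_forces"][...] if "adh_forces" in h5 else None
            sim._bond_count = int(h5.attrs["bond_count"])
            sim._last_velocity = h5["last_velocity"][...]
            rec = h5["records"]
            sim.records = TrajectoryRecord(
                time=rec["time"][...],
                centroid=rec["centroid"][...],
                velocity=rec["velocity"][...],
                aspect_ratio=rec["aspect_ratio"][...],
                max_nodal_force=rec["max_nodal_force"][...],
                force_integral=rec["force_integral"][...],
                bond_count=rec["bond_count"][...],
            )
        return sim


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def step(sim: Simulation) -> Simulation:
    return sim.step()


def run(config: ScenarioConfig, outdir=None, progress: bool = False) -> RunResult:
    return Simulation(config).run(outdir=outdir, progress=progress)


def checkpoint(sim: Simulation, path) -> None:
    sim.checkpoint(path)


def restore(path) -> Simulation:
    return Simulation.restore(path)
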