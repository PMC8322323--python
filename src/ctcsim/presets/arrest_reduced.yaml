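# Desk-scale platelet-mediated arrest scenario.
#
# A 20 um periodic vessel segment at 1 um lattice spacing; an 8 um tumor
# cell starts near the wall with wall-biased platelets pre-attached.  The
# firm-adhesion criterion is applied at the run's reduced scale: axial
# displacement below 0.5 um within every 1 ms window.  Adhesion constants
# are coarse-grained effective values (see docs/methods.md); the thermal
# energy sets the Dembo interaction range at the discretization scale.
vessel:
  diameter: 20.0
  length: 20.0
  dx: 1.0
  wall_site_spacing: 0.25
n_platelets: 5
ctc_diameter: 8.0
ctc_vertices: 162
platelet_diameter: 2.0
platelet_aspect: 0.5
platelet_vertices: 42
ctc_stiffness_scale: 1.0
platelet_stiffness_scale: 3.0
n_rbc: 0
wall_gap: 2.0
material:
  k_link: 166.0
  k_bend: 8.0
  k_area_local: 20.0
  k_area_global: 20.0
  k_volume: 300.0
  strain_max: 2.0
adhesion:
  sigma_b: 0.75
  sigma_ts: 0.015
  kr0: 10.0
  thermal_energy: 7.5e-14
  l0: 0.3
  cutoff: 1.2
  max_bonds_per_vertex: 32
tau: 1.0
re: 0.025
n_steps: 14000
output_every: 500
neighbor_every: 50
contact_cutoff: 0.4
k_contact: 100.0
arrest_tol: 0.5
arrest_window: 1.0e-3
scheme: effective_force
seed: 11
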