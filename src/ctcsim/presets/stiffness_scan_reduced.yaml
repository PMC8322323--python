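# Stiffness-sensitivity variant of the reduced arrest scenario: run with
# ctc_stiffness_scale (or platelet_stiffness_scale) overridden to 0.7 and
# 1.3 to compare softer/stiffer cells against the 1.0 baseline.
vessel:
  diameter: 20.0
  length: 20.0
  dx: 1.0
  wall_site_spacing: 0.25
n_platelets: 5
ctc_diameter: 8.0
ctc_vertices: 162
platelet_vertices: 42
ctc_stiffness_scale: 0.7
platelet_stiffness_scale: 3.0
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
n_steps: 14000
output_every: 500
neighbor_every: 50
contact_cutoff: 0.4
k_contact: 100.0
arrest_tol: 0.5
arrest_window: 1.0e-3
seed: 11
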