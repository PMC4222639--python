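# Bundled desk-scale demo configuration.
#
# The synthetic system is the default 465-residue Parkin-like chain
# (UBL 1-76 + linker 77-140 flexible, core 141-465 rigid).  Step counts are
# desk-scale: each variant trajectory is 150 ps of CG time, the demon chain
# drives the phosphorylated system across 5 low-mode guideposts.

master_seed: 0
output_dir: demonmd_out
solvate: true

toy:
  n_residues: 465
  bond_length: 3.8

solvation:
  shell_depth: 15.0
  water_density: 1.0
  ion_pairs: 5

potential:
  bond_k: 100.0
  bond_r0: 3.8
  angle_k: 5.0
  lj_epsilon: 0.25
  dielectric: distance
  nonbonded_cutoff: 9.0
  en_cutoff: 10.0
  en_k: 10.0

md:
  dt: 0.01
  thermostat: berendsen
  tau: 0.5
  T_target: 300.0
  n_steps: 15000
  com_removal_interval: 100
  frame_interval: 250
  neighbor_skin: 2.0
  n_replicates: 4

guideposts:
  n_posts: 5
  amplitude: 40.0
  min_iter: 120

demon:
  sprint_min: 30
  sprint_max: 90
  accept_tol: 0.0
  success_radius: 3.0
  max_sprints: 400
  burn_in: 100
  n_replicates: 4
  variant: pSer65

metrics:
  pocket_cutoff: 5.0
  sasa_points: 240
  final_fraction: 0.3333333333333333

zone:
  flex_halfwidth: 2
  physics_cutoff: 12.0
  inertia_scale: 11.0
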