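# demonmd

Coarse-grained Maxwell's-demon molecular dynamics for Parkin-like
multi-domain systems.

Parkin, the E3 ubiquitin ligase mutated in recessive parkinsonism, is
auto-inhibited: its N-terminal ubiquitin-like domain (UBL, residues 1-76)
and a flexible linker (77-140) clamp onto the zinc-finger-stabilised RING
cassette (141-465), burying the E2-binding site and the catalytic Cys431.
PINK1-dependent phosphorylation of Ser65 — which sits in a cleft between
the UBL and the linker — triggers a cascade of openings: the cleft widens
and hydrates, the UBL releases RING1/IBR, the REP element vacates the
E2-binding site, and RING0 exposes Cys431.

`demonmd` reimplements, at desk scale, the computational machinery used to
build that argument:

* **structio** — bead-level structures, multi-model PDB trajectories, and
  the named Parkin residue selections (domain map, cleft walls, CoM groups,
  E2 site, probe residues);
* **synthgen** — synthetic Parkin-like systems: a rigid elastic-network
  core, a mobile UBL + linker, a Ser65 cleft whose width responds to the
  site charge, solvation shells, and low-mode guidepost conformers;
* **cgpotential** — the coarse-grained force field (bonds, angles, optional
  torsions, shifted LJ + Coulomb with a distance-dependent dielectric,
  elastic network, harmonic restraints, zinc-finger-style semi-rigid group
  restraints) and site modifications (pSer65, S65A/D/E as parameter edits);
* **dynamics** — Polak-Ribiere / steepest-descent minimisation, velocity
  Verlet with Berendsen or Langevin thermostats and flying-ice-cube COM
  removal, the staged minimise/heat equilibration protocol, and the mixed
  torsional / low-mode Monte Carlo conformer search (5000-step budget,
  5.02 kcal/mol energy window, 3.0-7.5 A low-mode moves, 10 saved);
* **mdmd** — the Maxwell's-demon sampler: unbiased MD sprints of random
  length accepted only when the Kabsch Calpha RMSD to a guidepost does not
  rise, chained across guideposts, with replicates and discard statistics;
* **zemu** — zone-equilibrated mutation scoring: a 5-residue torsion-space
  flexibility zone inside a 12 A physics zone, `ddG = dG_wt - dG_mut`, and
  the interaction decomposition
  `ddG_ab = dG_ab - (dG_a + dG_b) + dG_kon + dS_sc`;
* **trajmetrics** — CoM distances, Shrake-Rupley SASA, pocket water counts,
  pair distances, RMSD/RMSF series, backbone pseudo-dihedrals;
* **orchestrator** — config, manifests and the `demonmd` CLI
  (`generate`, `simulate`, `analyze`, `ddg`, `demo`).

See `docs/methods.md` for the model, parameter choices and limitations.

## Worked example

Drive the phosphorylated synthetic system along 5 low-mode guideposts with
the demon and measure how far each chained leg lands from its guidepost:

```python
import demonmd as d
from demonmd.mdmd import chain_guideposts

pspec = d.PotentialSpec()
base = d.minimize(d.make_parkin_like(d.ToySpec(seed=0)), pspec,
                  max_iter=300).structure
driven = d.apply_modification(base, d.SiteModification(65, "pSer"))
posts = d.generate_guideposts(base, n_posts=5, amplitude=40.0, seed=1,
                              pspec=pspec)

cfg = d.DemonConfig(md=d.MDConfig(dt=0.01, thermostat="berendsen", tau=0.5,
                                  T_target=300.0, com_removal_interval=50,
                                  neighbor_skin=2.0),
                    sprint_min=30, sprint_max=90, success_radius=3.0,
                    max_sprints=250, burn_in=100, seed=0)
chain = chain_guideposts(driven, posts, cfg, p=pspec)
for k, st in enumerate(chain.leg_stats):
    print(f"leg {k}: reached={st.reached} final_cv={st.final_cv:.2f} A "
          f"sprints={st.n_sprints} discard={st.discard_fraction:.2f}")
```

Output (one CPU, ~10 s):

```
leg 0: reached=True final_cv=0.93 A sprints=0 discard=0.00
leg 1: reached=True final_cv=2.55 A sprints=0 discard=0.00
leg 2: reached=True final_cv=2.95 A sprints=83 discard=0.66
leg 3: reached=True final_cv=2.98 A sprints=102 discard=0.69
leg 4: reached=True final_cv=2.90 A sprints=34 discard=0.44
```

Each leg delivers the structure to within the 3 A success radius of its
guidepost.  The first legs are reached without sprinting (the first
guidepost is the minimised start and its neighbours are close); the later
legs need real demon work — tens of sprints, with 44-69% of sprints
discarded for moving the collective variable the wrong way.

The full pipeline, from system generation through trajectory metrics and a
ddG table, runs off the bundled configuration:

```bash
demonmd demo --out demo_run --seed 0
```

which writes the system and guidepost PDBs, per-variant replicate
trajectories (Ser65, pSer65, S65A, S65D, S65E), demon sprint ledgers,
metric CSVs (cleft CoM distance, Ser65-pocket SASA, UBL-RING1 / UBL-IBR /
REP-RING1 / RING0-Cys431 distances, core and N-terminal RMSD, per-residue
RMSF), figure panels, a ddG table, and per-stage manifests with seeds and
config hashes.

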