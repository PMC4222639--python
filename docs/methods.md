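# Methods

`demonmd` is a desk-scale reimplementation of the computational machinery
used to study the activation of the E3 ubiquitin ligase Parkin by
phosphorylation of Ser65: a coarse-grained bead model and force field, a
thermostatted integrator with the staged equilibration protocol, low-mode
conformer generation, the Maxwell's-demon biased sampler (MdMD) chained
across guidepost conformations, zone-equilibrated mutation scoring
(ZEMu-style ddG), and the trajectory metrics used to argue that pSer65 opens
a UBL-linker cleft and sequentially releases auto-inhibitory domain
contacts.  Everything runs on synthetic Parkin-like systems generated by the
package itself; no structure downloads are required.

## The coarse-grained model

One bead per residue (Calpha), 110 Da, radius 1.9 A.  Waters are single
neutral beads (18 Da, 1.4 A), ions are +1/-1 beads.  Units project-wide:
A, kcal/mol, ps, K, elementary charges, Da.

Energy terms (defaults in parentheses):

| term | form | default |
| --- | --- | --- |
| bond | 0.5 k (r - r0)^2 | k = 100 kcal/(mol A^2), r0 = 3.8 A |
| angle | 0.5 k (theta - theta0)^2 | k = 5 kcal/(mol rad^2); theta0 from the reference geometry |
| torsion | sum A (1 + cos(n phi - delta)) | none by default |
| LJ | 4 eps ((s/r)^12 - (s/r)^6), shifted at the cutoff | eps = 0.25 kcal/mol; per-pair sigma scales with bead radii so a standard Calpha pair has its minimum at 3.8 A |
| Coulomb | 332.0637 qi qj / (eps(r) r), shifted | distance-dependent eps(r) = 4r (a constant-dielectric mode and optional Debye screening are available) |
| elastic network | 0.5 k (d - d_ref)^2, rigid-tagged pairs within 10 A | k = 10 kcal/(mol A^2) |

1-2 and 1-3 nonbonded exclusions, no 1-4 scaling, 9 A nonbonded cutoff.
Both nonbonded contributions are energy-shifted at the cutoff so the
integrator sees no discontinuity when pairs cross it.  Angle reference
angles and elastic-network rest lengths are taken from the structure a
`System` is compiled from; a biased run keeps them anchored to its starting
conformation, which is what makes the rigid core a stable scaffold over a
whole chained run.

The 2-fs/SHAKE recipe of the all-atom protocol is replaced by stiff harmonic
bonds: CG beads have no fast X-H modes, so the constraint that exists to
enable the 2-fs step is unnecessary; the default timestep is configurable
and the bundled demo uses 10 fs (stable for the stiffest default mode,
omega = sqrt(2 k_bond/m) ~ 28 rad/ps, i.e. ~23 steps per period).

Site modifications are parameter edits at one residue: pSer adds -2 e (the
dominant phosphate protonation state at pH 7.4) and +0.4 A radius; S->D and
S->E add -1 e (S->E also +0.1 A, one methylene longer); S->A sets the site
charge to zero (alanine carries no polar charge) and shrinks the bead by
0.2 A; C->S changes no charge.  The pSer choice of -2 gives the maximal
contrast with the -1 phosphomimetics, matching the observed ordering of
cleft opening (pSer fastest, D/E intermediate).

## The synthetic Parkin-like system

The default generator builds a 465-residue chain mirroring the Parkin
domain plan: residues 1-140 flexible (UBL 1-76 + linker 77-140), residues
141-465 rigid (the zinc-finger-stabilised RING0/RING1/IBR/REP/RING2
cassette), tagged for elastic-network springs.  The architecture is a
sandwich assembled from lattice paths with the 3.8 A Calpha spacing:

* a rigid core blob (141-465) at the bottom;
* the linker wall (97-140) as a one-bead-thick serpentine laminated on the
  core's top face by plain LJ contact — the desk-scale analog of the linker
  packing against the RING cassette;
* the UBL as a compact 4 x 4 x 5 lattice blob resting on the charged
  stretch of the wall across a 4 A cleft gap;
* a slack 20-residue loop (77-96) joining UBL to wall on the open side.

The cleft electrostatics implement the Ser65 latch: wall residues 97-118
carry -0.5 e each; the Ser65 bead (which sits at a corner of the UBL face,
in contact with wall residues around 102/111/112) carries +0.8 e; the UBL's
N-terminal corner (residues 1-4, the "hinge") carries +0.25 e each.  In the
wild type the latch and hinge glue the UBL face onto the wall (initial
CoM1-CoM2 cleft distance ~7-9 A).  Phosphorylation flips the latch to
-1.2 e — a repulsive wedge; S65D/E to -0.2 e — glue lost plus a weak push;
S65A to 0 — glue lost.  All four modifications therefore widen the cleft
relative to wild type, with pSer the strongest driver, which is exactly the
qualitative contrast the trajectory metrics must reproduce.  These charges
are the generator's study conditions; they were chosen during generator
design so that the wild-type cleft is thermally stable at 300 K over the
demo trajectory length while every modified variant loosens or detaches,
and they are not exposed as tuning knobs.

Because the opening of a marginally stable contact is a stochastic event,
single CG trajectories of ~150 ps are noisy.  The bundled comparison
protocol therefore runs a small replicate ensemble (4 trajectories per
variant, seeds derived from the master seed) and compares ensemble means of
the final-third cleft distance — the same replicate logic the original
all-atom study used for its pathway claims.  Passing this comparison shows
the coarse model reproduces the direction of the charge effect; it says
nothing about magnitudes or timescales in the real protein, where opening
takes tens to hundreds of nanoseconds.  The effect sizes are graded
(pSer > D/E > A, with wild type lowest): across independent reseedings of
the whole protocol the ensemble means average roughly 9 A (wild type) vs
12-15 A (variants), but the weakest contrasts (S65A and S65E, whose only
difference from wild type is the lost latch charge) order correctly in
about two of three reseedings at this ensemble size — a 4-replicate,
150 ps ensemble sits near the resolution limit of the directional claim,
which is itself a faithful miniature of why the original study needed long
replicate trajectories.

Solvation places single-bead waters uniformly in a shell between 2.8 A
(`r_excl`, the bead-radius sum) and 15 A from the protein, rejection-sampled
against overlap, at a desk-scale density default of 1 water per 1000 A^3 of
shell volume (~300-700 waters for the default system) plus 5 Na+/Cl- pairs
emulating physiological-strength salt.  Hydration counting needs water
positions, not water physics, so waters are neutral beads.

## Guideposts and the demon

Guideposts are generated from the anisotropic elastic-network normal modes
of the Calpha network (uniform springs within 10 A): a seeded random
combination of the three lowest non-trivial modes, zeroed on the rigid
core, displaces the flexible region in evenly spaced increments up to an
amplitude (demo: 40 A RMS over flexible beads before relaxation), and each
conformer is energy-minimised against the starting reference.  Minimisation
re-compacts much of the raw displacement; the demo guidepost set spans
~4.6 A of all-Calpha RMSD from the start, in 5 posts.

The demon (MdMD) runs unbiased MD sprints of random length (uniform 30-90
steps in the demo; the randomised sprint interval is what decorrelates
replicates) and accepts a sprint only if the collective variable — Kabsch
Calpha RMSD to the current guidepost — did not increase (accept_tol = 0, the
strict demon).  A rejected sprint restores the pre-sprint coordinates and
redraws isotropic Boltzmann velocities; a directional draw is left as a
declared extension point.  A leg stops when the CV reaches the success
radius (3 A) or the sprint budget (250) is exhausted; chained legs hand the
terminal structure of one leg to the next guidepost.  On the demo system
the early legs start inside the success radius (the first guidepost is the
minimised start) and the later legs require tens to >100 sprints with
discard fractions of roughly 40-80% — higher than the 8-16% reported for
the all-atom system, as expected for a rougher, smaller landscape; the
package reports discard statistics, it does not enforce them.

With the demon disabled (accept_tol = infinity) a run reduces exactly to
plain velocity-Verlet integration, which is tested.

## Integrator, thermostats, equilibration

Velocity Verlet; Berendsen weak coupling (tau = 1 ps by default, 0.5 ps in
the demo) or Langevin (BAOAB-style exact OU velocity step) thermostats;
centre-of-mass translation *and* rotation (inertia-tensor based) removed
every `com_removal_interval` steps as the flying-ice-cube guard.  The
Berendsen scale factor is clamped to [0.8, 1.25] per step so a cold start
cannot overshoot.  Neighbour lists (cKDTree) are rebuilt when any bead has
moved more than half the skin (2 A in the demo).  NVE energy conservation
on a harmonic dimer (drift < 1e-4 relative over 10^4 steps at dt = 0.5 fs)
is the primary integrator oracle; analytic forces are verified against
central finite differences on randomised systems.

`staged_equilibration` reproduces the shape of the published protocol at
configurable (default much smaller) step counts, with a 6-entry stage
ledger: minimise; heat with positional restraints k = 10 kcal/(mol A^2);
minimise; heat with k = 5; minimise with restraints reduced by 1 (k = 4);
unrestrained linear ramp from 1 to 310 K.  The heating schedule is linear
because the source protocol says only "slowly heated".

Minimisation: Polak-Ribiere conjugate gradient (via scipy's CG, which is
the PR+ variant with a Wolfe line search, hence monotone in energy) or a
simple backtracking steepest descent.  The protocol literature names both
"Powell-Reeves" and "Polak-Ribiere"; this package implements Polak-Ribiere,
the variant named for the structural minimisations.

## Low-mode Monte Carlo search

`lowmode_mc_search` mixes backbone pseudo-torsion rotations (probability
0.5) with displacements along random low elastic-network modes whose RMS
magnitude is drawn uniformly from [3.0, 7.5] A, minimising after each move
and keeping structures within a 5.02 kcal/mol window of the running best;
up to 10 lowest-energy conformers at pairwise Calpha RMSD > 0.5 A are
returned, sorted by energy.  The step budget is
min(5000, 100 x rotatable bonds) by default and is scaled far down in the
tests (each step costs a minimisation).

## Zone-equilibrated mutation scoring

The flexibility zone is the mutated residue plus two residues each side
(clipped at termini), treated in torsion space: rotating about a zone
pseudo-bond moves only zone beads downstream of the pivot, so every
coordinate outside the zone is bit-identical through the calculation.  The
physics zone is every residue with a bead within 12 A of the flexible
residues; the score of a state is the CG energy of the physics-zone
sub-structure.  `ddG = dG_wt - dG_mut` after equilibrating both states with
the same derivative-free (Powell) torsion-space minimisation.  The
historical inertia-scaling factor 11.0 is recorded in `ZoneSpec` for
provenance but has no effect in a minimisation — it mattered only for the
variable-timestep dynamics of the original implementation.

The complex-formation decomposition
`ddG_ab = dG_ab - (dG_a + dG_b) + dG_kon + dS_sc` is implemented literally
with CG energies for the three dG terms and caller-supplied corrections
(default 0).  Because the scoring function is the CG energy rather than an
empirical knowledge-based potential, absolute ddG values are CG-scale
quantities: the meaningful outputs are signs, orderings across mutations of
different charge, and the zone mechanics — not kcal/mol comparable to
empirical predictors.

## Trajectory metrics

* centre-of-mass distances between named residue selections (mass-weighted
  by default; the source analysis says "centre of mass" without an atom
  set, so a geometric option is retained);
* Shrake-Rupley SASA with a deterministic golden-spiral quadrature
  (default 960 points, <= 2% error against the closed-form isolated-bead
  area; 240 points for per-frame series);
* pocket hydration: waters within 5 A of any pocket-residue bead, each
  counted once — the cavity criterion of the original hydration plots is
  not stated, so this cutoff rule is a declared surrogate;
* pair distances between named probes (e.g. Leu26-Cys238 for UBL-RING1,
  Tyr391-Cys238 for REP-RING1, Arg163-Cys431 for the active-site burial;
  the original "RMSD for centre-of-mass" phrasing for the RING0 metric
  mixes distance and RMSD language, so both a pair-distance and an
  RMSD-series reading are exposed);
* Kabsch RMSD series and RMSF (superposition onto the trajectory mean,
  iterated twice);
* backbone pseudo-dihedrals from consecutive Calpha quadruples, signed
  degrees in (-180, 180].

The named selection registry carries the published residue lists verbatim:
domain ranges UBL 1-76, linker 77-140, RING0 141-216, RING1 217-328,
IBR 329-378, REP 379-410, RING2 411-465; cleft walls, CoM1/CoM2, the
19-residue E2-binding site, and single-residue probes.

## Problem sizes and determinism

The bundled demo runs the full 465-bead system: 150 ps per variant
trajectory (4 replicates x 5 variants), 5 guideposts, demon chains of up to
250 sprints per leg, 4 demon replicates.  These sizes were chosen so the
whole pipeline is a few CPU-minutes while every convergence bound is
exercised with real sampling.  A single master seed fans out through
`numpy.random.SeedSequence` to per-stage and per-replicate seeds: reruns are
bit-identical, replicates are independent.  All generators are pure
functions of their seeds.

The nonbonded kernel is JIT-compiled with numba when available, with a pure
numpy/Python reference path (identical results to floating-point accuracy;
the gradient tests run against the compiled path).

## Known limitations

* The CG surrogate makes no claim of force-field equivalence with the
  all-atom protocols it mirrors (which themselves tested Charmm27, Amber
  and OPLS2005 without reporting a choice).
* Cutoff electrostatics with a distance-dependent dielectric stand in for
  PME; constant-volume runs stand in for the constant-pressure production
  ensemble.  No ensemble equivalence is claimed.
* Headline magnitudes of the original study (absolute cleft widths over
  100-1000 ns, water counts, 20 -> 50 A domain separations, FoldX ddG
  values) are properties of an undeposited all-atom model and external
  scoring functions; the package reproduces bounds, directions and
  mechanics, not those magnitudes.
* The synthetic system's charges and lattice geometry are a designed
  caricature: passing tests demonstrates the machinery (sampler, metrics,
  scoring) behaves correctly on a system with the right architecture, not
  that the real protein behaves this way.
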