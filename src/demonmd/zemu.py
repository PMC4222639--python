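"""Zone equilibration of mutants and mutation / interaction free energies.

A mutation is scored by relaxing a small flexibility zone (the mutated
residue plus two residues on each side) in torsion space, with all other
coordinates frozen, and evaluating the coarse-grained energy of the
enclosing physics zone (every residue with a bead within 12 A of the
flexible residues).  The mutation score is the classic difference

    ddG = dG_wt - dG_mut

and complex formation is scored with the interaction decomposition

    ddG_ab = dG_ab - (dG_a + dG_b) + dG_kon + dS_sc

where the kon-electrostatics and side-chain-entropy terms are supplied by
the caller (default 0).  Absolute values are CG-scale quantities; the
meaningful outputs are signs and orderings across mutations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .cgpotential import PotentialSpec, SiteModification, System, apply_modification
from .structio import Selection, Structure, apply_selection, extract

logger = logging.getLogger("demonmd.zemu")

__all__ = ["ZoneSpec", "DdgResult", "flexibility_zone", "physics_zone",
           "equilibrate_zone", "ddg_mutation", "ddg_interaction"]


@dataclass(frozen=True)
class ZoneSpec:
    """Zone geometry around a mutation site.

    ``inertia_scale`` is recorded for provenance with the torsion-space
    treatment it historically accompanied; it has no effect here because
    zone relaxation is a minimisation, not dynamics (intentionally inert).
    """

    site: int
    flex_halfwidth: int = 2
    physics_cutoff: float = 12.0
    inertia_scale: float = 11.0

    def __post_init__(self):
        if self.flex_halfwidth < 0:
            raise ValueError("flex_halfwidth must be >= 0")
        if self.physics_cutoff <= 0:
            raise ValueError("physics_cutoff must be > 0")


@dataclass
class DdgResult:
    dG_wt: float
    dG_mut: float
    ddG: float
    flex_zone_size: int
    physics_zone_size: int
    iterations: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


def flexibility_zone(s: Structure, spec: ZoneSpec) -> Selection:
    """Residues ``[site - hw, site + hw]`` clipped to the chain bounds."""
    res = s.res_ids[s.protein_indices]
    lo, hi = int(res.min()), int(res.max())
    if not (lo <= spec.site <= hi) or spec.site not in set(int(x) for x in res):
        raise ValueError(f"mutation site {spec.site} not in the chain ({lo}-{hi})")
    a = max(spec.site - spec.flex_halfwidth, lo)
    b = min(spec.site + spec.flex_halfwidth, hi)
    return Selection(f"flex_{spec.site}", set(range(a, b + 1)))


def physics_zone(s: Structure, flex: Selection, cutoff: float = 12.0) -> Selection:
    """Residues having any bead within ``cutoff`` of any flex-zone bead."""
    flex_idx = apply_selection(s, flex)
    prot = s.protein_indices
    tree = cKDTree(s.coords[prot])
    hits = tree.query_ball_point(s.coords[flex_idx], cutoff)
    res = set()
    for lst in hits:
        res.update(int(s.res_ids[prot[i]]) for i in lst)
    res.update(flex.res_ids)
    return Selection(f"physics_{flex.name}", res)


def _zone_torsion_params(s: Structure, flex_idx: np.ndarray):
    """Pivot triples for local torsion moves inside the zone.

    Rotating about the bond into bead ``i`` moves only the zone beads
    downstream of ``i`` (the remainder of the chain stays frozen), so each
    interior zone residue contributes one rotatable pseudo-bond.
    """
    pivots = []
    for k in range(1, len(flex_idx) - 1):
        pivots.append((int(flex_idx[k - 1]), int(flex_idx[k]), int(flex_idx[-1])))
    return pivots


def _apply_zone_torsions(coords: np.ndarray, pivots, thetas) -> np.ndarray:
    x = coords.copy()
    for (i, j, last), th in zip(pivots, thetas):
        if abs(th) < 1e-12:
            continue
        axis = x[j] - x[i]
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            continue
        axis = axis / nrm
        ca, sa = math.cos(th), math.sin(th)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + sa * K + (1 - ca) * (K @ K)
        seg = slice(j + 1, last + 1)
        x[seg] = (x[seg] - x[j]) @ R.T + x[j]
    return x


def _physics_energy(s: Structure, physics: Selection, p: PotentialSpec,
                    reference: Optional[Structure] = None) -> float:
    idx = apply_selection(s, physics)
    sub = extract(s, idx)
    ref = extract(reference, idx) if reference is not None else None
    total, _, _ = System(sub, p, reference=ref).energy_forces(sub.coords)
    return total


def equilibrate_zone(s: Structure, flex: Selection, physics: Selection,
                     p: PotentialSpec, max_iter: int = 200,
                     reference: Optional[Structure] = None) -> Structure:
    """Relax the flexibility zone in torsion space, freezing everything else.

    The objective is the CG energy of the physics zone; only flex-zone bead
    coordinates change.  The energy never increases (the start is a
    candidate).
    """
    flex_idx = apply_selection(s, flex)
    pivots = _zone_torsion_params(s, flex_idx)
    ref = reference if reference is not None else s
    if not pivots:
        return s.copy()

    def objective(thetas):
        x = _apply_zone_torsions(s.coords, pivots, thetas)
        return _physics_energy(s.with_coords(x), physics, p, reference=ref)

    e0 = objective(np.zeros(len(pivots)))
    res = optimize.minimize(objective, np.zeros(len(pivots)), method="Powell",
                            options={"maxiter": max_iter, "xtol": 1e-4,
                                     "ftol": 1e-8})
    if res.fun <= e0:
        best = res.x
    else:
        best = np.zeros(len(pivots))
    x = _apply_zone_torsions(s.coords, pivots, best)
    return s.with_coords(x)


def ddg_mutation(s: Structure, m: SiteModification, spec: Optional[ZoneSpec],
                 p: Optional[PotentialSpec] = None) -> DdgResult:
    """Zone-equilibrated mutation score, ``ddG = dG_wt - dG_mut``.

    Both states are relaxed with the same zone machinery and scored with the
    CG energy of the physics zone; the wild-type input is left untouched.
    """
    p = p or PotentialSpec()
    spec = spec or ZoneSpec(site=m.res_id)
    if spec.site != m.res_id:
        raise ValueError("zone site and mutation site disagree")
    flex = flexibility_zone(s, spec)
    physics = physics_zone(s, flex, spec.physics_cutoff)

    wt_eq = equilibrate_zone(s, flex, physics, p, reference=s)
    dG_wt = _physics_energy(wt_eq, physics, p, reference=s)

    mut = apply_modification(s, m)
    mut_eq = equilibrate_zone(mut, flex, physics, p, reference=mut)
    dG_mut = _physics_energy(mut_eq, physics, p, reference=mut)

    return DdgResult(
        dG_wt=float(dG_wt), dG_mut=float(dG_mut), ddG=float(dG_wt - dG_mut),
        flex_zone_size=len(flex.res_ids), physics_zone_size=len(physics.res_ids),
        iterations=len(flex.res_ids) - 2,
    )


def ddg_interaction(ab_complex: Structure, a: Structure, b: Structure,
                    dG_kon: float = 0.0, dS_sc: float = 0.0,
                    p: Optional[PotentialSpec] = None) -> float:
    """Interaction energy change of complex formation.

    ``a`` and ``b`` must partition the beads of ``ab_complex`` (checked by
    serial number).  The three dG terms are CG energies of the respective
    structures; ``dG_kon`` and ``dS_sc`` are caller-supplied corrections.
    """
    p = p or PotentialSpec()
    sa, sb = set(a.serials.tolist()), set(b.serials.tolist())
    sab = set(ab_complex.serials.tolist())
    if sa & sb or (sa | sb) != sab:
        raise ValueError("a and b must partition the beads of the complex")
    e_ab, _, _ = System(ab_complex, p).energy_forces(ab_complex.coords)
    e_a, _, _ = System(a, p).energy_forces(a.coords)
    e_b, _, _ = System(b, p).energy_forces(b.coords)
    return float(e_ab - (e_a + e_b) + dG_kon + dS_sc)
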