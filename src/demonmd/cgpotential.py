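"""Coarse-grained force field, restraints and site modifications.

One bead per residue (Calpha), single-bead waters and ions.  Units are fixed
project-wide: lengths in Angstrom, energies in kcal/mol, time in ps,
temperature in K, charge in elementary charges, mass in Dalton.

Energy terms
------------
bond        0.5 * bond_k * (r - bond_r0)^2       chain bonds
angle       0.5 * angle_k * (theta - theta0)^2   consecutive triples; theta0
                                                 from the reference geometry
                                                 unless fixed in the spec
torsion     sum_i A_i * (1 + cos(n_i*phi - phase_i))   optional, default none
LJ          4*eps*((s/r)^12 - (s/r)^6), energy-shifted at the cutoff; the
            per-pair sigma scales with the bead radii so that the minimum of
            a standard Calpha pair (radius 1.9 A each) sits at 3.8 A
coulomb     332.0637*qi*qj/(eps(r)*r), distance-dependent eps(r) = 4r by
            default (so E ~ 83*qi*qj/r^2), energy-shifted at the cutoff,
            optional Debye screening
elastic net 0.5 * en_k * (d - d_ref)^2 for rigid-tagged residue pairs within
            en_cutoff at the reference geometry (vanishes on the reference)
restraints  positional / relative-distance / torsional harmonics, plus an
            optional flat-bottom spherical container for droplet solvent

1-2 and 1-3 nonbonded pairs are excluded; there is no 1-4 scaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral
from .structio import Structure

logger = logging.getLogger("demonmd.cgpotential")

try:  # optional JIT of the pair kernel; the numpy path is the reference
    import numba as _numba
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _numba = None
    _HAVE_NUMBA = False

__all__ = [
    "KB", "COULOMB", "ACCEL",
    "PotentialSpec", "RestraintSet", "SiteModification", "System",
    "energy", "forces", "apply_modification", "zinc_restraints",
    "enm_modes",
]

# Boltzmann constant, kcal/(mol K)
KB = 0.0019872041
# Coulomb constant, kcal A / (mol e^2)
COULOMB = 332.0637
# kcal/(mol A) per Dalton -> A/ps^2
ACCEL = 418.4

# minimum pair distance used when evaluating nonbonded terms; keeps energies
# finite during aggressive line searches (a true overlap still raises)
_R_FLOOR = 0.5
_OVERLAP_TOL = 1e-6


@dataclass(frozen=True)
class PotentialSpec:
    """Force-field parameters.  All force constants kcal/mol based, A, rad."""

    bond_k: float = 100.0
    bond_r0: float = 3.8
    angle_k: float = 5.0
    angle_theta0: Optional[float] = None  # radians; None = reference geometry
    torsions: tuple = ()  # (amplitude kcal/mol, periodicity, phase rad)
    lj_epsilon: float = 0.25
    lj_sigma: float = 3.8 / 2 ** (1 / 6)  # sigma of a standard Calpha pair
    dielectric: str = "distance"  # {"constant", "distance"}
    dielectric_constant: float = 1.0
    debye_length: Optional[float] = None
    nonbonded_cutoff: float = 9.0
    en_cutoff: float = 10.0
    en_k: float = 10.0

    def __post_init__(self):
        for name in ("bond_k", "angle_k", "lj_epsilon", "en_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bond_r0", "lj_sigma", "nonbonded_cutoff", "en_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dielectric not in ("constant", "distance"):
            raise ValueError("dielectric must be 'constant' or 'distance'")
        if self.debye_length is not None and self.debye_length <= 0:
            raise ValueError("debye_length must be > 0")


@dataclass
class RestraintSet:
    """Harmonic restraints; force constants in kcal/(mol A^2) or kcal/mol."""

    positional: list = field(default_factory=list)  # (index, anchor xyz, k)
    relative: list = field(default_factory=list)    # (i, j, d0, k)
    torsional: list = field(default_factory=list)   # ((i,j,k,l), phi0 deg, k)
    container: Optional[tuple] = None               # (center xyz, radius, k)

    def __post_init__(self):
        for idx, _, k in self.positional:
            if k < 0:
                raise ValueError("restraint k must be >= 0")
        for i, j, d0, k in self.relative:
            if k < 0 or d0 < 0:
                raise ValueError("relative restraint needs k >= 0, d0 >= 0")
        for quad, _, k in self.torsional:
            if len(quad) != 4 or k < 0:
                raise ValueError("torsional restraint needs a 4-tuple, k >= 0")

    @classmethod
    def empty(cls) -> "RestraintSet":
        return cls()

    def merged(self, other: "RestraintSet") -> "RestraintSet":
        return RestraintSet(
            positional=self.positional + other.positional,
            relative=self.relative + other.relative,
            torsional=self.torsional + other.torsional,
            container=self.container or other.container,
        )


# kind -> (charge rule, radius delta).  Charge rule is either a float delta or
# "neutralize" (set the site charge to zero, i.e. delta = -q_current).
MODIFICATION_TABLE = {
    "pSer": (-2.0, +0.4),
    "S->D": (-1.0, 0.0),
    "S->E": (-1.0, +0.1),  # one methylene longer than Asp
    "S->A": ("neutralize", -0.2),
    "C->S": (0.0, 0.0),
    "identity": (0.0, 0.0),
}

_MOD_RES_NAMES = {"pSer": "SEP", "S->D": "ASP", "S->E": "GLU",
                  "S->A": "ALA", "C->S": "SER"}


@dataclass(frozen=True)
class SiteModification:
    """A point modification expressed as parameter edits at one residue.

    Phosphoserine is modelled as a -2 charge (dominant protonation state at
    pH 7.4) with a slightly larger bead; the phosphomimetics S->D/S->E carry
    -1; S->A neutralises the site and shrinks the bead.
    """

    res_id: int
    kind: str

    def __post_init__(self):
        if self.kind not in MODIFICATION_TABLE:
            raise ValueError(f"unknown modification kind {self.kind!r}; "
                             f"known: {sorted(MODIFICATION_TABLE)}")
        if self.res_id <= 0:
            raise ValueError("res_id must be positive")


def apply_modification(s: Structure, m: SiteModification) -> Structure:
    """Return a modified copy of ``s``; the input is untouched."""
    idx = np.where((s.res_ids == m.res_id)
                   & np.isin(s.labels.astype(str), ["CA", "P"]))[0]
    if len(idx) == 0:
        raise ValueError(f"residue {m.res_id} not found")
    out = s.copy()
    if m.kind == "identity":
        return out
    charge_rule, dr = MODIFICATION_TABLE[m.kind]
    i = int(idx[0])  # the Calpha bead carries the site parameters
    if charge_rule == "neutralize":
        out.charges[i] = 0.0
    else:
        out.charges[i] += charge_rule
    new_r = out.radii[i] + dr
    if new_r <= 0:
        raise ValueError("modification would make the bead radius non-positive")
    out.radii[i] = new_r
    out.res_names[idx] = _MOD_RES_NAMES.get(m.kind, out.res_names[i])
    return out


def zinc_restraints(s: Structure, rigid_sites: Sequence[Sequence[int]]) -> RestraintSet:
    """Semi-rigid group restraints emulating zinc-finger clamps.

    Each group gets all intra-group pairwise distance restraints at
    k = 50 kcal/(mol A^2) at the *current* distances, so the group can
    translate and rotate freely ("relative to each other, not to coordinate
    space").  Pseudo-torsions of residues flanking the group are softly
    restrained at k = 10 kcal/mol to their current values.
    """
    rel, tors = [], []
    res_of = {int(i): int(s.res_ids[i]) for i in range(s.n_beads)}
    res_to_idx = {}
    for i in range(s.n_beads):
        if str(s.labels[i]) == "CA":
            res_to_idx.setdefault(int(s.res_ids[i]), int(i))
    seen_quads = set()
    for group in rigid_sites:
        group = [int(g) for g in group]
        if len(group) < 2:
            raise ValueError("zinc restraint group must have >= 2 beads")
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                i, j = group[a], group[b]
                d0 = float(np.linalg.norm(s.coords[i] - s.coords[j]))
                rel.append((i, j, d0, 50.0))
        group_res = {res_of[g] for g in group}
        flank = set()
        for r in group_res:
            for n in (r - 1, r + 1):
                if n in res_to_idx and n not in group_res:
                    flank.add(n)
        for r in flank:
            quad_res = (r - 1, r, r + 1, r + 2)
            if not all(q in res_to_idx for q in quad_res):
                continue
            quad = tuple(res_to_idx[q] for q in quad_res)
            if quad in seen_quads:
                continue
            seen_quads.add(quad)
            phi0 = dihedral(*(s.coords[list(quad)]))
            tors.append((quad, phi0, 10.0))
    return RestraintSet(relative=rel, torsional=tors)


# ---------------------------------------------------------------------------
# Compiled system
# ---------------------------------------------------------------------------

class System:
    """A Structure compiled against a PotentialSpec for fast evaluation.

    The reference geometry (angle targets, elastic-network rest lengths) is
    taken from the structure the system is built from, unless an explicit
    ``reference`` structure is supplied — e.g. a biased run keeps the
    elastic network anchored to its starting conformation.
    """

    def __init__(self, structure: Structure, pspec: PotentialSpec,
                 restraints: Optional[RestraintSet] = None,
                 reference: Optional[Structure] = None):
        self.structure = structure
        self.pspec = pspec
        self.restraints = restraints or RestraintSet.empty()
        ref = reference if reference is not None else structure
        if ref.n_beads != structure.n_beads:
            raise ValueError("reference bead count mismatch")
        n = structure.n_beads
        self.n = n
        self.masses = structure.masses.copy()
        self.charges = structure.charges.copy()
        self.radii = structure.radii.copy()

        bonds = structure.bonds()
        self.bonds = bonds
        # consecutive triples / quadruples along the bonded chain
        adj = {}
        for i, j in bonds:
            adj.setdefault(int(i), set()).add(int(j))
            adj.setdefault(int(j), set()).add(int(i))
        angles = []
        for i, j in bonds:
            for k in sorted(adj.get(int(j), ())):
                if k != int(i) and (int(i), int(j)) < (int(j), k):
                    angles.append((int(i), int(j), k))
        self.angles = np.array(angles, dtype=int).reshape(-1, 3)
        quads = []
        for i, j, k in angles:
            for l in sorted(adj.get(k, ())):
                if l != j:
                    quads.append((i, j, k, l))
        self.torsion_quads = np.array(sorted(set(quads)), dtype=int).reshape(-1, 4)

        if pspec.angle_theta0 is None and len(self.angles):
            self.theta0 = _angle_values(ref.coords, self.angles)
        else:
            self.theta0 = np.full(len(self.angles),
                                  pspec.angle_theta0 if pspec.angle_theta0 is not None
                                  else 0.0)

        # 1-2 / 1-3 exclusions, encoded as i*n + j (i < j)
        excl = set()
        for i, j in bonds:
            excl.add(_enc(int(i), int(j), n))
        for i, j, k in self.angles:
            excl.add(_enc(int(i), int(k), n))
        self._exclusions = np.array(sorted(excl), dtype=np.int64)

        # elastic network on rigid-tagged residue beads
        rig = np.where(structure.rigid_mask)[0]
        if len(rig) >= 2:
            tree = cKDTree(ref.coords[rig])
            prs = tree.query_pairs(pspec.en_cutoff, output_type="ndarray")
            gi, gj = rig[prs[:, 0]], rig[prs[:, 1]]
            keep = ~np.isin(_enc(np.minimum(gi, gj), np.maximum(gi, gj), n),
                            self._exclusions)
            self.en_pairs = np.column_stack([gi[keep], gj[keep]])
            self.en_r0 = np.linalg.norm(ref.coords[self.en_pairs[:, 0]]
                                        - ref.coords[self.en_pairs[:, 1]], axis=1)
        else:
            self.en_pairs = np.zeros((0, 2), dtype=int)
            self.en_r0 = np.zeros(0)

        self._bond_i = np.ascontiguousarray(self.bonds[:, 0], dtype=np.int64)
        self._bond_j = np.ascontiguousarray(self.bonds[:, 1], dtype=np.int64)
        self._bond_r0 = np.full(len(self.bonds), pspec.bond_r0)
        self._en_i = np.ascontiguousarray(self.en_pairs[:, 0], dtype=np.int64)
        self._en_j = np.ascontiguousarray(self.en_pairs[:, 1], dtype=np.int64)
        self.en_r0 = np.ascontiguousarray(self.en_r0)

        self._compile_restraints()

    def _compile_restraints(self):
        r = self.restraints
        self._pos_idx = np.array([int(p[0]) for p in r.positional], dtype=int)
        self._pos_anchor = (np.array([p[1] for p in r.positional], dtype=float)
                            .reshape(-1, 3))
        self._pos_k = np.array([p[2] for p in r.positional], dtype=float)
        self._rel = np.array([(p[0], p[1]) for p in r.relative], dtype=int).reshape(-1, 2)
        self._rel_d0 = np.array([p[2] for p in r.relative], dtype=float)
        self._rel_k = np.array([p[3] for p in r.relative], dtype=float)
        self._tors_quads = [tuple(int(q) for q in p[0]) for p in r.torsional]
        self._tors_phi0 = [float(p[1]) for p in r.torsional]
        self._tors_k = [float(p[2]) for p in r.torsional]

    # -- neighbour list ----------------------------------------------------
    def nonbonded_pairs(self, x: np.ndarray, skin: float = 0.0) -> np.ndarray:
        tree = cKDTree(x)
        pairs = tree.query_pairs(self.pspec.nonbonded_cutoff + skin,
                                 output_type="ndarray")
        if len(pairs) == 0:
            return pairs.reshape(-1, 2)
        enc = _enc(pairs[:, 0], pairs[:, 1], self.n)
        return pairs[~np.isin(enc, self._exclusions)]

    def compile_pairs(self, pairs: np.ndarray) -> "PairBlock":
        i = np.ascontiguousarray(pairs[:, 0], dtype=np.int64)
        j = np.ascontiguousarray(pairs[:, 1], dtype=np.int64)
        sig = self.pspec.lj_sigma * (self.radii[i] + self.radii[j]) / 3.8
        return PairBlock(i, j, np.ascontiguousarray(sig ** 6),
                         np.ascontiguousarray(self.charges[i] * self.charges[j]))

    # -- energy / forces ---------------------------------------------------
    def energy_forces(self, x: np.ndarray, pairs: Optional[np.ndarray] = None,
                      check_overlap: bool = True):
        """Return ``(total, forces N x 3, per-term breakdown dict)``."""
        p = self.pspec
        x = np.asarray(x, dtype=float).reshape(self.n, 3)
        F = np.zeros_like(x)
        terms = {}

        # bonds
        e_bond = 0.0
        if len(self.bonds):
            e_bond = _harmonic_pair_kernel(x, self._bond_i, self._bond_j,
                                           self._bond_r0, p.bond_k, F)
        terms["bond"] = e_bond

        # angles
        e_angle = 0.0
        if len(self.angles) and p.angle_k > 0:
            e_angle = self._angle_term(x, F)
        terms["angle"] = e_angle

        # torsions (cosine series over chain quadruples)
        e_tors = 0.0
        if len(self.torsion_quads) and p.torsions:
            for amp, period, phase in p.torsions:
                e_tors += self._torsion_term(x, F, self.torsion_quads,
                                             amp, period, phase)
        terms["torsion"] = e_tors

        # nonbonded
        if pairs is None:
            pairs = self.nonbonded_pairs(x)
        if isinstance(pairs, PairBlock):
            block = pairs
        else:
            block = self.compile_pairs(np.asarray(pairs).reshape(-1, 2))
        e_lj = e_coul = 0.0
        if len(block.i):
            diel_mode = 1 if p.dielectric == "distance" else 0
            debye = p.debye_length if p.debye_length is not None else 0.0
            e_lj, e_coul, min_r2 = _pair_kernel(
                np.ascontiguousarray(x), block.i, block.j, block.sig6, block.qq,
                p.lj_epsilon, p.nonbonded_cutoff, diel_mode,
                p.dielectric_constant, debye, F)
            if check_overlap and min_r2 < _OVERLAP_TOL ** 2:
                raise OverlapError("overlapping beads (distance < 1e-6 A)")
        terms["lj"] = float(e_lj)
        terms["coulomb"] = float(e_coul)

        # elastic network
        e_en = 0.0
        if len(self.en_pairs) and p.en_k > 0:
            e_en = _harmonic_pair_kernel(x, self._en_i, self._en_j,
                                         self.en_r0, p.en_k, F)
        terms["elastic_network"] = e_en

        terms["restraint"] = self._restraint_term(x, F)

        total = float(sum(terms.values()))
        return total, F, terms

    def _angle_term(self, x, F) -> float:
        p = self.pspec
        i, j, k = self.angles[:, 0], self.angles[:, 1], self.angles[:, 2]
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.clip((u * v).sum(axis=1) / (nu * nv), -1 + 1e-10, 1 - 1e-10)
        th = np.arccos(c)
        dth = th - self.theta0
        e = 0.5 * p.angle_k * float(np.sum(dth ** 2))
        # dE/dtheta = k*dth; dtheta/dcos = -1/sin
        s = np.sqrt(1 - c ** 2)
        dEdc = p.angle_k * dth * (-1.0 / s)
        # dcos/du, dcos/dv
        dcdu = (v / (nu * nv)[:, None]) - (c / nu ** 2)[:, None] * u
        dcdv = (u / (nu * nv)[:, None]) - (c / nv ** 2)[:, None] * v
        Fi = -dEdc[:, None] * dcdu
        Fk = -dEdc[:, None] * dcdv
        np.add.at(F, i, Fi)
        np.add.at(F, k, Fk)
        np.add.at(F, j, -(Fi + Fk))
        return e

    def _torsion_term(self, x, F, quads, amp, period, phase) -> float:
        e = 0.0
        for (a, b, c, d) in quads:
            phi = math.radians(dihedral(x[a], x[b], x[c], x[d]))
            e += amp * (1 + math.cos(period * phi - phase))
            dEdphi = -amp * period * math.sin(period * phi - phase)
            self._add_dihedral_force(x, F, (a, b, c, d), dEdphi)
        return float(e)

    def _restraint_torsion_energy(self, x, quad, phi0_deg, k) -> float:
        phi = dihedral(*(x[list(quad)]))
        dphi = (phi - phi0_deg + 180.0) % 360.0 - 180.0
        return 0.5 * k * math.radians(dphi) ** 2

    def _restraint_term(self, x, F) -> float:
        e = 0.0
        if len(self._pos_idx):
            d = x[self._pos_idx] - self._pos_anchor
            e += 0.5 * float(np.sum(self._pos_k * (d ** 2).sum(axis=1)))
            np.add.at(F, self._pos_idx, -self._pos_k[:, None] * d)
        if len(self._rel):
            i, j = self._rel[:, 0], self._rel[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self._rel_d0
            e += 0.5 * float(np.sum(self._rel_k * dr ** 2))
            f = (-self._rel_k * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(F, i, f)
            np.add.at(F, j, -f)
        for quad, phi0, k in zip(self._tors_quads, self._tors_phi0, self._tors_k):
            phi = dihedral(*(x[list(quad)]))
            dphi_deg = (phi - phi0 + 180.0) % 360.0 - 180.0
            dphi = math.radians(dphi_deg)
            e += 0.5 * k * dphi ** 2
            self._add_dihedral_force(x, F, quad, k * dphi)
        if self.restraints.container is not None:
            center, radius, k = self.restraints.container
            center = np.asarray(center, dtype=float)
            d = x - center
            r = np.linalg.norm(d, axis=1)
            over = r - radius
            mask = over > 0
            if np.any(mask):
                e += 0.5 * k * float(np.sum(over[mask] ** 2))
                f = (-k * over[mask] / r[mask])[:, None] * d[mask]
                np.add.at(F, np.where(mask)[0], f)
        return e

    def _add_dihedral_force(self, x, F, quad, dEdphi):
        """Analytic dihedral gradient (standard MD formulation).

        The sign flip matches this package's dihedral sign convention."""
        a, b, c, d = quad
        dEdphi = -dEdphi
        b1 = x[b] - x[a]
        b2 = x[c] - x[b]
        b3 = x[d] - x[c]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        n1sq = max(float(n1 @ n1), 1e-12)
        n2sq = max(float(n2 @ n2), 1e-12)
        nb2 = max(float(np.linalg.norm(b2)), 1e-12)
        fa = -dEdphi * nb2 / n1sq * n1
        fd = dEdphi * nb2 / n2sq * n2
        tb = (float(b3 @ b2) / nb2 ** 2) * fd - (float(b1 @ b2) / nb2 ** 2) * fa
        F[a] += fa
        F[b] += -fa + tb
        F[c] += -fd - tb
        F[d] += fd

    def temperature(self, velocities: np.ndarray, n_constrained_dof: int = 3) -> float:
        ke = 0.5 * float(np.sum(self.masses[:, None] * velocities ** 2)) / ACCEL
        dof = max(3 * self.n - n_constrained_dof, 1)
        return 2.0 * ke / (dof * KB)


class OverlapError(ValueError):
    """Two beads closer than the numerical floor for the LJ term."""


def _enc(i, j, n):
    return np.asarray(i, dtype=np.int64) * n + np.asarray(j, dtype=np.int64)


def _scatter_pair(F, i, j, f, n):
    """Accumulate +f on rows i and -f on rows j (bincount is much faster
    than np.add.at for the pair counts seen here)."""
    for k in range(3):
        F[:, k] += np.bincount(i, weights=f[:, k], minlength=n)
        F[:, k] -= np.bincount(j, weights=f[:, k], minlength=n)


@dataclass
class PairBlock:
    """Precompiled nonbonded pair list (indices, per-pair sigma^6, qi*qj)."""

    i: np.ndarray
    j: np.ndarray
    sig6: np.ndarray
    qq: np.ndarray


def _pair_kernel_py(x, i, j, sig6, qq, eps, rc, diel_mode, diel_const,
                    debye, F):
    """Reference nonbonded kernel: shifted LJ + shifted Coulomb.

    Returns ``(e_lj, e_coulomb, min_r2)``; forces are accumulated into F.
    """
    e_lj = 0.0
    e_c = 0.0
    min_r2 = 1e30
    rc2 = rc * rc
    floor2 = _R_FLOOR * _R_FLOOR
    inv_rc6 = 1.0 / rc2 ** 3
    for k in range(len(i)):
        a = i[k]
        b = j[k]
        dx = x[a, 0] - x[b, 0]
        dy = x[a, 1] - x[b, 1]
        dz = x[a, 2] - x[b, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        if r2 >= rc2:
            continue
        r2e = r2 if r2 > floor2 else floor2
        inv_r2 = 1.0 / r2e
        sr6 = sig6[k] * inv_r2 * inv_r2 * inv_r2
        src6 = sig6[k] * inv_rc6
        e_lj += 4.0 * eps * ((sr6 * sr6 - sr6) - (src6 * src6 - src6))
        # (dU/dr)/r for LJ
        dudr_r = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv_r2
        fpre = -dudr_r
        q = qq[k]
        if q != 0.0:
            r = math.sqrt(r2e)
            if diel_mode == 1:
                pref = COULOMB / 4.0
                u = pref * q * inv_r2
                uc = pref * q / rc2
                dudr = -2.0 * pref * q * inv_r2 / r
            else:
                pref = COULOMB / diel_const
                u = pref * q / r
                uc = pref * q / rc
                dudr = -pref * q * inv_r2
            if debye > 0.0:
                scr = math.exp(-r / debye)
                dudr = dudr * scr - u * scr / debye
                u = u * scr
                uc = uc * math.exp(-rc / debye)
            e_c += u - uc
            fpre += -dudr / r
        fx = fpre * dx
        fy = fpre * dy
        fz = fpre * dz
        F[a, 0] += fx
        F[a, 1] += fy
        F[a, 2] += fz
        F[b, 0] -= fx
        F[b, 1] -= fy
        F[b, 2] -= fz
    return e_lj, e_c, min_r2


def _harmonic_pair_kernel_py(x, i, j, r0, k, F):
    """Harmonic pair term 0.5*k*(r - r0)^2; forces accumulated into F."""
    e = 0.0
    for m in range(len(i)):
        a = i[m]
        b = j[m]
        dx = x[a, 0] - x[b, 0]
        dy = x[a, 1] - x[b, 1]
        dz = x[a, 2] - x[b, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[m]
        e += 0.5 * k * dr * dr
        fpre = -k * dr / (r if r > 1e-12 else 1e-12)
        fx = fpre * dx
        fy = fpre * dy
        fz = fpre * dz
        F[a, 0] += fx
        F[a, 1] += fy
        F[a, 2] += fz
        F[b, 0] -= fx
        F[b, 1] -= fy
        F[b, 2] -= fz
    return e


if _HAVE_NUMBA:
    _pair_kernel = _numba.njit(cache=False, fastmath=True)(_pair_kernel_py)
    _harmonic_pair_kernel = _numba.njit(cache=False, fastmath=True)(
        _harmonic_pair_kernel_py)
else:  # pragma: no cover
    _pair_kernel = _pair_kernel_py
    _harmonic_pair_kernel = _harmonic_pair_kernel_py


def _angle_values(coords, angles):
    i, j, k = angles[:, 0], angles[:, 1], angles[:, 2]
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = (u * v).sum(axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(c, -1.0, 1.0))


def energy(s: Structure, p: PotentialSpec,
           r: Optional[RestraintSet] = None,
           reference: Optional[Structure] = None):
    """Total CG energy and per-term breakdown of a structure.

    Note the reference geometry for angles and the elastic network defaults
    to ``s`` itself; pass ``reference`` to score against a different anchor.
    """
    sys_ = System(s, p, r, reference=reference)
    total, _, terms = sys_.energy_forces(s.coords)
    return total, terms


def forces(s: Structure, p: PotentialSpec,
           r: Optional[RestraintSet] = None,
           reference: Optional[Structure] = None) -> np.ndarray:
    """Analytic forces (negative energy gradient), N x 3 kcal/(mol A)."""
    sys_ = System(s, p, r, reference=reference)
    _, F, _ = sys_.energy_forces(s.coords)
    return F


def enm_modes(s: Structure, cutoff: float = 10.0, n_modes: int = 10,
              k: float = 1.0):
    """Lowest non-trivial normal modes of an anisotropic elastic network.

    Builds the standard ANM Hessian over all protein beads (uniform spring
    ``k`` between pairs within ``cutoff``) and returns ``(frequencies,
    modes)`` where ``modes[m]`` is an ``N x 3`` displacement field for the
    m-th non-trivial mode (the six rigid-body modes are dropped).
    """
    idx = s.protein_indices
    x = s.coords[idx]
    n = len(idx)
    if n < 4:
        raise ValueError("elastic network needs at least 4 beads")
    tree = cKDTree(x)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) < n:
        raise ValueError("elastic network is too sparse; increase the cutoff")
    H = np.zeros((3 * n, 3 * n))
    for a, b in pairs:
        d = x[a] - x[b]
        r2 = float(d @ d)
        blk = -k * np.outer(d, d) / r2
        sa, sb = 3 * a, 3 * b
        H[sa:sa + 3, sb:sb + 3] += blk
        H[sb:sb + 3, sa:sa + 3] += blk
        H[sa:sa + 3, sa:sa + 3] -= blk
        H[sb:sb + 3, sb:sb + 3] -= blk
    vals, vecs = np.linalg.eigh(H)
    order = np.argsort(vals)
    # skip the 6 rigid-body modes (near-zero eigenvalues)
    nontrivial = [m for m in order if vals[m] > 1e-8][:n_modes]
    freqs = np.sqrt(np.maximum(vals[nontrivial], 0.0))
    fields = []
    for m in nontrivial:
        field_full = np.zeros((s.n_beads, 3))
        field_full[idx] = vecs[:, m].reshape(n, 3)
        fields.append(field_full)
    return freqs, fields
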