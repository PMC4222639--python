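"""Synthetic Parkin-like systems, solvation shells and guidepost conformers.

The default generator emulates the architecture the method is exercised on:

* a mobile N-terminal unit (residues 1-76, "UBL-like") built as a compact
  lattice blob, connected through a flexible linker (77-140) whose first
  stretch wraps into a wall facing the UBL blob,
* a rigid, elastic-network-stabilised core (141-465) standing in for the
  zinc-finger RING cassette,
* a cleft between the UBL face and the linker wall whose width responds to
  the charge carried by the bead at residue 65: the wild-type site holds a
  small positive partial charge latched against the negatively charged wall,
  so phosphorylation (-2) or phosphomimetic substitution (-1) turns the
  latch into a repulsive wedge, while the phospho-dead S->A variant merely
  removes the latch,
* optional single-bead waters and ions in a shell for hydration counting.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .cgpotential import PotentialSpec, System, enm_modes
from .dynamics import minimize
from .structio import Structure

logger = logging.getLogger("demonmd.synthgen")

__all__ = ["ToySpec", "SolvationSpec", "GuidepostSet",
           "make_parkin_like", "solvate_shell", "generate_guideposts",
           "default_parkin_plan"]

# lattice constant of the builder: the LJ minimum of a standard Calpha pair,
# so the assembled lattice sits at a comfortable nonbonded geometry
_WALL_CHARGE = -0.5
_SER65_CHARGE = +0.8
_HINGE_CHARGE = +0.25
_CLEFT_GAP = 4.0


def default_parkin_plan() -> list:
    """Domain plan mirroring the Parkin architecture: 1-140 flexible
    (UBL + linker), 141-465 rigid (RING0/RING1/IBR/REP/RING2 core)."""
    return [((1, 140), "flexible"), ((141, 465), "rigid")]


@dataclass(frozen=True)
class ToySpec:
    n_residues: int = 465
    domain_plan: Optional[tuple] = None  # ((first, last), "rigid"|"flexible")
    seed: int = 0
    bond_length: float = 3.8
    ser65_site: Optional[int] = None  # default: 65 when present

    def __post_init__(self):
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")
        plan = self.domain_plan
        if plan is None:
            if self.n_residues == 465:
                plan = tuple((tuple(rng), kind) for rng, kind in default_parkin_plan())
            else:
                half = self.n_residues // 2
                plan = (((1, half), "flexible"), ((half + 1, self.n_residues), "rigid"))
        else:
            plan = tuple((tuple(rng), str(kind)) for rng, kind in plan)
        # plan must tile 1..n_residues
        spans = sorted(rng for rng, _ in plan)
        if spans[0][0] != 1 or spans[-1][1] != self.n_residues:
            raise ValueError("domain plan must cover 1..n_residues")
        for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
            if c != b + 1:
                raise ValueError("domain plan ranges must tile without gaps")
        for (a, b), kind in plan:
            if kind not in ("rigid", "flexible"):
                raise ValueError(f"unknown rigidity class {kind!r}")
        object.__setattr__(self, "domain_plan", plan)
        site = self.ser65_site
        if site is None:
            site = 65 if self.n_residues >= 65 else max(self.n_residues // 4, 1)
        object.__setattr__(self, "ser65_site", int(site))


@dataclass(frozen=True)
class SolvationSpec:
    shell_depth: float = 15.0
    water_density: float = 1.0  # waters per 1000 A^3 of shell volume
    ion_pairs: int = 5          # emulates physiological-strength Na+/Cl-
    seed: int = 0
    r_excl: float = 2.8

    def __post_init__(self):
        if self.shell_depth <= 0:
            raise ValueError("shell_depth must be > 0")
        if self.water_density <= 0:
            raise ValueError("water_density must be > 0")
        if self.ion_pairs < 0:
            raise ValueError("ion_pairs must be >= 0")


class GuidepostSet:
    """Ordered reference structures defining a transition pathway."""

    def __init__(self, posts: Sequence[Structure]):
        self.posts = list(posts)
        if len(self.posts) < 2:
            raise ValueError("a guidepost set needs at least 2 posts")

    def __len__(self):
        return len(self.posts)

    def __getitem__(self, k):
        return self.posts[k]

    def __iter__(self):
        return iter(self.posts)


# ---------------------------------------------------------------------------
# lattice helpers
# ---------------------------------------------------------------------------

def _grid_serpentine(n: int, nx: int, ny: int, a: float) -> np.ndarray:
    """n points on a 3-D boustrophedon lattice path with step ``a``.

    Consecutive points are always one lattice step apart, so the path can be
    used directly as a bonded chain.
    """
    pts = np.zeros((n, 3))
    per_layer = nx * ny
    for b in range(n):
        layer, rem = divmod(b, per_layer)
        if layer % 2 == 1:
            rem = per_layer - 1 - rem
        row, col = divmod(rem, nx)
        if row % 2 == 1:
            col = nx - 1 - col
        pts[b] = (col * a, row * a, layer * a)
    return pts


def _zigzag(n: int, a: float, start: np.ndarray, direction: np.ndarray,
            amp: float = 1.2) -> np.ndarray:
    """Near-straight zigzag chain with exact step ``a``."""
    direction = direction / np.linalg.norm(direction)
    # orthogonal unit vector for the zigzag wiggle
    ortho = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(ortho) < 1e-6:
        ortho = np.cross(direction, [0.0, 1.0, 0.0])
    ortho /= np.linalg.norm(ortho)
    dx = math.sqrt(max(a * a - (2 * amp) ** 2, 0.25 * a * a))
    pts = [np.asarray(start, dtype=float)]
    for k in range(1, n):
        wig = amp if k % 2 else -amp
        pts.append(pts[0] + direction * dx * k + ortho * wig)
    return np.array(pts)


def _tent_path(p0: np.ndarray, p2: np.ndarray, n_interior: int, a: float,
               away: np.ndarray) -> np.ndarray:
    """Interior points of a two-leg detour from ``p0`` to ``p2``.

    The path consumes ``(n_interior + 1) * a`` of chain length by bulging
    toward ``away``; points are sampled at exact spacing ``a`` along the two
    straight legs, so bonds keep their rest length (up to the apex kink).
    """
    total = (n_interior + 1) * a
    d = p2 - p0
    dist = float(np.linalg.norm(d))
    if total <= dist + 0.5 * a:  # nearly straight: interpolate directly
        return np.array([p0 + d * (k / (n_interior + 1))
                         for k in range(1, n_interior + 1)])
    mid = 0.5 * (p0 + p2)
    u = away / np.linalg.norm(away)

    def _bezier_samples(height):
        apex = mid + height * u
        t = np.linspace(0.0, 1.0, 4001)[:, None]
        curve = ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * apex + t ** 2 * p2)
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return curve, arc

    # choose the bulge height so the curve's arc length equals the chain
    # length to consume (monotone in height -> bisection)
    lo_h, hi_h = 0.0, 2.0 * total
    for _ in range(60):
        height = 0.5 * (lo_h + hi_h)
        curve, arc = _bezier_samples(height)
        if arc[-1] < total:
            lo_h = height
        else:
            hi_h = height
    curve, arc = _bezier_samples(0.5 * (lo_h + hi_h))
    targets = np.arange(1, n_interior + 1) * arc[-1] / (n_interior + 1)
    idx = np.searchsorted(arc, targets)
    return curve[np.clip(idx, 0, len(curve) - 1)]


def _default_cleft_layout(spec: ToySpec) -> Tuple[np.ndarray, np.ndarray]:
    """Coordinates + charges for the default 465-residue Parkin-like chain.

    Sandwich architecture, bottom to top:

    * rigid core blob (141-465), elastic-network stabilised;
    * linker wall (97-140) as a one-bead-thick serpentine laminated on the
      core's top face (plain LJ contact), so the wall is mechanically
      supported the way the real linker packs against the RING cassette;
    * UBL blob (1-76) resting on the charged stretch of the wall across the
      cleft gap, anchored at its N-terminal corner (hinge, residues 1-4)
      with the Ser65 latch at the opposite corner;
    * a slack connector loop (77-96) joining UBL to wall on the open side.
    """
    a = spec.bond_length
    n = spec.n_residues
    coords = np.zeros((n, 3))
    charges = np.zeros(n)
    gap = _CLEFT_GAP

    # --- linker wall: residues 97-140, serpentine in the plane y = 0,
    # rows along x (descending), columns along z
    wall = _grid_serpentine(44, 5, 9, a)
    wall_xyz = np.column_stack([26.6 - wall[:, 1],
                                np.zeros(44),
                                wall[:, 0]])
    coords[96:140] = wall_xyz
    wall_end = wall_xyz[-1]

    # --- rigid core: residues 141-465 under the wall (top face at y = -gap),
    # first bead one lattice contact below the wall end (the 140-141 bond);
    # 9 columns so the core face supports the full x-footprint of the wall
    core = _grid_serpentine(325, 9, 6, a)
    core_xyz = np.column_stack([wall_end[0] + core[:, 0],
                                -gap - core[:, 1],
                                wall_end[2] - core[:, 2]])
    coords[140:465] = core_xyz

    # --- UBL blob: residues 1-76 above the charged wall rows, its y-min
    # face (residues 1-4, 61-68, ...) toward the wall across the cleft gap
    ubl = _grid_serpentine(76, 4, 4, a) + np.array([15.2, gap, 0.0])
    coords[0:76] = ubl

    # --- slack connector loop: residues 77-96 bulge away from the assembly
    coords[76:96] = _tent_path(coords[75], coords[96], 20, a,
                               away=np.array([1.0, 0.6, 0.2]))

    # negatively charged wall (residues 97-118), the Ser65 latch charge, and
    # a hinge zipper (residues 1-4) that keeps the UBL anchored at its
    # N-terminal corner in every variant so the latch end controls the cleft
    charges[96:118] = _WALL_CHARGE
    charges[0:4] = _HINGE_CHARGE
    charges[spec.ser65_site - 1] = _SER65_CHARGE
    return coords, charges


def _generic_layout(spec: ToySpec) -> Tuple[np.ndarray, np.ndarray]:
    """Flexible ranges as zigzag strands, rigid ranges as lattice blobs."""
    a = spec.bond_length
    coords = np.zeros((spec.n_residues, 3))
    charges = np.zeros(spec.n_residues)
    cursor = np.zeros(3)
    for (first, last), kind in sorted(spec.domain_plan):
        m = last - first + 1
        if kind == "flexible":
            seg = _zigzag(m, a, cursor, np.array([1.0, 0.0, 0.0]))
        else:
            side = max(int(round(m ** (1 / 3))), 2)
            seg = _grid_serpentine(m, side, side, a) + cursor
        coords[first - 1:last] = seg
        cursor = seg[-1] + np.array([a, 0.0, 0.0])
    if spec.ser65_site <= spec.n_residues:
        charges[spec.ser65_site - 1] = _SER65_CHARGE
    return coords, charges


def make_parkin_like(spec: Optional[ToySpec] = None) -> Structure:
    """Build a self-avoiding Calpha-bead chain per the domain plan.

    Rigid ranges are compact lattice blobs tagged for elastic-network
    restraints; flexible ranges are extended (except the default full-size
    plan, which folds the N-terminal unit against the linker to form the
    Ser65 cleft).  Coordinates carry a small seeded jitter so no two builds
    with different seeds coincide, and the result is bit-reproducible for a
    fixed seed.
    """
    spec = spec or ToySpec()
    is_default = (spec.n_residues == 465
                  and spec.domain_plan == tuple(
                      (tuple(rng), kind) for rng, kind in default_parkin_plan()))
    coords, charges = (_default_cleft_layout(spec) if is_default
                       else _generic_layout(spec))

    rng = np.random.default_rng(spec.seed)
    coords = coords + rng.normal(0.0, 0.08, size=coords.shape)

    rigid = set()
    for (first, last), kind in spec.domain_plan:
        if kind == "rigid":
            rigid.update(range(first, last + 1))

    n = spec.n_residues
    res_names = np.array(["GLY"] * n, dtype=object)
    res_names[spec.ser65_site - 1] = "SER"
    s = Structure(
        serials=np.arange(1, n + 1), res_ids=np.arange(1, n + 1),
        res_names=res_names, labels=np.array(["CA"] * n, dtype=object),
        masses=np.full(n, 110.0), charges=charges, radii=np.full(n, 1.9),
        coords=coords, rigid_res_ids=rigid,
    )
    # self-avoidance audit: non-bonded pairs may not approach closer than 2 A
    tree = cKDTree(s.coords)
    pairs = tree.query_pairs(2.0, output_type="ndarray")
    bad = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) > 1]
    if len(bad):
        raise RuntimeError("builder produced clashing beads; this is a bug")
    return s


def solvate_shell(s: Structure, spec: Optional[SolvationSpec] = None) -> Structure:
    """Append single-bead waters (and +1/-1 ion pairs) in a hydration shell.

    Waters are placed uniformly at random in the region between ``r_excl``
    and ``shell_depth`` from the nearest protein bead, rejection-sampled
    against protein and water-water overlap.
    """
    spec = spec or SolvationSpec()
    rng = np.random.default_rng(spec.seed)
    prot_xyz = s.coords
    tree = cKDTree(prot_xyz)
    lo = prot_xyz.min(axis=0) - spec.shell_depth
    hi = prot_xyz.max(axis=0) + spec.shell_depth
    box_vol = float(np.prod(hi - lo))

    # Monte Carlo estimate of the shell volume to convert density -> count
    probe = rng.uniform(lo, hi, size=(4000, 3))
    d, _ = tree.query(probe)
    frac = float(np.mean((d > spec.r_excl) & (d <= spec.shell_depth)))
    shell_vol = box_vol * frac
    n_waters = max(int(round(spec.water_density * shell_vol / 1000.0)), 0)
    n_total = n_waters + 2 * spec.ion_pairs

    placed = []
    max_tries = 400 * max(n_total, 1)
    tries = 0
    while len(placed) < n_total:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"solvation failed: placed {len(placed)}/{n_total} beads after "
                f"{max_tries} tries; lower water_density or shell_depth")
        pt = rng.uniform(lo, hi)
        d, _ = tree.query(pt)
        if not (spec.r_excl < d <= spec.shell_depth):
            continue
        if placed:
            dd = np.linalg.norm(np.array(placed) - pt, axis=1)
            if np.min(dd) < spec.r_excl:
                continue
        placed.append(pt)

    out = s.copy()
    base_res = int(s.res_ids.max())
    base_serial = int(s.serials.max())
    labels = ["W"] * n_waters + ["NA", "CL"] * spec.ion_pairs
    res_names = ["HOH"] * n_waters + ["NA", "CL"] * spec.ion_pairs
    masses = [18.0] * n_waters + [23.0, 35.5] * spec.ion_pairs
    q = [0.0] * n_waters + [1.0, -1.0] * spec.ion_pairs
    radii = [1.4] * n_waters + [1.2, 1.8] * spec.ion_pairs
    return Structure(
        serials=np.concatenate([s.serials, base_serial + np.arange(1, n_total + 1)]),
        res_ids=np.concatenate([s.res_ids, base_res + np.arange(1, n_total + 1)]),
        res_names=np.concatenate([s.res_names, np.array(res_names, dtype=object)]),
        labels=np.concatenate([s.labels, np.array(labels, dtype=object)]),
        masses=np.concatenate([s.masses, masses]),
        charges=np.concatenate([s.charges, q]),
        radii=np.concatenate([s.radii, radii]),
        coords=np.vstack([s.coords, np.array(placed).reshape(-1, 3)]),
        chain_id=s.chain_id, rigid_res_ids=set(s.rigid_res_ids),
    )


def generate_guideposts(s: Structure, n_posts: int = 5, amplitude: float = 12.0,
                        seed: int = 0,
                        pspec: Optional[PotentialSpec] = None,
                        min_iter: int = 120) -> GuidepostSet:
    """Low-mode conformers at evenly spaced amplitudes along the pathway.

    Builds the elastic-network normal-mode basis on the Calpha network,
    combines the three lowest non-trivial modes with seeded weights, zeroes
    the displacement on the rigid core, and displaces the flexible region in
    ``n_posts`` evenly spaced increments up to ``amplitude`` (flexible-region
    RMS displacement, A).  Each conformer is energy-minimised against the
    starting reference; the first guidepost is the minimised start.
    """
    if n_posts < 2:
        raise ValueError("n_posts must be >= 2")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    pspec = pspec or PotentialSpec()
    flex = ~s.rigid_mask & np.isin(s.labels.astype(str), ["CA", "P"])
    if not np.any(flex):
        raise ValueError("structure has no flexible region to displace")
    rng = np.random.default_rng(seed)
    _, modes = enm_modes(s, cutoff=pspec.en_cutoff, n_modes=3)
    weights = rng.uniform(0.5, 1.0, size=len(modes)) * rng.choice([-1, 1], len(modes))
    direction = sum(w * m for w, m in zip(weights, modes))
    direction[~flex] = 0.0
    rms = math.sqrt(float((direction[flex] ** 2).sum()) / flex.sum())
    if rms < 1e-9:
        raise ValueError("lowest modes do not move the flexible region")
    direction = direction / rms

    sys_ = System(s, pspec)  # reference geometry anchored at the start
    posts = []
    for k in range(n_posts):
        disp = direction * amplitude * (k / (n_posts - 1))
        trial = s.with_coords(s.coords + disp)
        res = minimize(trial, pspec, system=sys_, max_iter=min_iter)
        posts.append(res.structure)
    return GuidepostSet(posts)
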