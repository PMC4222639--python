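"""Structures, trajectories and named residue selections.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
set of coarse-grained beads (one per residue for protein, one per water/ion),
and a :class:`Trajectory` is a stack of coordinate frames sharing one
topology.  Files are exchanged as a fixed-column PDB dialect:

* one ``ATOM`` record per protein bead (label ``CA`` or ``P``),
* waters and ions as ``HETATM`` (labels ``W``, ``NA``, ``CL``),
* the partial charge of a bead is stored in the B-factor column,
* the occupancy column carries the rigid tag (2.00 = rigid, 1.00 = flexible),
* trajectories are multi-model PDB (``MODEL``/``ENDMDL``) with the frame time
  in a ``REMARK   6 TIME`` record.

This keeps every artifact human-readable and round-trippable without any
binary sidecar.  Residue numbering is 1-based UniProt-style throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger("demonmd.structio")

__all__ = [
    "Bead",
    "Structure",
    "Trajectory",
    "Selection",
    "DomainMap",
    "PDBParseError",
    "SelectionError",
    "InvalidResidueError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "parkin_selections",
    "apply_selection",
    "extract",
]


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


class SelectionError(ValueError):
    """Base class for selection application failures."""


class InvalidResidueError(SelectionError):
    """Selection references residues absent from the structure."""


class EmptySelectionError(SelectionError):
    """Selection is valid but matches no beads (e.g. label filter)."""


# Default bead parameters by atom label: (mass Da, radius A, charge e).
# Unknown labels fall back to a generic residue bead (logged once per read).
DEFAULT_BEAD_PARAMS = {
    "CA": (110.0, 1.9, 0.0),
    "P": (95.0, 2.3, -2.0),   # phosphate pseudo-bead
    "W": (18.0, 1.4, 0.0),    # single-bead water
    "NA": (23.0, 1.2, 1.0),
    "CL": (35.5, 1.8, -1.0),
}
_FALLBACK_PARAMS = (110.0, 1.9, 0.0)

PROTEIN_LABELS = frozenset({"CA", "P"})


@dataclass(frozen=True)
class Bead:
    serial: int
    res_id: int
    res_name: str
    atom_label: str
    mass: float
    charge: float
    radius: float
    xyz: np.ndarray

    def __post_init__(self):
        if self.serial <= 0:
            raise ValueError(f"serial must be positive, got {self.serial}")
        if self.res_id <= 0:
            raise ValueError(f"res_id must be positive, got {self.res_id}")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))


class Structure:
    """Ordered beads with vectorised attribute access.

    Attributes are exposed as numpy arrays (``coords``, ``masses``,
    ``charges``, ``radii``, ``res_ids``, ``serials``, ``labels``,
    ``res_names``).  ``rigid_res_ids`` tags residues that belong to the
    restraint-stabilised core (elastic-network springs apply between them).
    Bonded topology is the implicit chain: consecutive protein beads with
    consecutive or equal res_ids are bonded; waters and ions are free.
    """

    def __init__(
        self,
        serials: Sequence[int],
        res_ids: Sequence[int],
        res_names: Sequence[str],
        labels: Sequence[str],
        masses: Sequence[float],
        charges: Sequence[float],
        radii: Sequence[float],
        coords: np.ndarray,
        chain_id: str = "A",
        box: Optional[np.ndarray] = None,
        rigid_res_ids: Optional[set] = None,
    ):
        self.serials = np.asarray(serials, dtype=int)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.res_names = np.asarray(res_names, dtype=object)
        self.labels = np.asarray(labels, dtype=object)
        self.masses = np.asarray(masses, dtype=float)
        self.charges = np.asarray(charges, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.chain_id = chain_id
        self.box = None if box is None else np.asarray(box, dtype=float)
        self.rigid_res_ids = set() if rigid_res_ids is None else set(rigid_res_ids)
        self._validate()

    def _validate(self):
        n = len(self.serials)
        for name in ("res_ids", "res_names", "labels", "masses", "charges", "radii"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be N x 3")
        if len(np.unique(self.serials)) != n:
            raise ValueError("duplicate serial in Structure")
        if np.any(self.serials <= 0) or np.any(self.res_ids <= 0):
            raise ValueError("serials and res_ids must be positive")
        if np.any(self.masses <= 0) or np.any(self.radii <= 0):
            raise ValueError("masses and radii must be > 0")
        prot = self.protein_indices
        if len(prot) > 1 and np.any(np.diff(self.res_ids[prot]) < 0):
            raise ValueError("res_id must be non-decreasing along the protein chain")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_beads(cls, beads: Iterable[Bead], chain_id: str = "A",
                   rigid_res_ids: Optional[set] = None) -> "Structure":
        beads = list(beads)
        if not beads:
            raise ValueError("cannot build a Structure from zero beads")
        return cls(
            [b.serial for b in beads],
            [b.res_id for b in beads],
            [b.res_name for b in beads],
            [b.atom_label for b in beads],
            [b.mass for b in beads],
            [b.charge for b in beads],
            [b.radius for b in beads],
            np.array([b.xyz for b in beads], dtype=float),
            chain_id=chain_id,
            rigid_res_ids=rigid_res_ids,
        )

    # -- accessors --------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.serials)

    @property
    def beads(self) -> list:
        return [
            Bead(int(self.serials[i]), int(self.res_ids[i]), str(self.res_names[i]),
                 str(self.labels[i]), float(self.masses[i]), float(self.charges[i]),
                 float(self.radii[i]), self.coords[i].copy())
            for i in range(self.n_beads)
        ]

    @property
    def protein_indices(self) -> np.ndarray:
        return np.where(np.isin(self.labels.astype(str), list(PROTEIN_LABELS)))[0]

    @property
    def water_indices(self) -> np.ndarray:
        return np.where(self.labels.astype(str) == "W")[0]

    @property
    def rigid_mask(self) -> np.ndarray:
        if not self.rigid_res_ids:
            return np.zeros(self.n_beads, dtype=bool)
        prot = np.isin(self.labels.astype(str), list(PROTEIN_LABELS))
        return prot & np.isin(self.res_ids, sorted(self.rigid_res_ids))

    def bonds(self) -> np.ndarray:
        """Chain bonds as an array of index pairs (protein beads only)."""
        prot = self.protein_indices
        pairs = []
        for a, b in zip(prot[:-1], prot[1:]):
            if 0 <= self.res_ids[b] - self.res_ids[a] <= 1:
                pairs.append((a, b))
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def copy(self) -> "Structure":
        return Structure(
            self.serials.copy(), self.res_ids.copy(), self.res_names.copy(),
            self.labels.copy(), self.masses.copy(), self.charges.copy(),
            self.radii.copy(), self.coords.copy(), chain_id=self.chain_id,
            box=None if self.box is None else self.box.copy(),
            rigid_res_ids=set(self.rigid_res_ids),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(self.n_beads, 3)
        return out

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return (
            np.array_equal(self.serials, other.serials)
            and np.array_equal(self.res_ids, other.res_ids)
            and np.array_equal(self.res_names, other.res_names)
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.masses, other.masses)
            and np.allclose(self.charges, other.charges)
            and np.allclose(self.radii, other.radii)
            and np.allclose(self.coords, other.coords)
        )

    def __repr__(self) -> str:
        return f"<Structure {self.n_beads} beads, chain {self.chain_id}>"


class Trajectory:
    """Ordered coordinate frames over one Structure topology."""

    def __init__(self, topology: Structure, times: Sequence[float],
                 frames: Sequence[np.ndarray]):
        self.topology = topology
        self.times = np.asarray(times, dtype=float)
        self.frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one frame")
        n = topology.n_beads
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {k} has {f.shape[0]} beads, topology has {n}")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def structure_at(self, k: int) -> Structure:
        return self.topology.with_coords(self.frames[k])

    def __iter__(self):
        return iter(self.frames)

    @staticmethod
    def concatenate(parts: Sequence["Trajectory"]) -> "Trajectory":
        parts = [p for p in parts if p is not None]
        if not parts:
            raise ValueError("nothing to concatenate")
        topo = parts[0].topology
        times, frames = [], []
        offset = 0.0
        for p in parts:
            for t, f in zip(p.times, p.frames):
                times.append(offset + t)
                frames.append(f)
            offset = times[-1]
        return Trajectory(topo, times, frames)


@dataclass(frozen=True)
class Selection:
    """A named set of residues, optionally filtered by atom label."""

    name: str
    res_ids: frozenset = field(default_factory=frozenset)
    atom_labels: Optional[frozenset] = None

    def __post_init__(self):
        object.__setattr__(self, "res_ids", frozenset(int(r) for r in self.res_ids))
        if self.atom_labels is not None:
            object.__setattr__(self, "atom_labels", frozenset(self.atom_labels))
        if not self.res_ids:
            raise ValueError(f"selection {self.name!r} is empty")
        if any(r <= 0 for r in self.res_ids):
            raise ValueError(f"selection {self.name!r} has non-positive residues")


@dataclass(frozen=True)
class DomainMap:
    """Half-open residue ranges ``name -> [start, stop)`` tiling the chain."""

    ranges: dict

    def __post_init__(self):
        spans = sorted(self.ranges.values())
        for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
            if b != c:
                raise ValueError("domain ranges must be contiguous and non-overlapping")
        for a, b in spans:
            if b <= a:
                raise ValueError("empty domain range")

    @property
    def first_residue(self) -> int:
        return min(a for a, _ in self.ranges.values())

    @property
    def last_residue(self) -> int:
        return max(b for _, b in self.ranges.values()) - 1

    def residues(self, name: str) -> frozenset:
        a, b = self.ranges[name]
        return frozenset(range(a, b))

    def selection(self, name: str) -> Selection:
        return Selection(name, self.residues(name))

    def domain_of(self, res_id: int) -> str:
        for name, (a, b) in self.ranges.items():
            if a <= res_id < b:
                return name
        raise KeyError(f"residue {res_id} not covered by the domain map")


# ---------------------------------------------------------------------------
# Parkin selection registry (residue lists as printed in the source structure
# analysis: cleft walls between the UBL and the linker, the two centre-of-mass
# groups flanking Ser65, the E2-binding patch on RING1, and single-residue
# probes used for domain-distance metrics).
# ---------------------------------------------------------------------------

PARKIN_DOMAINS = DomainMap({
    "UBL": (1, 77),
    "linker": (77, 141),
    "RING0": (141, 217),
    "RING1": (217, 329),
    "IBR": (329, 379),
    "REP": (379, 411),
    "RING2": (411, 466),
})


def parkin_selections() -> dict:
    """Named selections for the human Parkin residue numbering (1-465).

    Returns a registry mapping selection names to :class:`Selection` objects,
    with the entry ``"domains"`` holding the :class:`DomainMap`.
    """
    reg = {
        "cleft_wall_1": Selection("cleft_wall_1",
                                  {97, 105, 110, 111, 112, 115, 116, 117, 118}),
        "cleft_wall_2": Selection("cleft_wall_2",
                                  {1, 2, 3, 4, 19, 61, 62, 63, 64, 66, 67}),
        "CoM1": Selection("CoM1", {110, 111, 115}),
        "CoM2": Selection("CoM2", {1, 2, 3, 4, 63}),
        "e2_site": Selection("e2_site",
                             {236, 237, 238, 239, 240, 241, 242, 243, 244, 245,
                              259, 260, 261, 262, 263, 264, 265, 266, 267}),
        "rep_ring1_core": Selection("rep_ring1_core", {238, 240, 241, 263}),
        "Ser65": Selection("Ser65", {65}),
        "Leu26": Selection("Leu26", {26}),
        "Cys238": Selection("Cys238", {238}),
        "Phe364": Selection("Phe364", {364}),
        "Tyr391": Selection("Tyr391", {391}),
        "Cys431": Selection("Cys431", {431}),
        "Arg163": Selection("Arg163", {163}),
        "rigid_core": Selection("rigid_core", set(range(141, 466))),
        "flexible_nterm": Selection("flexible_nterm", set(range(1, 141))),
    }
    reg["domains"] = PARKIN_DOMAINS
    return reg


def selections_to_json(path) -> None:
    """Export the Parkin selection registry as JSON."""
    reg = parkin_selections()
    payload = {}
    for name, sel in reg.items():
        if isinstance(sel, Selection):
            payload[name] = sorted(sel.res_ids)
    payload["domains"] = {k: list(v) for k, v in PARKIN_DOMAINS.ranges.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def apply_selection(s: Structure, sel: Selection) -> np.ndarray:
    """Indices of beads matched by ``sel``, in bead order.

    Raises :class:`InvalidResidueError` if the selection references residues
    the structure does not have, and :class:`EmptySelectionError` if the
    residues exist but the label filter removes every bead.
    """
    present = set(int(r) for r in np.unique(s.res_ids))
    missing = set(sel.res_ids) - present
    if missing:
        raise InvalidResidueError(
            f"selection {sel.name!r}: residues {sorted(missing)[:8]} not in structure")
    mask = np.isin(s.res_ids, sorted(sel.res_ids))
    if sel.atom_labels is not None:
        mask &= np.isin(s.labels.astype(str), sorted(sel.atom_labels))
    else:
        # default: protein beads only, so waters sharing res_ids never leak in
        mask &= np.isin(s.labels.astype(str), list(PROTEIN_LABELS))
    idx = np.where(mask)[0]
    if len(idx) == 0:
        raise EmptySelectionError(f"selection {sel.name!r} matched no beads")
    return idx


def extract(s: Structure, indices: Sequence[int]) -> Structure:
    """Sub-structure containing only the given bead indices (order kept)."""
    idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
    if len(idx) == 0:
        raise ValueError("cannot extract an empty sub-structure")
    return Structure(
        s.serials[idx], s.res_ids[idx], s.res_names[idx], s.labels[idx],
        s.masses[idx], s.charges[idx], s.radii[idx], s.coords[idx],
        chain_id=s.chain_id,
        rigid_res_ids=set(s.rigid_res_ids) & set(int(r) for r in s.res_ids[idx]),
    )


# ---------------------------------------------------------------------------
# PDB dialect
# ---------------------------------------------------------------------------

def _format_atom(i: int, s: Structure) -> str:
    label = str(s.labels[i])
    record = "ATOM  " if label in PROTEIN_LABELS else "HETATM"
    name = label if len(label) >= 4 else f" {label:<3s}"
    occ = 2.0 if (label in PROTEIN_LABELS and int(s.res_ids[i]) in s.rigid_res_ids) else 1.0
    x, y, z = s.coords[i]
    return (
        f"{record}{int(s.serials[i]):5d} {name:<4s}{'':1s}{str(s.res_names[i]):>3s} "
        f"{s.chain_id:1s}{int(s.res_ids[i]):4d}{'':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{float(s.charges[i]):6.2f}"
    )


def _structure_lines(s: Structure) -> list:
    return [_format_atom(i, s) for i in range(s.n_beads)]


def write_pdb(s: Structure, path) -> None:
    """Write a Structure in the fixed-column CG PDB dialect."""
    lines = _structure_lines(s) + ["END"]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip() or "UNK"
        chain = line[21] if len(line) > 21 and line[21].strip() else "A"
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    occ_field = line[54:60].strip()
    bfac_field = line[60:66].strip()
    occ = float(occ_field) if occ_field else 1.0
    charge_col = float(bfac_field) if bfac_field else None
    return serial, name, res_name, chain, res_id, (x, y, z), occ, charge_col


def read_pdb(path) -> Structure:
    """Read a single-model PDB file into a Structure.

    Unknown atom labels fall back to a generic 110 Da / 1.9 A bead (warned).
    The B-factor column, when present, overrides the default bead charge;
    occupancy >= 1.5 tags the residue as rigid-core.
    """
    path = Path(path)
    text = path.read_text()
    serials, res_ids, res_names, labels = [], [], [], []
    masses, charges, radii, coords = [], [], [], []
    chain = "A"
    rigid = set()
    warned_labels = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        serial, name, res_name, ch, res_id, xyz, occ, qcol = _parse_atom_line(line, lineno)
        mass, radius, q_default = DEFAULT_BEAD_PARAMS.get(name, _FALLBACK_PARAMS)
        if name not in DEFAULT_BEAD_PARAMS and name not in warned_labels:
            logger.warning("unknown atom label %r at line %d: using default bead "
                           "(mass 110 Da, radius 1.9 A)", name, lineno)
            warned_labels.add(name)
        serials.append(serial)
        res_ids.append(res_id)
        res_names.append(res_name)
        labels.append(name)
        masses.append(mass)
        charges.append(q_default if qcol is None else qcol)
        radii.append(radius)
        coords.append(xyz)
        chain = ch
        if occ >= 1.5 and name in PROTEIN_LABELS:
            rigid.add(res_id)
    if not serials:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if len(set(serials)) != len(serials):
        raise PDBParseError(f"{path}: duplicate atom serial")
    return Structure(serials, res_ids, res_names, labels, masses, charges,
                     radii, np.array(coords), chain_id=chain, rigid_res_ids=rigid)


def write_trajectory(t: Trajectory, path) -> None:
    """Write a Trajectory as multi-model PDB (one MODEL per frame)."""
    if t.n_frames == 0:
        raise ValueError("empty frame list")
    out = []
    topo = t.topology
    for k in range(t.n_frames):
        out.append(f"MODEL {k + 1:8d}")
        out.append(f"REMARK   6 TIME {t.times[k]:.6f}")
        out.extend(_structure_lines(topo.with_coords(t.frames[k])))
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def _read_xyz_trajectory(path) -> Trajectory:
    """Whitespace-delimited XYZ alternative: repeated (N, comment, N lines)."""
    lines = Path(path).read_text().split("\n")
    i, frames, times = 0, [], []
    labels = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        block = lines[i + 2:i + 2 + n]
        lab, xyz = [], []
        for row in block:
            parts = row.split()
            lab.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        labels = lab
        frames.append(np.array(xyz))
        tok = comment.split()
        times.append(float(tok[-1]) if tok and _is_float(tok[-1]) else float(len(times)))
        i += 2 + n
    if not frames:
        raise PDBParseError(f"{path}: empty XYZ file")
    n = len(labels)
    params = [DEFAULT_BEAD_PARAMS.get(l, _FALLBACK_PARAMS) for l in labels]
    topo = Structure(
        serials=list(range(1, n + 1)), res_ids=list(range(1, n + 1)),
        res_names=["UNK"] * n, labels=labels,
        masses=[p[0] for p in params], charges=[p[2] for p in params],
        radii=[p[1] for p in params], coords=frames[0],
    )
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = list(range(len(frames)))
    return Trajectory(topo, times, frames)


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_trajectory(path) -> Trajectory:
    """Read a multi-model PDB (or whitespace XYZ) trajectory."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return _read_xyz_trajectory(path)
    text = path.read_text()
    blocks, times = [], []
    current, current_time = [], None
    in_model = False
    topo = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, current, current_time = True, [], None
        elif rec == "ENDMDL":
            if not current:
                raise PDBParseError(f"line {lineno}: MODEL with no atoms")
            blocks.append(current)
            times.append(current_time)
            in_model = False
        elif line.startswith("REMARK   6 TIME"):
            current_time = float(line.split()[-1])
        elif rec in ("ATOM", "HETATM"):
            if not in_model:
                in_model, current, current_time = True, [], None
            current.append((lineno, line))
    if in_model and current:
        blocks.append(current)
        times.append(current_time)
    if not blocks:
        raise PDBParseError(f"{path}: no frames found")
    frames = []
    for k, block in enumerate(blocks):
        xyz = []
        for lineno, line in block:
            _, _, _, _, _, pos, _, _ = _parse_atom_line(line, lineno)
            xyz.append(pos)
        frames.append(np.array(xyz))
        if k == 0:
            topo = _structure_from_lines([line for _, line in block])
    if any(t is None for t in times):
        times = list(range(len(frames)))
    return Trajectory(topo, times, frames)


def _structure_from_lines(lines) -> Structure:
    serials, res_ids, res_names, labels = [], [], [], []
    masses, charges, radii, coords = [], [], [], []
    chain = "A"
    rigid = set()
    for lineno, line in enumerate(lines, start=1):
        serial, name, res_name, ch, res_id, xyz, occ, qcol = _parse_atom_line(line, lineno)
        mass, radius, q_default = DEFAULT_BEAD_PARAMS.get(name, _FALLBACK_PARAMS)
        serials.append(serial)
        res_ids.append(res_id)
        res_names.append(res_name)
        labels.append(name)
        masses.append(mass)
        charges.append(q_default if qcol is None else qcol)
        radii.append(radius)
        coords.append(xyz)
        chain = ch
        if occ >= 1.5 and name in PROTEIN_LABELS:
            rigid.add(res_id)
    return Structure(serials, res_ids, res_names, labels, masses, charges,
                     radii, np.array(coords), chain_id=chain, rigid_res_ids=rigid)
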