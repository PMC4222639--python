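"""Trajectory metrics: centre-of-mass distances, SASA, pocket hydration,
pair distances, RMSD/RMSF series and backbone pseudo-dihedrals.

All metrics are invariant under global rotation and translation of each
frame.  Series are returned as :class:`MetricSeries`, exportable to CSV
(time, value, units header) and JSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral, kabsch_rmsd, superpose
from .structio import (Selection, Structure, Trajectory, apply_selection)

logger = logging.getLogger("demonmd.trajmetrics")

__all__ = ["MetricSeries", "com_distance", "com_distance_series", "sasa",
           "count_pocket_waters", "pocket_water_series", "pair_distance",
           "pair_distance_series", "rmsd_series", "rmsf", "phi_psi",
           "sasa_series"]


@dataclass
class MetricSeries:
    name: str
    times: np.ndarray
    values: np.ndarray
    units: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        lines = [f"time_ps,{self.name}_{self.units}"]
        lines += [f"{t:.6f},{v:.6f}" for t, v in zip(self.times, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "units": self.units,
                           "times_ps": self.times.tolist(),
                           "values": self.values.tolist()})

    def mean_final_fraction(self, fraction: float = 1 / 3) -> float:
        """Mean over the final ``fraction`` of the series (steady-state read)."""
        k = max(int(math.ceil(len(self.values) * fraction)), 1)
        return float(np.mean(self.values[-k:]))


def _centroid(s: Structure, idx: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "mass":
        w = s.masses[idx]
    elif weighting == "geometric":
        w = np.ones(len(idx))
    else:
        raise ValueError("weighting must be 'mass' or 'geometric'")
    return (w[:, None] * s.coords[idx]).sum(axis=0) / w.sum()


def com_distance(frame: Structure, selA: Selection, selB: Selection,
                 weighting: str = "mass") -> float:
    """Distance between the (mass-)weighted centroids of two selections."""
    ia = apply_selection(frame, selA)
    ib = apply_selection(frame, selB)
    if set(ia.tolist()) & set(ib.tolist()):
        raise ValueError("selections overlap")
    return float(np.linalg.norm(_centroid(frame, ia, weighting)
                                - _centroid(frame, ib, weighting)))


def com_distance_series(traj: Trajectory, selA: Selection, selB: Selection,
                        weighting: str = "mass",
                        name: str = "com_distance") -> MetricSeries:
    vals = [com_distance(traj.structure_at(k), selA, selB, weighting)
            for k in range(traj.n_frames)]
    return MetricSeries(name, traj.times, vals, "A")


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(s: Structure, probe: float = 1.4, n_sphere_points: int = 960,
         selection: Optional[Selection] = None):
    """Shrake-Rupley solvent-accessible surface area.

    Returns ``(per_bead, total)`` in A^2; ``selection`` restricts both the
    reported beads and the total (neighbours still occlude regardless).
    """
    if n_sphere_points < 16:
        raise ValueError("n_sphere_points must be >= 16")
    pts = _sphere_points(n_sphere_points)
    radii = s.radii + probe
    coords = s.coords
    tree = cKDTree(coords)
    if selection is None:
        targets = np.arange(s.n_beads)
    else:
        targets = apply_selection(s, selection)
    rmax = float(radii.max())
    per_bead = np.zeros(len(targets))
    for t, i in enumerate(targets):
        ri = radii[i]
        surf = coords[i] + ri * pts
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in nbrs:
            d = surf - coords[j]
            exposed &= (d ** 2).sum(axis=1) > radii[j] ** 2
            if not exposed.any():
                break
        per_bead[t] = 4 * math.pi * ri * ri * exposed.mean()
    return per_bead, float(per_bead.sum())


def sasa_series(traj: Trajectory, selection: Selection, probe: float = 1.4,
                n_sphere_points: int = 240,
                name: str = "sasa") -> MetricSeries:
    vals = [sasa(traj.structure_at(k), probe, n_sphere_points, selection)[1]
            for k in range(traj.n_frames)]
    return MetricSeries(name, traj.times, vals, "A2")


# ---------------------------------------------------------------------------
# pocket hydration
# ---------------------------------------------------------------------------

def count_pocket_waters(frame: Structure, pocket: Selection,
                        cutoff: float = 5.0) -> int:
    """Waters within ``cutoff`` of any pocket-residue bead (counted once)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    waters = frame.water_indices
    if len(waters) == 0:
        logger.info("frame contains no waters; pocket count is 0")
        return 0
    if cutoff == 0:
        return 0
    pocket_idx = apply_selection(frame, pocket)
    tree = cKDTree(frame.coords[pocket_idx])
    d, _ = tree.query(frame.coords[waters])
    return int(np.sum(d <= cutoff))


def pocket_water_series(traj: Trajectory, pocket: Selection,
                        cutoff: float = 5.0,
                        name: str = "pocket_waters") -> MetricSeries:
    vals = [count_pocket_waters(traj.structure_at(k), pocket, cutoff)
            for k in range(traj.n_frames)]
    return MetricSeries(name, traj.times, vals, "count")


# ---------------------------------------------------------------------------
# distances, RMSD, RMSF
# ---------------------------------------------------------------------------

def _resolve_probe(s: Structure, probe: Tuple[int, str]) -> int:
    res_id, label = probe
    idx = np.where((s.res_ids == res_id) & (s.labels.astype(str) == label))[0]
    if len(idx) == 0:
        raise ValueError(f"probe ({res_id}, {label!r}) not found")
    if len(idx) > 1:
        raise ValueError(f"probe ({res_id}, {label!r}) is ambiguous")
    return int(idx[0])


def pair_distance(frame: Structure, probeA: Tuple[int, str],
                  probeB: Tuple[int, str]) -> float:
    ia, ib = _resolve_probe(frame, probeA), _resolve_probe(frame, probeB)
    return float(np.linalg.norm(frame.coords[ia] - frame.coords[ib]))


def pair_distance_series(traj: Trajectory, probeA: Tuple[int, str],
                         probeB: Tuple[int, str],
                         name: str = "pair_distance") -> MetricSeries:
    ia = _resolve_probe(traj.topology, probeA)
    ib = _resolve_probe(traj.topology, probeB)
    vals = [float(np.linalg.norm(f[ia] - f[ib])) for f in traj.frames]
    return MetricSeries(name, traj.times, vals, "A")


def rmsd_series(traj: Trajectory, ref: Structure,
                sel: Optional[Selection] = None,
                name: str = "rmsd") -> MetricSeries:
    """Per-frame Kabsch RMSD to a reference over a selection."""
    if sel is None:
        idx = np.where(traj.topology.labels.astype(str) == "CA")[0]
        idx_ref = np.where(ref.labels.astype(str) == "CA")[0]
    else:
        idx = apply_selection(traj.topology, sel)
        idx_ref = apply_selection(ref, sel)
    if len(idx) != len(idx_ref):
        raise ValueError("selection maps to different counts in traj and ref")
    refc = ref.coords[idx_ref]
    vals = [kabsch_rmsd(f[idx], refc) for f in traj.frames]
    return MetricSeries(name, traj.times, vals, "A")


def rmsf(traj: Trajectory, sel: Optional[Selection] = None,
         n_mean_iterations: int = 2):
    """Per-bead root-mean-square fluctuation about the mean structure.

    Frames are superposed on the selection onto the running mean structure
    (iterated ``n_mean_iterations`` times), then RMSF is the per-bead RMS
    deviation from the time-mean position.  Returns ``(res_ids, rmsf)``.
    """
    topo = traj.topology
    if sel is None:
        idx = np.where(topo.labels.astype(str) == "CA")[0]
    else:
        idx = apply_selection(topo, sel)
    X = np.array([f[idx] for f in traj.frames])
    mean = X[0].copy()
    for _ in range(max(n_mean_iterations, 1)):
        aligned = np.array([superpose(x, mean) for x in X])
        mean = aligned.mean(axis=0)
    dev = aligned - mean
    vals = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    return topo.res_ids[idx].copy(), vals


def phi_psi(s: Structure) -> List[Tuple[float, float]]:
    """Backbone pseudo-dihedral pairs from consecutive Calpha quadruples.

    With one bead per residue, residue ``i`` gets the pseudo-phi from beads
    (i-2, i-1, i, i+1) and pseudo-psi from (i-1, i, i+1, i+2); angles are
    signed degrees in (-180, 180].
    """
    idx = np.where(s.labels.astype(str) == "CA")[0]
    x = s.coords[idx]
    out = []
    for k in range(2, len(idx) - 2):
        phi = dihedral(x[k - 2], x[k - 1], x[k], x[k + 1])
        psi = dihedral(x[k - 1], x[k], x[k + 1], x[k + 2])
        out.append((phi, psi))
    return out
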