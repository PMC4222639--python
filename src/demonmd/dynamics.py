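"""Minimisation, thermostatted integration and low-mode Monte Carlo search.

The integrator is plain velocity Verlet with an optional Berendsen
weak-coupling or Langevin (BAOAB) thermostat.  Centre-of-mass translation
*and* rotation are removed periodically to guard against the flying-ice-cube
artefact.  Constraints are replaced by stiff harmonic bonds: coarse-grained
beads have no fast X-H modes, so the 2-fs-with-SHAKE recipe of all-atom
protocols maps onto a stiff-bond CG chain with a configurable timestep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional

import numpy as np
from scipy import optimize

from .cgpotential import (ACCEL, KB, PotentialSpec, RestraintSet, System,
                          enm_modes)
from .geometry import kabsch_rmsd
from .structio import Structure, Trajectory

logger = logging.getLogger("demonmd.dynamics")

__all__ = [
    "MDConfig", "MCSearchConfig", "EquilibrationConfig",
    "MinimizationResult", "IntegrationResult", "EquilibrationResult",
    "MCSearchResult", "SimulationError",
    "minimize", "boltzmann_velocities", "integrate",
    "staged_equilibration", "lowmode_mc_search",
]


class SimulationError(RuntimeError):
    """Energy divergence or non-finite state during a run."""


@dataclass
class MDConfig:
    """Integration parameters (ps, K).  ``dt`` keeps the 2-fs spirit of the
    all-atom protocol but is freely configurable for CG masses."""

    dt: float = 0.002
    thermostat: str = "berendsen"  # {"none", "berendsen", "langevin"}
    tau: float = 1.0
    T_target: float = 300.0
    n_steps: int = 1000
    seed: int = 0
    com_removal_interval: int = 100
    frame_interval: int = 100
    energy_bound: float = 1e9
    neighbor_skin: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.tau <= 0 or self.T_target <= 0:
            raise ValueError("dt, tau and T_target must be positive")
        if self.thermostat not in ("none", "berendsen", "langevin"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")


@dataclass
class MCSearchConfig:
    """Mixed torsional / low-mode conformational search parameters."""

    max_steps_per_attempt: int = 5000
    steps_per_rotatable_bond: int = 100
    n_saved: int = 10
    energy_window: float = 5.02
    p_torsion: float = 0.5
    lowmode_min: float = 3.0
    lowmode_max: float = 7.5
    seed: int = 0
    min_iter: int = 150
    distinct_rmsd: float = 0.5
    n_modes: int = 5
    torsion_sigma_deg: float = 30.0

    def __post_init__(self):
        if not (0.0 <= self.p_torsion <= 1.0):
            raise ValueError("p_torsion must be in [0, 1]")
        if not (0 < self.lowmode_min < self.lowmode_max):
            raise ValueError("need 0 < lowmode_min < lowmode_max")


@dataclass
class MinimizationResult:
    structure: Structure
    energy: float
    grad_norm: float
    n_iter: int
    converged: bool
    reason: str
    energy_trace: List[float] = field(default_factory=list)


@dataclass
class IntegrationResult:
    trajectory: Trajectory
    velocities: np.ndarray
    final_coords: np.ndarray
    temperatures: np.ndarray
    energies: np.ndarray


def minimize(s: Structure, p: PotentialSpec,
             r: Optional[RestraintSet] = None,
             method: str = "cg_polak_ribiere",
             tol: float = 1e-4, max_iter: int = 500,
             system: Optional[System] = None,
             movable: Optional[np.ndarray] = None) -> MinimizationResult:
    """Energy minimisation; returns the relaxed structure plus diagnostics.

    ``cg_polak_ribiere`` delegates to scipy's CG (Polak-Ribiere+ with Wolfe
    line search, so accepted iterates never increase the energy);
    ``steepest_descent`` is a simple backtracking gradient descent.
    ``movable`` optionally restricts optimisation to a subset of beads.
    """
    if method not in ("steepest_descent", "cg_polak_ribiere"):
        raise ValueError(f"unknown method {method!r}")
    sys_ = system if system is not None else System(s, p, r)
    n = sys_.n
    x_full = s.coords.copy()
    if movable is None:
        movable = np.arange(n)
    movable = np.asarray(movable, dtype=int)

    skin = 1.5
    state = {"x": None, "pairs": None}

    def fun(z):
        xf = x_full.copy()
        xf[movable] = z.reshape(-1, 3)
        if (state["pairs"] is None
                or np.max(np.abs(xf - state["x"])) > skin / 2):
            state["pairs"] = sys_.compile_pairs(
                sys_.nonbonded_pairs(xf, skin=skin))
            state["x"] = xf.copy()
        e, F, _ = sys_.energy_forces(xf, state["pairs"], check_overlap=False)
        if not np.isfinite(e):
            e = 1e30
        return e, -F[movable].ravel()

    e0, g0 = fun(x_full[movable].ravel())
    if not np.isfinite(e0) or e0 >= 1e30:
        raise SimulationError("non-finite starting energy")
    trace = [e0]

    def cb(z):
        e, _ = fun(z)
        trace.append(e)

    if method == "cg_polak_ribiere":
        res = optimize.minimize(fun, x_full[movable].ravel(), jac=True,
                                method="CG", callback=cb,
                                options={"gtol": tol, "maxiter": max_iter})
        z = res.x
        n_iter = int(res.nit)
    else:
        z = x_full[movable].ravel().copy()
        step = 1e-3
        e, g = fun(z)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            gn = np.max(np.abs(g))
            if gn < tol:
                break
            # backtracking line search along -g
            trial_step = step
            for _ in range(40):
                z_new = z - trial_step * g
                e_new, g_new = fun(z_new)
                if e_new < e:
                    break
                trial_step *= 0.5
            else:
                break
            z, e, g = z_new, e_new, g_new
            step = min(trial_step * 1.5, 1.0)
            trace.append(e)

    e_fin, g_fin = fun(z)
    gnorm = float(np.max(np.abs(g_fin))) if len(g_fin) else 0.0
    converged = gnorm < tol
    reason = "gradient_tolerance" if converged else "max_iterations"
    x_out = x_full.copy()
    x_out[movable] = z.reshape(-1, 3)
    if e_fin > e0 + 1e-9:  # never return an uphill result
        x_out, e_fin = x_full, e0
        reason = "no_improvement"
    return MinimizationResult(s.with_coords(x_out), float(e_fin), gnorm,
                              n_iter, converged, reason, trace)


def boltzmann_velocities(masses: np.ndarray, T: float,
                         seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Maxwell-Boltzmann velocity draw (A/ps) with COM momentum removed."""
    if T <= 0:
        raise ValueError("T must be > 0")
    masses = np.asarray(masses, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * T * ACCEL / masses)
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def _remove_com_motion(x, v, m):
    """Subtract COM translation and rigid rotation (inertia-tensor based)."""
    mtot = m.sum()
    v -= (m[:, None] * v).sum(axis=0) / mtot
    com = (m[:, None] * x).sum(axis=0) / mtot
    rx = x - com
    L = (m[:, None] * np.cross(rx, v)).sum(axis=0)
    r2 = (rx ** 2).sum(axis=1)
    I = (m[:, None, None] * (r2[:, None, None] * np.eye(3)[None]
                             - np.einsum("ij,ik->ijk", rx, rx))).sum(axis=0)
    try:
        omega = np.linalg.solve(I, L)
    except np.linalg.LinAlgError:
        return v
    v -= np.cross(omega[None, :], rx)
    return v


def integrate(s: Structure, v: np.ndarray, p: PotentialSpec,
              cfg: MDConfig,
              r: Optional[RestraintSet] = None,
              system: Optional[System] = None,
              start_time: float = 0.0,
              T_schedule: Optional[Callable[[int], float]] = None) -> IntegrationResult:
    """Velocity-Verlet integration with thermostat and COM-motion removal.

    Frames are stored every ``frame_interval`` steps (always including the
    final step).  ``T_schedule(step) -> K`` overrides the target temperature
    per step (used by the heating stages).
    """
    sys_ = system if system is not None else System(s, p, r)
    n = sys_.n
    m = sys_.masses
    x = s.coords.copy()
    v = np.asarray(v, dtype=float).reshape(n, 3).copy()
    dt = cfg.dt
    rng = np.random.default_rng(cfg.seed)

    pairs = sys_.compile_pairs(sys_.nonbonded_pairs(x, skin=cfg.neighbor_skin))
    x_at_build = x.copy()
    e, F, _ = sys_.energy_forces(x, pairs)
    a = F * ACCEL / m[:, None]

    times, frames, temps, energies = [], [], [], []
    # Langevin (BAOAB-style exact OU step on velocities)
    if cfg.thermostat == "langevin":
        gamma = 1.0 / cfg.tau
        c1 = math.exp(-gamma * dt)

    for step in range(1, cfg.n_steps + 1):
        T_tgt = T_schedule(step) if T_schedule is not None else cfg.T_target
        x += v * dt + 0.5 * a * dt * dt
        if np.max(np.abs(x - x_at_build)) > cfg.neighbor_skin / 2:
            pairs = sys_.compile_pairs(
                sys_.nonbonded_pairs(x, skin=cfg.neighbor_skin))
            x_at_build = x.copy()
        e, F, _ = sys_.energy_forces(x, pairs)
        if not np.isfinite(e) or abs(e) > cfg.energy_bound:
            raise SimulationError(f"energy divergence at step {step}: E={e}")
        a_new = F * ACCEL / m[:, None]
        v += 0.5 * (a + a_new) * dt
        a = a_new

        if cfg.thermostat == "berendsen":
            T_inst = sys_.temperature(v)
            if T_inst > 1e-12:
                lam2 = 1.0 + (dt / cfg.tau) * (T_tgt / T_inst - 1.0)
                lam = math.sqrt(min(max(lam2, 0.64), 1.5625))
                v *= lam
        elif cfg.thermostat == "langevin":
            sigma = np.sqrt(KB * T_tgt * ACCEL / m)[:, None]
            v = c1 * v + math.sqrt(1 - c1 * c1) * sigma * rng.normal(size=v.shape)

        if cfg.com_removal_interval > 0 and step % cfg.com_removal_interval == 0:
            v = _remove_com_motion(x, v, m)

        if step % cfg.frame_interval == 0 or step == cfg.n_steps:
            times.append(start_time + step * dt)
            frames.append(x.copy())
            temps.append(sys_.temperature(v))
            ke = 0.5 * float(np.sum(m[:, None] * v ** 2)) / ACCEL
            energies.append(e + ke)

    if not frames:
        times, frames = [start_time + cfg.n_steps * dt], [x.copy()]
        temps, energies = [sys_.temperature(v)], [e]
    traj = Trajectory(s, times, frames)
    return IntegrationResult(traj, v, x.copy(), np.array(temps), np.array(energies))


@dataclass
class EquilibrationConfig:
    """Desk-scale shape of the staged minimisation/heating protocol."""

    min_iter: int = 200
    heat_steps: int = 500
    ramp_steps: int = 500
    dt: float = 0.002
    tau: float = 0.2
    T_heat: float = 300.0
    T_ramp_start: float = 1.0
    T_ramp_end: float = 310.0
    restraint_ks: tuple = (10.0, 5.0, 4.0)
    seed: int = 0


@dataclass
class StageRecord:
    name: str
    kind: str
    restraint_k: Optional[float]
    energy: float
    T_end: Optional[float]


@dataclass
class EquilibrationResult:
    structure: Structure
    stages: List[StageRecord]
    velocities: np.ndarray


def staged_equilibration(s: Structure, p: PotentialSpec,
                         cfg: Optional[EquilibrationConfig] = None) -> EquilibrationResult:
    """Minimise / restrained-heat cycles, then an unrestrained 1->310 K ramp.

    Stage ledger (6 entries): minimise; heat with positional restraints
    k = 10; minimise; heat with k = 5; minimise with k reduced by 1 (= 4);
    unrestrained linear temperature ramp to 310 K.
    """
    cfg = cfg or EquilibrationConfig()
    k10, k5, k4 = cfg.restraint_ks
    stages: List[StageRecord] = []
    rng = np.random.default_rng(cfg.seed)

    def positional_restraints(struct, k):
        prot = struct.protein_indices
        return RestraintSet(positional=[(int(i), struct.coords[i].copy(), k)
                                        for i in prot])

    cur = s
    res = minimize(cur, p, max_iter=cfg.min_iter)
    cur = res.structure
    stages.append(StageRecord("min_1", "minimize", None, res.energy, None))

    v = boltzmann_velocities(cur.masses, cfg.T_heat, rng=rng)
    md = MDConfig(dt=cfg.dt, thermostat="berendsen", tau=cfg.tau,
                  T_target=cfg.T_heat, n_steps=cfg.heat_steps,
                  seed=int(rng.integers(2 ** 31)), frame_interval=cfg.heat_steps)
    out = integrate(cur, v, p, md, r=positional_restraints(cur, k10))
    cur = cur.with_coords(out.final_coords)
    stages.append(StageRecord("heat_k10", "heat", k10,
                              float(out.energies[-1]), float(out.temperatures[-1])))

    res = minimize(cur, p, max_iter=cfg.min_iter)
    cur = res.structure
    stages.append(StageRecord("min_2", "minimize", None, res.energy, None))

    v = boltzmann_velocities(cur.masses, cfg.T_heat, rng=rng)
    md = replace(md, seed=int(rng.integers(2 ** 31)))
    out = integrate(cur, v, p, md, r=positional_restraints(cur, k5))
    cur = cur.with_coords(out.final_coords)
    stages.append(StageRecord("heat_k5", "heat", k5,
                              float(out.energies[-1]), float(out.temperatures[-1])))

    res = minimize(cur, p, r=positional_restraints(cur, k4), max_iter=cfg.min_iter)
    cur = res.structure
    stages.append(StageRecord("min_k4", "minimize", k4, res.energy, None))

    v = boltzmann_velocities(cur.masses, max(cfg.T_ramp_start, 1.0), rng=rng)
    md = replace(md, seed=int(rng.integers(2 ** 31)), n_steps=cfg.ramp_steps,
                 T_target=cfg.T_ramp_end, frame_interval=cfg.ramp_steps)
    span = max(cfg.ramp_steps - 1, 1)

    def ramp(step):
        f = min((step - 1) / span, 1.0)
        return cfg.T_ramp_start + f * (cfg.T_ramp_end - cfg.T_ramp_start)

    out = integrate(cur, v, p, md, T_schedule=ramp)
    cur = cur.with_coords(out.final_coords)
    stages.append(StageRecord("ramp_1_310", "ramp", None,
                              float(out.energies[-1]), cfg.T_ramp_end))
    return EquilibrationResult(cur, stages, out.velocities)


# ---------------------------------------------------------------------------
# Mixed torsional / low-mode Monte Carlo conformer search
# ---------------------------------------------------------------------------

@dataclass
class MCMoveRecord:
    step: int
    kind: str  # "torsion" | "lowmode"
    magnitude: float  # degrees for torsion moves, A (RMS) for low-mode moves
    energy: float
    kept: bool


@dataclass
class MCSearchResult:
    conformers: List[Structure]
    energies: List[float]
    records: List[MCMoveRecord]


def _rotate_downstream(coords, bonds_axis_i, bonds_axis_j, angle_rad, last=None):
    """Rotate beads downstream of bond (i, j) about the bond axis."""
    x = coords.copy()
    pivot = x[bonds_axis_j]
    axis = x[bonds_axis_j] - x[bonds_axis_i]
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        return x
    axis = axis / nrm
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + sa * K + (1 - ca) * (K @ K)
    stop = len(x) if last is None else last + 1
    seg = x[bonds_axis_j + 1:stop]
    x[bonds_axis_j + 1:stop] = (seg - pivot) @ R.T + pivot
    return x


def lowmode_mc_search(s: Structure, p: PotentialSpec,
                      cfg: Optional[MCSearchConfig] = None,
                      r: Optional[RestraintSet] = None) -> MCSearchResult:
    """Low-mode / torsional Monte Carlo conformer generation.

    Each step perturbs the current structure either by a random backbone
    pseudo-torsion rotation (probability ``p_torsion``) or by a displacement
    along a random low-frequency elastic-network mode with RMS magnitude
    drawn uniformly from ``[lowmode_min, lowmode_max]``, then minimises.
    Structures within ``energy_window`` of the running best are kept; up to
    ``n_saved`` lowest-energy conformers (pairwise RMSD > ``distinct_rmsd``)
    are returned, sorted by energy.
    """
    cfg = cfg or MCSearchConfig()
    rng = np.random.default_rng(cfg.seed)
    sys_ = System(s, p, r)
    prot = s.protein_indices
    n_rot = max(len(prot) - 3, 1)
    n_steps = int(min(cfg.max_steps_per_attempt,
                      cfg.steps_per_rotatable_bond * n_rot))

    _, modes = enm_modes(s, cutoff=p.en_cutoff, n_modes=cfg.n_modes)
    base = minimize(s, p, system=sys_, max_iter=cfg.min_iter)
    current = base.structure
    e_current = base.energy
    pool: List[tuple] = [(e_current, current)]
    best = e_current
    records: List[MCMoveRecord] = []

    for step in range(1, n_steps + 1):
        if rng.random() < cfg.p_torsion and len(prot) >= 4:
            # torsion move about a random internal pseudo-bond
            b = int(rng.integers(1, len(prot) - 2))
            ang = math.radians(rng.normal(0.0, cfg.torsion_sigma_deg))
            trial_coords = _rotate_downstream(current.coords, int(prot[b - 1]),
                                              int(prot[b]), ang)
            kind, mag = "torsion", abs(math.degrees(ang))
        else:
            mode = modes[int(rng.integers(len(modes)))]
            mag = float(rng.uniform(cfg.lowmode_min, cfg.lowmode_max))
            rms = math.sqrt(float((mode ** 2).sum()) / max(len(prot), 1))
            disp = mode / max(rms, 1e-12) * mag * (1 if rng.random() < 0.5 else -1)
            trial_coords = current.coords + disp
            kind = "lowmode"
        trial = current.with_coords(trial_coords)
        try:
            res = minimize(trial, p, system=sys_, max_iter=cfg.min_iter)
        except SimulationError:
            records.append(MCMoveRecord(step, kind, mag, math.inf, False))
            continue
        e_trial = res.energy
        kept = e_trial <= best + cfg.energy_window
        records.append(MCMoveRecord(step, kind, mag, e_trial, kept))
        if kept:
            pool.append((e_trial, res.structure))
            if e_trial < best:
                best = e_trial
            current, e_current = res.structure, e_trial
        # always restart the walk from the best-so-far half the time to
        # keep the search near the low-energy basin
        elif rng.random() < 0.5:
            current = min(pool, key=lambda t: t[0])[1]
            e_current = min(pool, key=lambda t: t[0])[0]

    best = min(e for e, _ in pool)
    pool = [(e, st) for e, st in pool if e <= best + cfg.energy_window]
    pool.sort(key=lambda t: t[0])
    chosen: List[tuple] = []
    for e, st in pool:
        if all(kabsch_rmsd(st.coords[prot], other.coords[prot]) > cfg.distinct_rmsd
               for _, other in chosen):
            chosen.append((e, st))
        if len(chosen) >= cfg.n_saved:
            break
    if not chosen:
        raise SimulationError("no conformers accepted; enlarge the energy window")
    return MCSearchResult([st for _, st in chosen], [e for e, _ in chosen], records)
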