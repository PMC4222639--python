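"""Maxwell's-demon molecular dynamics (MdMD).

Short unbiased MD "sprints" are accepted only when a global collective
variable — the Kabsch-superposition Calpha RMSD to a reference guidepost —
moves toward the target (or rises by at most ``accept_tol``); otherwise the
sprint is discarded and the run resumes from the pre-sprint snapshot with
fresh Boltzmann velocities.  Sprint lengths are drawn uniformly from a
configurable window so that replicate runs decorrelate ("the time of
sampling varies").  Chaining runs across an ordered guidepost set drives a
structure along a low-mode-generated conformational pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cgpotential import PotentialSpec, RestraintSet, System
from .dynamics import MDConfig, boltzmann_velocities, integrate
from .geometry import kabsch_rmsd
from .structio import Selection, Structure, Trajectory, apply_selection
from .synthgen import GuidepostSet

logger = logging.getLogger("demonmd.mdmd")

__all__ = ["DemonConfig", "DemonRunStats", "SprintRecord", "ChainResult",
           "rmsd_cv", "demon_run", "chain_guideposts", "run_replicates"]


def rmsd_cv(s: Structure, ref: Structure, sel: Optional[Selection] = None) -> float:
    """Optimal-superposition (Kabsch) Calpha RMSD between two structures.

    ``sel`` defaults to all Calpha beads; superposition uses the same
    selection.  The selection must resolve to equal bead counts in both.
    """
    if sel is None:
        idx_s = np.where(s.labels.astype(str) == "CA")[0]
        idx_r = np.where(ref.labels.astype(str) == "CA")[0]
    else:
        idx_s = apply_selection(s, sel)
        idx_r = apply_selection(ref, sel)
    if len(idx_s) != len(idx_r):
        raise ValueError(f"selection maps to {len(idx_s)} beads in the mobile "
                         f"structure but {len(idx_r)} in the reference")
    return kabsch_rmsd(s.coords[idx_s], ref.coords[idx_r])


@dataclass
class DemonConfig:
    """Demon sampler parameters.

    ``success_radius`` is the CV value at which a leg is declared reached
    (stop criterion); set it to ``None`` to let a run always exhaust
    ``max_sprints`` (useful when the terminal CV itself is the measurement).
    """

    md: MDConfig = field(default_factory=lambda: MDConfig(
        dt=0.01, thermostat="berendsen", tau=0.5, T_target=300.0,
        com_removal_interval=50))
    selection: Optional[Selection] = None  # None = all Calpha beads
    sprint_min: int = 30
    sprint_max: int = 90
    accept_tol: float = 0.0
    success_radius: Optional[float] = 3.0
    max_sprints: int = 400
    burn_in: int = 100
    seed: int = 0
    velocity_mode: str = "isotropic"  # "directional" reserved (config stub)

    def __post_init__(self):
        if self.success_radius is not None and self.success_radius <= 0:
            raise ValueError("success_radius must be > 0 (or None)")
        if not (0 < self.sprint_min <= self.sprint_max):
            raise ValueError("need 0 < sprint_min <= sprint_max")
        if self.max_sprints < 1:
            raise ValueError("max_sprints must be >= 1")
        if self.velocity_mode not in ("isotropic", "directional"):
            raise ValueError("velocity_mode must be 'isotropic' or 'directional'")
        if self.velocity_mode == "directional":
            raise NotImplementedError(
                "directional velocity draws are a declared extension point; "
                "only isotropic Boltzmann redraws are implemented")


@dataclass
class SprintRecord:
    sprint: int
    n_steps: int
    cv_before: float
    cv_after: float
    accepted: bool


@dataclass
class DemonRunStats:
    """Per-sprint ledger of one demon run against one guidepost."""

    records: List[SprintRecord]
    reached: bool
    final_cv: float
    success_radius: Optional[float]

    @property
    def n_sprints(self) -> int:
        return len(self.records)

    @property
    def n_accepted(self) -> int:
        return sum(1 for r in self.records if r.accepted)

    @property
    def n_discarded(self) -> int:
        return sum(1 for r in self.records if not r.accepted)

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / max(self.n_sprints, 1)

    def to_rows(self) -> List[dict]:
        rows = []
        discarded = 0
        for r in self.records:
            discarded += 0 if r.accepted else 1
            rows.append({
                "sprint": r.sprint, "n_steps": r.n_steps,
                "cv_before": r.cv_before, "cv_after": r.cv_after,
                "accepted": int(r.accepted),
                "cum_discard_fraction": discarded / r.sprint,
            })
        return rows

    def write_ledger(self, path) -> None:
        rows = self.to_rows()
        header = "sprint\tn_steps\tcv_before_A\tcv_after_A\taccepted\tcum_discard_fraction"
        lines = [header] + [
            f"{r['sprint']}\t{r['n_steps']}\t{r['cv_before']:.4f}\t"
            f"{r['cv_after']:.4f}\t{r['accepted']}\t{r['cum_discard_fraction']:.4f}"
            for r in rows]
        Path(path).write_text("\n".join(lines) + "\n")

    def summary(self) -> dict:
        return {
            "n_sprints": self.n_sprints,
            "n_accepted": self.n_accepted,
            "n_discarded": self.n_discarded,
            "discard_fraction": self.discard_fraction,
            "reached": self.reached,
            "final_cv_A": self.final_cv,
        }


@dataclass
class ChainResult:
    trajectory: Trajectory
    leg_stats: List[DemonRunStats]
    final_structure: Structure

    @property
    def all_reached(self) -> bool:
        return all(st.reached for st in self.leg_stats)


def demon_run(s: Structure, v: Optional[np.ndarray], p: PotentialSpec,
              r: Optional[RestraintSet], guidepost: Structure,
              cfg: DemonConfig,
              system: Optional[System] = None,
              start_time: float = 0.0) -> Tuple[Trajectory, DemonRunStats, Structure, np.ndarray]:
    """Drive ``s`` toward ``guidepost`` with the demon acceptance rule.

    Returns ``(trajectory of accepted checkpoints, stats, final structure,
    final velocities)``.  The trajectory contains only accepted states (plus
    the post-burn-in starting state), so its CV sequence is non-increasing
    up to ``accept_tol`` by construction of the acceptance rule.
    """
    sys_ = system if system is not None else System(s, p, r)
    rng = np.random.default_rng(cfg.seed)
    md_seed = lambda: int(rng.integers(2 ** 31))

    x = s.coords.copy()
    if v is None:
        v = boltzmann_velocities(s.masses, cfg.md.T_target, rng=rng)
    v = np.asarray(v, dtype=float).copy()

    t = start_time
    if cfg.burn_in > 0:
        md = replace(cfg.md, n_steps=cfg.burn_in, seed=md_seed(),
                     frame_interval=cfg.burn_in)
        out = integrate(s.with_coords(x), v, p, md, system=sys_, start_time=t)
        x, v = out.final_coords, out.velocities
        t = float(out.trajectory.times[-1])

    cv = rmsd_cv(s.with_coords(x), guidepost, cfg.selection)
    times, frames = [t], [x.copy()]
    records: List[SprintRecord] = []
    reached = cfg.success_radius is not None and cv <= cfg.success_radius

    sprint = 0
    while not reached and sprint < cfg.max_sprints:
        sprint += 1
        n_steps = int(rng.integers(cfg.sprint_min, cfg.sprint_max + 1))
        md = replace(cfg.md, n_steps=n_steps, seed=md_seed(),
                     frame_interval=n_steps)
        out = integrate(s.with_coords(x), v, p, md, system=sys_, start_time=t)
        cv_after = rmsd_cv(s.with_coords(out.final_coords), guidepost,
                           cfg.selection)
        accepted = cv_after <= cv + cfg.accept_tol
        records.append(SprintRecord(sprint, n_steps, cv, cv_after, accepted))
        if accepted:
            x, v = out.final_coords, out.velocities
            t = float(out.trajectory.times[-1])
            cv = cv_after
            times.append(t)
            frames.append(x.copy())
        else:
            # restore the snapshot, redraw thermal velocities
            v = boltzmann_velocities(s.masses, cfg.md.T_target, rng=rng)
        if cfg.success_radius is not None and cv <= cfg.success_radius:
            reached = True

    stats = DemonRunStats(records, reached, cv, cfg.success_radius)
    traj = Trajectory(s, times, frames)
    return traj, stats, s.with_coords(x), v


def chain_guideposts(s: Structure, posts: GuidepostSet, cfg: DemonConfig,
                     p: Optional[PotentialSpec] = None,
                     r: Optional[RestraintSet] = None,
                     system: Optional[System] = None) -> ChainResult:
    """Run the demon against each guidepost in order, handing off structures.

    Leg ``k`` starts from the terminal structure of leg ``k-1``.  A leg that
    exhausts ``max_sprints`` without reaching the success radius is flagged
    (``stats.reached == False``) but the chain continues.
    """
    if len(posts) < 2:
        raise ValueError("need at least 2 guideposts")
    p = p or PotentialSpec()
    sys_ = system if system is not None else System(s, p, r)
    rng = np.random.default_rng(cfg.seed)
    cur = s
    v = None
    t = 0.0
    legs, stats_list = [], []
    for k, post in enumerate(posts):
        leg_cfg = replace(cfg, seed=int(rng.integers(2 ** 31)))
        traj, stats, cur, v = demon_run(cur, v, p, r, post, leg_cfg,
                                        system=sys_, start_time=t)
        if not stats.reached:
            logger.warning("leg %d did not reach its guidepost "
                           "(final CV %.2f A)", k, stats.final_cv)
        legs.append(traj)
        stats_list.append(stats)
        t = float(traj.times[-1]) + cfg.md.dt
    full = _concat_legs(s, legs)
    return ChainResult(full, stats_list, cur)


def _concat_legs(topology: Structure, legs: Sequence[Trajectory]) -> Trajectory:
    times, frames = [], []
    last_t = -np.inf
    for leg in legs:
        for t, f in zip(leg.times, leg.frames):
            if t <= last_t:
                t = np.nextafter(last_t, np.inf) + 1e-9
            times.append(t)
            frames.append(f)
            last_t = t
    return Trajectory(topology, times, frames)


def run_replicates(s: Structure, posts: GuidepostSet, cfg: DemonConfig,
                   n_reps: int,
                   p: Optional[PotentialSpec] = None,
                   r: Optional[RestraintSet] = None) -> List[ChainResult]:
    """Independent chained runs with replicate seeds derived from the master.

    Each replicate draws its own sprint lengths and velocities (the spawned
    seed streams guarantee non-duplicative runs), so superposing the
    replicate pathways probes the robustness of the transition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    p = p or PotentialSpec()
    sys_ = System(s, p, r)
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_reps)
    out = []
    for k in range(n_reps):
        rep_seed = int(seeds[k].generate_state(1)[0] % (2 ** 31))
        rep_cfg = replace(cfg, seed=rep_seed)
        out.append(chain_guideposts(s, posts, rep_cfg, p=p, r=r, system=sys_))
    return out
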