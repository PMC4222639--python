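"""Pipeline orchestration: config, CLI and the staged demo workflow.

Stages (each a CLI subcommand over the library):

* ``generate``  — build the synthetic system, a solvated copy, and the
  low-mode guidepost set;
* ``simulate``  — unbiased replicate runs for each Ser65 variant (cleft
  opening comparison) plus a demon-chained run with replicates on the
  phosphorylated system (pathway sampling);
* ``analyze``   — metric series (cleft CoM distance, pocket SASA, pocket
  waters, domain pair distances, RMSD/RMSF) as CSV/JSON and figure panels;
* ``ddg``       — zone-equilibrated ddG for a table of site modifications;
* ``demo``      — all of the above with the bundled desk-scale config.

A single master seed fans out deterministically (numpy SeedSequence) to
per-stage and per-replicate seeds, so a rerun with the same config is
bit-identical while replicates stay distinct.  Every stage writes a manifest
(inputs, outputs, seeds, config hash, wall time).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import List, Optional

import click
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cgpotential import PotentialSpec, SiteModification, apply_modification
from .dynamics import MDConfig, boltzmann_velocities, integrate, minimize
from .mdmd import DemonConfig, run_replicates
from .structio import (Selection, parkin_selections, read_pdb,
                       read_trajectory, write_pdb, write_trajectory)
from .synthgen import (GuidepostSet, SolvationSpec, ToySpec,
                       generate_guideposts, make_parkin_like, solvate_shell)
from .trajmetrics import (com_distance_series,
                          pair_distance_series, pocket_water_series,
                          rmsd_series, rmsf, sasa_series)
from .zemu import ZoneSpec, ddg_mutation

logger = logging.getLogger("demonmd.orchestrator")

VARIANTS = {
    "Ser65": "identity",
    "pSer65": "pSer",
    "S65A": "S->A",
    "S65D": "S->D",
    "S65E": "S->E",
}


# ---------------------------------------------------------------------------
# schema-validated configuration (unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ToySection(_Strict):
    n_residues: int = 465
    bond_length: float = 3.8


class SolvationSection(_Strict):
    shell_depth: float = 15.0
    water_density: float = 1.0
    ion_pairs: int = 5


class PotentialSection(_Strict):
    bond_k: float = 100.0
    bond_r0: float = 3.8
    angle_k: float = 5.0
    lj_epsilon: float = 0.25
    lj_sigma: float = 3.8 / 2 ** (1 / 6)
    dielectric: str = "distance"
    dielectric_constant: float = 1.0
    debye_length: Optional[float] = None
    nonbonded_cutoff: float = 9.0
    en_cutoff: float = 10.0
    en_k: float = 10.0

    def build(self) -> PotentialSpec:
        return PotentialSpec(**self.model_dump())


class MDSection(_Strict):
    dt: float = 0.01
    thermostat: str = "berendsen"
    tau: float = 0.5
    T_target: float = 300.0
    n_steps: int = 15000
    com_removal_interval: int = 100
    frame_interval: int = 250
    neighbor_skin: float = 2.0
    n_replicates: int = 4


class GuidepostSection(_Strict):
    n_posts: int = 5
    amplitude: float = 40.0
    min_iter: int = 120


class DemonSection(_Strict):
    sprint_min: int = 30
    sprint_max: int = 90
    accept_tol: float = 0.0
    success_radius: Optional[float] = 3.0
    max_sprints: int = 400
    burn_in: int = 100
    n_replicates: int = 4
    variant: str = "pSer65"  # the demon drives the activated system


class MetricsSection(_Strict):
    pocket_cutoff: float = 5.0
    sasa_points: int = 240
    final_fraction: float = 1 / 3


class ZoneSection(_Strict):
    flex_halfwidth: int = 2
    physics_cutoff: float = 12.0
    inertia_scale: float = 11.0


class RunConfig(_Strict):
    master_seed: int = 0
    output_dir: str = "demonmd_out"
    solvate: bool = True
    toy: ToySection = Field(default_factory=ToySection)
    solvation: SolvationSection = Field(default_factory=SolvationSection)
    potential: PotentialSection = Field(default_factory=PotentialSection)
    md: MDSection = Field(default_factory=MDSection)
    guideposts: GuidepostSection = Field(default_factory=GuidepostSection)
    demon: DemonSection = Field(default_factory=DemonSection)
    metrics: MetricsSection = Field(default_factory=MetricsSection)
    zone: ZoneSection = Field(default_factory=ZoneSection)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
        ss = np.random.SeedSequence([self.master_seed, h])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def default_config() -> RunConfig:
    """The bundled desk-scale demo configuration."""
    from importlib import resources
    with resources.files("demonmd.data").joinpath("demo.yaml").open() as fh:
        return RunConfig(**(yaml.safe_load(fh) or {}))


def _write_manifest(outdir: Path, stage: str, cfg: RunConfig, inputs: list,
                    outputs: list, seeds: dict, t0: float) -> None:
    manifest = {
        "stage": stage,
        "demonmd_version": __version__,
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "stage_seeds": seeds,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "wall_time_s": round(time.time() - t0, 3),
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run `demonmd {producer}` first")
    return path


def _md_config(cfg: RunConfig, seed: int, n_steps: Optional[int] = None) -> MDConfig:
    md = cfg.md
    return MDConfig(dt=md.dt, thermostat=md.thermostat, tau=md.tau,
                    T_target=md.T_target,
                    n_steps=n_steps if n_steps is not None else md.n_steps,
                    seed=seed, com_removal_interval=md.com_removal_interval,
                    frame_interval=md.frame_interval,
                    neighbor_skin=md.neighbor_skin)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def cmd_generate(cfg: RunConfig) -> dict:
    """Build the synthetic system, its solvated copy and the guidepost set."""
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("generate")
    pspec = cfg.potential.build()

    toy = ToySpec(n_residues=cfg.toy.n_residues, seed=seed,
                  bond_length=cfg.toy.bond_length)
    system = make_parkin_like(toy)
    base = minimize(system, pspec, max_iter=300).structure

    sol_spec = SolvationSpec(shell_depth=cfg.solvation.shell_depth,
                             water_density=cfg.solvation.water_density,
                             ion_pairs=cfg.solvation.ion_pairs, seed=seed)
    outputs = []
    sys_path = outdir / "system.pdb"
    write_pdb(base, sys_path)
    outputs.append(sys_path)
    if cfg.solvate:
        solvated = solvate_shell(base, sol_spec)
        sol_path = outdir / "system_solvated.pdb"
        write_pdb(solvated, sol_path)
        outputs.append(sol_path)

    posts = generate_guideposts(base, n_posts=cfg.guideposts.n_posts,
                                amplitude=cfg.guideposts.amplitude,
                                seed=seed, pspec=pspec,
                                min_iter=cfg.guideposts.min_iter)
    for k, post in enumerate(posts):
        p_path = outdir / f"guidepost_{k:02d}.pdb"
        write_pdb(post, p_path)
        outputs.append(p_path)
    _write_manifest(outdir, "generate", cfg, [], outputs,
                    {"generate": seed}, t0)
    logger.info("generate: wrote %d files to %s", len(outputs), outdir)
    return {"structure": base, "guideposts": posts, "outputs": outputs}


def cmd_simulate(cfg: RunConfig) -> dict:
    """Unbiased replicate runs per Ser65 variant + a demon-chained pathway.

    The variant comparison runs ``md.n_replicates`` independent trajectories
    per variant from Boltzmann starts (replicate seeds derived from the
    master) — single CG trajectories of a marginal-stability event are
    noisy, so downstream analysis compares replicate-ensemble means.
    The demon chain drives the activated (phosphorylated) system along the
    generated guideposts with ``demon.n_replicates`` replicates.
    """
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    pspec = cfg.potential.build()
    base = read_pdb(_require(outdir / "system.pdb", "generate"))
    posts = GuidepostSet([
        read_pdb(_require(outdir / f"guidepost_{k:02d}.pdb", "generate"))
        for k in range(cfg.guideposts.n_posts)])

    seeds = {}
    outputs = []
    sim_seed = cfg.stage_seed("simulate")
    rep_seqs = np.random.SeedSequence(sim_seed).spawn(cfg.md.n_replicates)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rep_seqs]
    seeds["variant_replicates"] = rep_seeds

    for name, kind in VARIANTS.items():
        variant = apply_modification(base, SiteModification(65, kind))
        for r, sd in enumerate(rep_seeds):
            v = boltzmann_velocities(variant.masses, cfg.md.T_target, seed=sd)
            out = integrate(variant, v, pspec, _md_config(cfg, sd))
            path = outdir / f"traj_{name}_rep{r}.pdb"
            write_trajectory(out.trajectory, path)
            outputs.append(path)

    demon_seed = cfg.stage_seed("demon")
    seeds["demon"] = demon_seed
    driven = apply_modification(base, SiteModification(
        65, VARIANTS[cfg.demon.variant]))
    dcfg = DemonConfig(
        md=_md_config(cfg, demon_seed),
        sprint_min=cfg.demon.sprint_min, sprint_max=cfg.demon.sprint_max,
        accept_tol=cfg.demon.accept_tol,
        success_radius=cfg.demon.success_radius,
        max_sprints=cfg.demon.max_sprints, burn_in=cfg.demon.burn_in,
        seed=demon_seed)
    chains = run_replicates(driven, posts, dcfg, cfg.demon.n_replicates,
                            p=pspec)
    demon_summary = []
    for r, chain in enumerate(chains):
        path = outdir / f"demon_chain_rep{r}.pdb"
        write_trajectory(chain.trajectory, path)
        outputs.append(path)
        for leg, stats in enumerate(chain.leg_stats):
            ledger = outdir / f"demon_stats_rep{r}_leg{leg}.tsv"
            stats.write_ledger(ledger)
            outputs.append(ledger)
        demon_summary.append({
            "replicate": r,
            "legs": [st.summary() for st in chain.leg_stats],
            "all_reached": chain.all_reached,
        })
    stats_path = outdir / "demon_summary.json"
    stats_path.write_text(json.dumps(demon_summary, indent=1))
    outputs.append(stats_path)
    _write_manifest(outdir, "simulate", cfg,
                    [outdir / "system.pdb"], outputs, seeds, t0)
    logger.info("simulate: wrote %d files", len(outputs))
    return {"outputs": outputs, "demon_summary": demon_summary}


def _variant_metrics(cfg: RunConfig, outdir: Path, reg: dict):
    """Cleft metrics per variant, averaged over replicate trajectories."""
    summary = {}
    outputs = []
    for name in VARIANTS:
        finals = []
        for r in range(cfg.md.n_replicates):
            traj = read_trajectory(
                _require(outdir / f"traj_{name}_rep{r}.pdb", "simulate"))
            ser = com_distance_series(traj, reg["CoM1"], reg["CoM2"],
                                      name=f"cleft_com_{name}_rep{r}")
            path = outdir / f"cleft_com_{name}_rep{r}.csv"
            ser.to_csv(path)
            outputs.append(path)
            finals.append(ser.mean_final_fraction(cfg.metrics.final_fraction))
        summary[name] = {
            "cleft_com_final_mean_A": float(np.mean(finals)),
            "replicate_values_A": [round(float(v), 3) for v in finals],
        }
    return summary, outputs


def cmd_analyze(cfg: RunConfig) -> dict:
    """Metric series and summary statistics from the simulate stage."""
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    reg = parkin_selections()
    variant_summary, outputs = _variant_metrics(cfg, outdir, reg)
    summary = {"variants": variant_summary}

    # pathway metrics on the first demon replicate
    chain_path = _require(outdir / "demon_chain_rep0.pdb", "simulate")
    chain = read_trajectory(chain_path)
    start = chain.structure_at(0)
    panels = {
        "ubl_ring1": pair_distance_series(chain, (26, "CA"), (238, "CA"),
                                          name="ubl_ring1_Leu26_Cys238"),
        "ubl_ibr": pair_distance_series(chain, (26, "CA"), (364, "CA"),
                                        name="ubl_ibr_Leu26_Phe364"),
        "rep_ring1": pair_distance_series(chain, (391, "CA"), (238, "CA"),
                                          name="rep_ring1_Tyr391_Cys238"),
        "ring0_active": pair_distance_series(chain, (163, "CA"), (431, "CA"),
                                             name="ring0_cys431_Arg163_Cys431"),
        "cleft_com": com_distance_series(chain, reg["CoM1"], reg["CoM2"],
                                         name="cleft_com_pathway"),
        "core_rmsd": rmsd_series(chain, start, reg["rigid_core"],
                                 name="core_rmsd"),
        "nterm_rmsd": rmsd_series(chain, start, reg["flexible_nterm"],
                                  name="nterm_rmsd"),
    }
    pocket = Selection("ser65_pocket", reg["cleft_wall_1"].res_ids
                       | reg["cleft_wall_2"].res_ids | {65})
    panels["pocket_sasa"] = sasa_series(chain, pocket,
                                        n_sphere_points=cfg.metrics.sasa_points,
                                        name="ser65_pocket_sasa")
    if len(chain.topology.water_indices):
        panels["pocket_waters"] = pocket_water_series(
            chain, pocket, cfg.metrics.pocket_cutoff)
    for key, series in panels.items():
        path = outdir / f"metric_{key}.csv"
        series.to_csv(path)
        outputs.append(path)
        summary[key] = {
            "first": float(series.values[0]),
            "last": float(series.values[-1]),
            "mean_final_third": series.mean_final_fraction(1 / 3),
            "units": series.units,
        }
    res_ids, fluct = rmsf(chain)
    rmsf_path = outdir / "metric_rmsf.csv"
    rmsf_path.write_text("res_id,rmsf_A\n" + "\n".join(
        f"{int(r)},{v:.4f}" for r, v in zip(res_ids, fluct)) + "\n")
    outputs.append(rmsf_path)
    flex_mask = res_ids <= 140
    summary["rmsf"] = {
        "flexible_mean_A": float(fluct[flex_mask].mean()),
        "core_mean_A": float(fluct[~flex_mask].mean()),
    }

    summary_path = outdir / "analysis_summary.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    outputs.append(summary_path)
    outputs.extend(_plot_panels(outdir, panels, summary))
    _write_manifest(outdir, "analyze", cfg, [chain_path], outputs,
                    {"analyze": cfg.stage_seed("analyze")}, t0)
    return {"summary": summary, "outputs": outputs}


def _plot_panels(outdir: Path, panels: dict, summary: dict) -> List[Path]:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # headless plotting is best-effort
        logger.warning("matplotlib unavailable; skipping figure panels")
        return []
    outputs = []
    fig, axes = plt.subplots(2, 3, figsize=(13, 7))
    order = ["cleft_com", "pocket_sasa", "ubl_ring1", "ubl_ibr",
             "rep_ring1", "core_rmsd"]
    for ax, key in zip(axes.ravel(), order):
        if key not in panels:
            ax.axis("off")
            continue
        s = panels[key]
        ax.plot(s.times, s.values, lw=0.9)
        ax.set_xlabel("time (ps)")
        ax.set_ylabel(f"{s.name} ({s.units})")
    fig.tight_layout()
    path = outdir / "panels_pathway.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    outputs.append(path)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    names = list(summary["variants"])
    vals = [summary["variants"][n]["cleft_com_final_mean_A"] for n in names]
    ax.bar(names, vals, color=["#444", "#2a8", "#c55", "#c0c", "#55c"])
    ax.set_ylabel("cleft CoM distance, final third (A)")
    fig.tight_layout()
    path = outdir / "panels_variants.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    outputs.append(path)
    return outputs


def cmd_ddg(cfg: RunConfig, mutations: Optional[List[str]] = None) -> dict:
    """Zone-equilibrated ddG for a table of modifications.

    ``mutations`` rows are ``"<res_id> <kind>"`` (e.g. ``"65 pSer"``);
    default: the five Ser65 variants.
    """
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pspec = cfg.potential.build()
    sys_path = outdir / "system.pdb"
    if sys_path.exists():
        base = read_pdb(sys_path)
    else:
        seed = cfg.stage_seed("generate")
        base = minimize(make_parkin_like(ToySpec(seed=seed)), pspec,
                        max_iter=300).structure
    if mutations is None:
        mutations = [f"65 {kind}" for kind in
                     ("pSer", "S->A", "S->D", "S->E", "identity")]
    rows = []
    for line in mutations:
        parts = line.split()
        site, kind = int(parts[0]), parts[1]
        zspec = ZoneSpec(site=site, flex_halfwidth=cfg.zone.flex_halfwidth,
                         physics_cutoff=cfg.zone.physics_cutoff,
                         inertia_scale=cfg.zone.inertia_scale)
        res = ddg_mutation(base, SiteModification(site, kind), zspec, pspec)
        rows.append((site, kind, res))
    table = outdir / "ddg_table.tsv"
    lines = ["site\tkind\tdG_wt_kcal\tdG_mut_kcal\tddG_kcal\tflex_zone\tphysics_zone"]
    for site, kind, res in rows:
        lines.append(f"{site}\t{kind}\t{res.dG_wt:.4f}\t{res.dG_mut:.4f}\t"
                     f"{res.ddG:.4f}\t{res.flex_zone_size}\t{res.physics_zone_size}")
    table.write_text("\n".join(lines) + "\n")
    _write_manifest(outdir, "ddg", cfg, [], [table],
                    {"ddg": cfg.stage_seed("ddg")}, t0)
    return {"rows": rows, "outputs": [table]}


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load(config_path: Optional[str]) -> RunConfig:
    return load_config(config_path) if config_path else default_config()


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging")
def cli(verbose):
    """Coarse-grained Maxwell's-demon MD toolkit for Parkin-like systems."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


_cfg_opt = click.option("--config", "config_path", type=click.Path(exists=True),
                        default=None, help="YAML run configuration")
_out_opt = click.option("--out", "out_dir", default=None,
                        help="override the output directory")
_seed_opt = click.option("--seed", "seed", type=int, default=None,
                         help="override the master seed")


def _apply_overrides(cfg: RunConfig, out_dir, seed) -> RunConfig:
    patch = {}
    if out_dir is not None:
        patch["output_dir"] = out_dir
    if seed is not None:
        patch["master_seed"] = seed
    return cfg.model_copy(update=patch) if patch else cfg


@cli.command()
@_cfg_opt
@_out_opt
@_seed_opt
def generate(config_path, out_dir, seed):
    """Build system, solvated copy and guideposts."""
    cmd_generate(_apply_overrides(_load(config_path), out_dir, seed))


@cli.command()
@_cfg_opt
@_out_opt
@_seed_opt
def simulate(config_path, out_dir, seed):
    """Variant trajectories and demon-chained pathway runs."""
    cmd_simulate(_apply_overrides(_load(config_path), out_dir, seed))


@cli.command()
@_cfg_opt
@_out_opt
@_seed_opt
def analyze(config_path, out_dir, seed):
    """Metric series, summary JSON and figure panels."""
    out = cmd_analyze(_apply_overrides(_load(config_path), out_dir, seed))
    click.echo(json.dumps(out["summary"]["variants"], indent=1))


@cli.command()
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--mutations", type=click.Path(exists=True), default=None,
              help="text file: one '<res_id> <kind>' per line")
def ddg(config_path, out_dir, seed, mutations):
    """Zone-equilibrated mutation ddG table."""
    cfg = _apply_overrides(_load(config_path), out_dir, seed)
    muts = None
    if mutations:
        muts = [l.strip() for l in Path(mutations).read_text().splitlines()
                if l.strip() and not l.startswith("#")]
    out = cmd_ddg(cfg, muts)
    for site, kind, res in out["rows"]:
        click.echo(f"{site} {kind}: ddG = {res.ddG:.3f} kcal/mol")


@cli.command()
@_cfg_opt
@_out_opt
@_seed_opt
def demo(config_path, out_dir, seed):
    """Full pipeline: generate -> simulate -> analyze -> ddg."""
    cfg = _apply_overrides(_load(config_path), out_dir, seed)
    cmd_generate(cfg)
    cmd_simulate(cfg)
    out = cmd_analyze(cfg)
    cmd_ddg(cfg)
    click.echo(json.dumps(out["summary"]["variants"], indent=1))


if __name__ == "__main__":
    cli()
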