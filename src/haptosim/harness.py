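"""Condition grids, replicate sweeps, and aggregation.

The study design varies initial adhesion density (2.5, 5, 7.5%) and relative
gradient steepness (0, 2, 5, 10% per cell radius), optionally adds
cell-mediated ECM removal (low 0.03, high 0.1 per second) and a deterministic
chemotactic input (antiparallel or orthogonal to the haptotactic axis, with
relative steepness 0, 5, or 10%).  Replicates combine random-number supersets
with starting positions; chemotaxis conditions pin the start at (10, 8)
because the chemotactic field depends on x.

A ``scale`` factor shrinks step counts and replicate counts proportionally
for desk-scale smoke sweeps; full scale reproduces the publication design
(long on one CPU).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adhesion_lattice as al
from . import morphodynamics as md
from . import solver as sv
from .metrics import summarize, track_metrics

__all__ = [
    "Condition",
    "ConditionGrid",
    "RunManifest",
    "build_condition_grid",
    "run_sweep",
    "aggregate",
    "desk_scale_configs",
]

REMOVAL_RATES = {"none": 0.0, "low": 0.03, "high": 0.1}
DENSITIES = (0.025, 0.05, 0.075)
STEEPNESSES = (0.0, 0.02, 0.05, 0.10)
CHEMO_STEEPNESSES = (0.0, 0.05, 0.10)
STARTS = ((6.0, 8.0), (10.0, 8.0), (14.0, 8.0))
CHEMO_START = (10.0, 8.0)


@dataclass(frozen=True)
class Condition:
    """One cell-migration condition (everything except superset and start)."""

    n0: float
    g: float
    removal: str = "none"
    chemo_orientation: str = "none"
    g_C: float = 0.0

    @property
    def krem0(self) -> float:
        return REMOVAL_RATES[self.removal]

    def label(self) -> str:
        parts = [f"n0={100 * self.n0:g}%", f"g={100 * self.g:g}%",
                 f"rem={self.removal}"]
        if self.chemo_orientation != "none":
            parts.append(f"chemo={self.chemo_orientation}:{100 * self.g_C:g}%")
        return " ".join(parts)


@dataclass
class ConditionGrid:
    """A set of conditions with a shared replicate plan."""

    figure: str
    conditions: list
    superset_ids: list
    starts: list
    n_steps: int
    scale: float = 1.0

    @property
    def n_replicates(self) -> int:
        return len(self.superset_ids) * len(self.starts)

    def runs(self):
        """Yield (condition, superset_id, start) for every planned run."""
        for cond in self.conditions:
            for ss in self.superset_ids:
                for start in self.starts:
                    yield cond, ss, start


def build_condition_grid(figure_spec: str, scale: float = 1.0) -> ConditionGrid:
    """Replicate plan for one of the published condition grids.

    ``fig3``: 12 gradient conditions (3 densities x 4 steepnesses), 18
    replicates each (6 supersets x 3 starts).  ``fig4`` adds low/high ECM
    removal.  ``fig5``/``fig6`` are the 54-condition dual-gradient grids
    (antiparallel / orthogonal chemotaxis) with 12 supersets and the start
    pinned at (10, 8).  ``scale`` in (0, 1] shrinks step and replicate
    counts proportionally (at least 2 supersets are kept).
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")

    def shrink(count: int) -> int:
        return max(2, int(round(count * scale)))

    n_steps = max(1, int(round(20000 * scale)))
    if figure_spec == "fig3":
        conds = [Condition(n0, g) for n0 in DENSITIES for g in STEEPNESSES]
        supersets = list(range(shrink(6)))
        starts = list(STARTS)
    elif figure_spec == "fig4":
        conds = [
            Condition(n0, g, removal)
            for n0 in DENSITIES for g in STEEPNESSES
            for removal in ("low", "high")
        ]
        supersets = list(range(shrink(6)))
        starts = list(STARTS)
    elif figure_spec in ("fig5", "fig6"):
        orientation = ("antiparallel-y" if figure_spec == "fig5"
                       else "orthogonal-x")
        conds = [
            Condition(n0, g, removal, orientation, g_c)
            for n0 in DENSITIES
            for g in (0.0, 0.05, 0.10)
            for removal in ("none", "low")
            for g_c in CHEMO_STEEPNESSES
        ]
        supersets = list(range(shrink(12)))
        starts = [CHEMO_START]
    else:
        raise ValueError(f"unknown figure spec {figure_spec!r}")
    return ConditionGrid(figure=figure_spec, conditions=conds,
                         superset_ids=supersets, starts=starts,
                         n_steps=n_steps, scale=scale)


@dataclass
class RunManifest:
    """Replay-sufficient record of one run."""

    run_id: str
    condition: dict
    superset_id: int
    start: list
    status: str
    metrics: dict = field(default_factory=dict)
    track_path: str = ""
    schedule_sha: str = ""
    sim_config: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    version: str = "1"

    def save(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**yaml.safe_load(path.read_text()))


def desk_scale_configs(n_steps: int = 1200):
    """Desk-scale configuration for trend checks and smoke sweeps.

    Half-resolution mesh (voxel 0.1, interface width eps 0.1 — the
    interface-localized generation weight eps |grad phi| is invariant under
    this rescaling), a 6x6 window inside a 16x16 domain, and shorter runs.
    """
    sim = sv.SimulationConfig(box_size=6.0, voxel=0.1, domain_size=16.0,
                              n_steps=n_steps, sample_every=60)
    params = md.ModelParams(eps=0.1)
    return sim, params


def _lattice_for(cond: Condition, sim: sv.SimulationConfig,
                 start) -> al.LatticeConfig:
    n_sites = int(round(sim.domain_size / sim.lattice_pitch))
    return al.LatticeConfig(
        Nx=n_sites, Ny=n_sites, ell=sim.lattice_pitch, n0=cond.n0, g=cond.g,
        x0=start[0], y0=start[1], krem0=cond.krem0,
    )


def _run_id(cond: Condition, superset_id: int, start, sim) -> str:
    key = json.dumps([asdict(cond), superset_id, list(start),
                      sim.to_dict()], sort_keys=True)
    return hashlib.sha1(key.encode()).hexdigest()[:12]


def run_sweep(grid: ConditionGrid, out_dir,
              sim_config: sv.SimulationConfig | None = None,
              params: md.ModelParams | None = None) -> list[RunManifest]:
    """Execute every run of a grid (resumable; completed runs are skipped).

    Adhesion schedules are packed once per (lattice configuration without
    removal, superset) and replayed by every removal-free variant that
    shares them; removal variants consume the same random superset live, so
    their schedules coincide with the packed ones until the expected count
    first changes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched_dir = out / "schedules"
    sched_dir.mkdir(exist_ok=True)
    if sim_config is None or params is None:
        d_sim, d_params = desk_scale_configs(grid.n_steps)
        sim_config = sim_config or d_sim
        params = params or d_params
    sim_config = sv.SimulationConfig(
        **{**sim_config.to_dict(), "n_steps": grid.n_steps})

    manifests = []
    for cond, ss, start in grid.runs():
        rid = _run_id(cond, ss, start, sim_config)
        mpath = out / f"{rid}.yaml"
        if mpath.exists():
            man = RunManifest.load(mpath)
            if man.status in ("completed", "domain_exit"):
                manifests.append(man)
                continue
        lattice = _lattice_for(cond, sim_config, start)
        adhesion_source: int | al.SchedulePack = ss
        sched_sha = ""
        if cond.krem0 == 0.0:
            skey = hashlib.sha1(json.dumps(
                [lattice.to_dict(), ss], sort_keys=True).encode()
            ).hexdigest()[:12]
            spath = sched_dir / f"{skey}.h5"
            if spath.exists():
                pack = al.load_schedule(spath)
            else:
                n_frames = grid.n_steps // max(
                    1, int(round(lattice.dt / sim_config.pde_dt)))
                pack = al.simulate_schedule(lattice, n_frames, ss)
                al.save_schedule(pack, spath)
            sched_sha = hashlib.sha1(
                np.packbits(pack.schedule).tobytes()).hexdigest()
            adhesion_source = pack
        run_params = params
        if cond.chemo_orientation != "none":
            run_params = md.ModelParams(**{**params.to_dict(),
                                           "g_C": cond.g_C})
        try:
            track, _, run_man = sv.run_simulation(
                sim_config, run_params, lattice, adhesion_source,
                chemo_orientation=cond.chemo_orientation, start=start,
            )
            tpath = out / f"{rid}_track.csv"
            track.to_dataframe().to_csv(tpath, index=False)
            man = RunManifest(
                run_id=rid, condition=asdict(cond), superset_id=ss,
                start=list(start), status=run_man["status"],
                metrics=track_metrics(track).to_dict(),
                track_path=str(tpath), schedule_sha=sched_sha,
                sim_config=sim_config.to_dict(), params=run_man["params"],
            )
        except Exception as exc:  # partial failures recorded, sweep continues
            man = RunManifest(
                run_id=rid, condition=asdict(cond), superset_id=ss,
                start=list(start), status=f"failed: {exc}",
                sim_config=sim_config.to_dict(), params=params.to_dict(),
            )
        man.save(mpath)
        manifests.append(man)
    return manifests


def aggregate(manifests, metric: str = "HI") -> pd.DataFrame:
    """Per-condition mean and 95% CI of a tactic-fidelity metric.

    Conditions with fewer than 2 completed replicates are flagged
    (``ok = False``) rather than summarized.
    """
    if metric not in ("HI", "CI", "persistence"):
        raise ValueError(f"unsupported metric {metric!r}")
    rows = []
    by_cond: dict = {}
    for man in manifests:
        if isinstance(man, (str, Path)):
            man = RunManifest.load(Path(man))
        label = Condition(**man.condition).label()
        by_cond.setdefault(label, []).append(man)
    for label, group in by_cond.items():
        done = [m for m in group
                if m.status in ("completed", "domain_exit") and m.metrics]
        row = {"condition": label, "n": len(done), "metric": metric}
        if len(done) >= 2:
            vals = [m.metrics[metric] for m in done]
            mean, half = summarize(vals)
            pers = [m.metrics["persistence"] for m in done]
            pmean, phalf = summarize(pers)
            row.update(mean=mean, ci95=half, ok=True,
                       persistence_mean=pmean, persistence_ci95=phalf)
        else:
            row.update(mean=np.nan, ci95=np.nan, ok=False,
                       persistence_mean=np.nan, persistence_ci95=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
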