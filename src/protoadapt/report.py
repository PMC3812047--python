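"""Scenario runner, tabular writers and figure-style report rendering.

``run_scenario`` dispatches a named standard scenario (or a config file) to
the matching simulator, writes CSV/JSON outputs plus a run manifest, and
returns a :class:`RunRecord`.  All core models are deterministic, so repeated
runs of the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    GradientStimulus,
    SimulationConfig,
    StepStimulus,
    load_config,
    list_fixtures,
    make_fixture,
)
from .chemotaxis import ChemotaxisParams, precision_dissipation_sweep
from .gradient2d import build_disk_mesh, dipole_series, simulate_gradient
from .metrics import fcd_distance, summarize
from .one_component import simulate_step
from .thermo import dissipation_series
from .two_component import simulate_two_component

__all__ = ["RunRecord", "run_scenario", "render_report", "config_hash"]

_CSV_KW = dict(index=False, float_format="%.12g")


def config_hash(config: SimulationConfig) -> str:
    """Deterministic hash of a configuration (stable across runs)."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    scenario: str
    config_hash: str
    version: str
    wall_time_s: float
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "config_hash": self.config_hash,
            "version": self.version,
            "wall_time_s": self.wall_time_s,
            "outputs": self.outputs,
        }


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, **_CSV_KW)
    return str(path)


def _run_step_scenario(name, config, outdir, outputs):
    traj = simulate_step(config)
    outputs.append(_write_csv(traj.to_frame(), outdir / f"{name}_trajectory.csv"))
    if name == "fig4_dissipation":
        dis = dissipation_series(traj, config.diffusion, config.geometry)
        outputs.append(_write_csv(dis.to_frame(), outdir / f"{name}_dissipation.csv"))
    if isinstance(config.stimulus, StepStimulus) and config.stimulus.c0 > 0:
        summary = summarize(traj, config.stimulus).to_dict()
        p = outdir / f"{name}_metrics.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True))
        outputs.append(str(p))


def _run_fig6_ladder(name, config, outdir, outputs):
    key = "c1_values" if "c1_values" in config.sweep else "c0_values"
    rows = []
    for value in config.sweep[key]:
        stim = (
            StepStimulus(c0=0.0, c1=value, t_step=config.stimulus.t_step)
            if key == "c1_values"
            else StepStimulus(c0=value, c1=0.0, t_step=config.stimulus.t_step)
        )
        traj = simulate_step(config.replace(stimulus=stim))
        from .metrics import adaptation_time

        rows.append(
            {"step_mM": value, "adaptation_time_s": adaptation_time(traj, stim.t_step)}
        )
    outputs.append(
        _write_csv(pd.DataFrame(rows), outdir / f"{name}_adaptation_times.csv")
    )


def _run_fcd_pair(name, config, outdir, outputs):
    trajs = []
    for c0, c1 in config.sweep["pairs"]:
        stim = StepStimulus(c0=c0, c1=c1, t_step=config.stimulus.t_step)
        traj = simulate_step(config.replace(stimulus=stim))
        trajs.append(traj)
        outputs.append(
            _write_csv(traj.to_frame(), outdir / f"{name}_{c0:g}to{c1:g}.csv")
        )
    dist = fcd_distance(trajs[0], trajs[1])
    p = outdir / f"{name}_fcd.json"
    p.write_text(json.dumps({"fcd_distance": dist}, indent=2))
    outputs.append(str(p))


def _run_gradient(name, config, outdir, outputs):
    sol = config.solver
    mesh = build_disk_mesh(config.geometry.radius, sol.n_r, sol.n_theta)
    t_grid = np.arange(0.0, sol.t_end + 0.5 * sol.dt, sol.dt)
    series = simulate_gradient(
        mesh,
        config.stimulus,
        config.diffusion.D_ligand,
        config.diffusion.permeability,
        t_grid,
        bc_mode=sol.bc_mode,
        probe_rho=config.geometry.rho,
    )
    dip = dipole_series(series, config.geometry, config.receptor)
    outputs.append(_write_csv(dip.to_frame(), outdir / f"{name}_summary.csv"))
    for k, snap in enumerate(series.snapshots):
        x, y = mesh.node_positions()
        df = pd.DataFrame({"x": x, "y": y, "c": snap.u})
        outputs.append(_write_csv(df, outdir / f"{name}_field_{k:02d}.csv"))


def run_scenario(
    name_or_path: str, outdir: str | Path, model: str = "one_component"
) -> RunRecord:
    """Run a named standard scenario (or a YAML config file) and write outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name_or_path in list_fixtures():
        name = name_or_path
        config = make_fixture(name)
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ValueError(
                f"unknown scenario {name_or_path!r}; available: "
                f"{', '.join(list_fixtures())} (or a config file path)"
            )
        name = path.stem
        config = load_config(path)
    t0 = time.perf_counter()
    outputs: list[str] = []
    if isinstance(config.stimulus, GradientStimulus):
        _run_gradient(name, config, outdir, outputs)
    elif "pairs" in config.sweep:
        _run_fcd_pair(name, config, outdir, outputs)
    elif "c1_values" in config.sweep or "c0_values" in config.sweep:
        _run_fig6_ladder(name, config, outdir, outputs)
    elif model == "two_component":
        traj = simulate_two_component(config)
        outputs.append(_write_csv(traj.to_frame(), outdir / f"{name}_trajectory.csv"))
    else:
        _run_step_scenario(name, config, outdir, outputs)
    record = RunRecord(
        scenario=name,
        config_hash=config_hash(config),
        version=__version__,
        wall_time_s=time.perf_counter() - t0,
        outputs=outputs,
    )
    (outdir / f"{name}_manifest.json").write_text(
        json.dumps(
            {k: v for k, v in record.to_dict().items() if k != "wall_time_s"},
            indent=2,
            sort_keys=True,
        )
    )
    return record


def run_chemotaxis_sweep(
    x_grid, c0: float, c1: float, outdir: str | Path, params: ChemotaxisParams | None = None
) -> RunRecord:
    """Dissipation-precision sweep over the equilibrium fraction, written as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or ChemotaxisParams()
    t0 = time.perf_counter()
    table = precision_dissipation_sweep(x_grid, StepStimulus(c0=c0, c1=c1), params)
    out = _write_csv(table, outdir / "chemotaxis_sweep.csv")
    return RunRecord(
        scenario="chemotaxis_sweep",
        config_hash=hashlib.sha256(
            json.dumps([list(map(float, x_grid)), c0, c1], sort_keys=True).encode()
        ).hexdigest()[:16],
        version=__version__,
        wall_time_s=time.perf_counter() - t0,
        outputs=[out],
    )


def render_report(records: list[RunRecord], outdir: str | Path) -> list[str]:
    """Render multi-panel figure-style plots for a list of run records."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("no run records to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    figures: list[str] = []
    for rec in records:
        missing = [p for p in rec.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing outputs for {rec.scenario}: {missing}")
        csvs = [p for p in rec.outputs if p.endswith("_trajectory.csv")]
        summary = [p for p in rec.outputs if p.endswith("_summary.csv")]
        sweeps = [p for p in rec.outputs if p.endswith("_sweep.csv") or p.endswith("_adaptation_times.csv")]
        if csvs:
            df = pd.read_csv(csvs[0])
            cols = [c for c in ("c_out", "c_in", "A", "A1", "A2") if c in df.columns]
            fig, axes = plt.subplots(1, len(cols), figsize=(4 * len(cols), 3))
            axes = np.atleast_1d(axes)
            for ax, col in zip(axes, cols):
                ax.plot(df["t"], df[col])
                ax.set_xlabel("t (s)")
                ax.set_ylabel(col)
            fig.suptitle(rec.scenario)
            fig.tight_layout()
        elif summary:
            df = pd.read_csv(summary[0])
            fig, axes = plt.subplots(1, 2, figsize=(8, 3))
            axes[0].plot(df["t"], df["P"])
            axes[0].set_ylabel("dipole P")
            axes[1].plot(df["t"], df["polarization"])
            axes[1].set_ylabel("polarization")
            for ax in axes:
                ax.set_xlabel("t (s)")
            fig.suptitle(rec.scenario)
            fig.tight_layout()
        elif sweeps:
            df = pd.read_csv(sweeps[0])
            xcol, ycols = df.columns[0], df.columns[1:]
            fig, axes = plt.subplots(1, len(ycols), figsize=(4 * len(ycols), 3))
            axes = np.atleast_1d(axes)
            for ax, col in zip(axes, ycols):
                ax.plot(df[xcol], df[col], marker="o")
                ax.set_xlabel(xcol)
                ax.set_ylabel(col)
            fig.suptitle(rec.scenario)
            fig.tight_layout()
        else:
            continue
        path = outdir / f"{rec.scenario}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(str(path))
    return figures
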