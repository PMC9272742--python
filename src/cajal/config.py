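"""YAML run configurations: schema validation, model building, execution.

A run configuration describes one simulation: a morphology file with
per-section nseg, mechanism sources, density placements, point processes,
detectors, connections, event drives, recordings, the simulation settings
(optionally with mid-run backend switches), and output paths.  The schema
is deliberately flat and explicit — fixture generators write one entry per
cell rather than relying on templating.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .engine import Model, SimConfig, Simulation
from .errors import ConfigError
from .morphology import discretize, read_swc

_TOP_KEYS = {"morphology", "mechanisms", "cells", "placements",
             "point_processes", "detectors", "connections", "drives",
             "recordings", "sim", "switch", "outputs"}
_SIM_KEYS = {"dt", "tstop", "v_init", "celsius", "seed", "backend"}


def load_config(path) -> dict:
    """Load and validate a run configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = sorted(set(cfg) - _TOP_KEYS)
    if unknown:
        raise ConfigError("unknown configuration keys", unknown)
    missing = [k for k in ("morphology", "sim") if k not in cfg]
    if missing:
        raise ConfigError("missing required configuration keys", missing)
    sim = cfg["sim"]
    bad = sorted(set(sim) - _SIM_KEYS)
    if bad:
        raise ConfigError("unknown sim keys", [f"sim.{k}" for k in bad])
    dt = float(sim.get("dt", 0.025))
    tstop = float(sim.get("tstop", 5.0))
    if dt <= 0:
        raise ConfigError("sim.dt must be positive", ["sim.dt"])
    if tstop < 0:
        raise ConfigError("sim.tstop must be >= 0", ["sim.tstop"])
    if abs(dt * round(tstop / dt) - tstop) > 1e-9 * max(1.0, tstop):
        raise ConfigError("sim.tstop must be an integer multiple of sim.dt",
                          ["sim.tstop"])
    return cfg


def build_simulation(cfg: dict, basedir) -> tuple[Simulation, dict]:
    """Instantiate the model a configuration describes.

    Returns the simulation and a name -> point-process-id map.
    """
    basedir = Path(basedir)
    morph_cfg = cfg["morphology"]
    morph = read_swc(basedir / morph_cfg["file"])
    nseg = morph_cfg.get("nseg", 1)
    if isinstance(nseg, dict):
        nseg = {int(k): int(v) for k, v in nseg.items()}
    model = Model()
    n_cells = int(cfg.get("cells", 1))
    for _ in range(n_cells):
        model.add_cell(discretize(morph, nseg=nseg,
                                  cm=morph_cfg.get("cm", 1.0),
                                  ra=morph_cfg.get("ra", 100.0)))
    for entry in cfg.get("mechanisms", []):
        if "file" in entry:
            model.use((basedir / entry["file"]).read_text())
        elif "builtin" in entry:
            model.use(entry["builtin"])
        else:
            raise ConfigError("mechanism entry needs 'file' or 'builtin'",
                              ["mechanisms"])
    sections = [s.id for s in morph.sections]
    for entry in cfg.get("placements", []):
        secs = sections if entry.get("section") == "all" else [entry["section"]]
        for sec in secs:
            model.insert(int(entry["cell"]), int(sec), entry["mech"],
                         **(entry.get("params") or {}))
    pp_ids: dict[str, int] = {}
    for entry in cfg.get("point_processes", []):
        pp_ids[str(entry["id"])] = model.place(
            int(entry["cell"]), int(entry["section"]), float(entry["x"]),
            entry["mech"], **(entry.get("params") or {}))
    for entry in cfg.get("detectors", []):
        model.add_detector(int(entry["cell"]), int(entry["section"]),
                           float(entry["x"]),
                           threshold=float(entry.get("threshold", -20.0)))
    for entry in cfg.get("connections", []):
        target = entry["target"]
        if target not in pp_ids:
            raise ConfigError("connection target does not resolve",
                              [f"connections.target={target}"])
        model.connect(int(entry["source"]), pp_ids[target],
                      weight=float(entry["weight"]),
                      delay=float(entry["delay"]))
    for entry in cfg.get("drives", []):
        target = entry["target"]
        if target not in pp_ids:
            raise ConfigError("drive target does not resolve",
                              [f"drives.target={target}"])
        model.drive(pp_ids[target], [float(t) for t in entry["times"]],
                    float(entry["weight"]))
    sim_cfg = cfg["sim"]
    config = SimConfig(dt=float(sim_cfg.get("dt", 0.025)),
                       tstop=float(sim_cfg.get("tstop", 5.0)),
                       v_init=float(sim_cfg.get("v_init", -65.0)),
                       celsius=float(sim_cfg.get("celsius", 6.3)),
                       seed=int(sim_cfg.get("seed", 0)),
                       backend=str(sim_cfg.get("backend", "reference")))
    sim = Simulation(model, config)
    for entry in cfg.get("recordings", []):
        if entry.get("kind", "v") == "v":
            sim.record_v(int(entry["cell"]), int(entry["section"]),
                         float(entry["x"]), name=entry.get("name"))
        else:
            loc = (int(entry["cell"]), int(entry["section"]),
                   float(entry["x"]), entry["mech"])
            sim.record_var(loc, entry["var"], name=entry.get("name"))
    return sim, pp_ids


def run_config(path, outdir=None) -> dict:
    """Execute a configuration end to end and write its outputs.

    Returns a summary dict (spike count, output paths, timing table).
    """
    path = Path(path)
    cfg = load_config(path)
    basedir = path.parent
    outdir = Path(outdir) if outdir is not None else basedir
    sim, _pp = build_simulation(cfg, basedir)
    sim.finitialize()
    tstop = float(cfg["sim"].get("tstop", 5.0))
    plan = []
    t_prev, backend = 0.0, str(cfg["sim"].get("backend", "reference"))
    for sw in cfg.get("switch", []) or []:
        plan.append((float(sw["t"]), backend))
        backend = str(sw["backend"])
        t_prev = float(sw["t"])
    plan.append((tstop, backend))
    t_now = 0.0
    for t_target, bk in plan:
        if t_target > t_now:
            sim.psolve(t_target, bk)
            t_now = t_target
    outputs = cfg.get("outputs", {}) or {}
    written = {}
    if "recordings" in outputs:
        out = outdir / outputs["recordings"]
        write_recordings_csv(sim, out)
        written["recordings"] = str(out)
    if "raster" in outputs:
        out = outdir / outputs["raster"]
        write_raster(sim.spikes, out)
        written["raster"] = str(out)
    if "timing" in outputs:
        out = outdir / outputs["timing"]
        out.write_text(json.dumps(sim.timing, indent=2) + "\n")
        written["timing"] = str(out)
    return {"spikes": len(sim.spikes), "outputs": written,
            "timing": sim.timing}


def write_recordings_csv(sim: Simulation, path) -> None:
    """t column plus one column per recorded variable."""
    recs = sim.recorders
    with open(path, "w") as fh:
        fh.write(",".join(["t"] + [r.name for r in recs]) + "\n")
        if not recs:
            return
        times = recs[0].times
        cols = [np.asarray(r.values) for r in recs]
        for i, t in enumerate(times):
            fh.write(",".join([f"{t:.9g}"] + [f"{col[i]:.17g}" for col in cols])
                     + "\n")


def write_raster(spikes, path) -> None:
    """Spike raster text: "time<TAB>gid", sorted by time then gid."""
    with open(path, "w") as fh:
        for t, gid in sorted(spikes):
            fh.write(f"{t:.9g}\t{gid}\n")
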