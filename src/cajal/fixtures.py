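"""Deterministic synthetic fixtures: the models the tests and examples run.

Every fixture is generated programmatically — no data files ship with the
package.  In-memory builders return ready-to-run objects; ``gen_fixture``
writes the equivalent on-disk form (SWC morphology, mechanism sources, a
YAML run configuration) for the CLI.

Fixtures
--------
ball_and_stick   soma (20 um cylinder, hh) + 200 um passive dendrite
random_tree      random branching passive morphology (seeded)
ring_network     N ball-and-stick cells connected soma -> next dendrite
test_cylinder    200 um x 2 um cylinder at 1,001 segments (cable/diffusion
                 benchmark geometry)
circadian        Leloup-Goldbeter PER/TIM oscillator: 10 species, 21
                 reactions, hour-scale rates, no diffusion
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .engine import Model
from .mechdsl.library import SOURCES
from .morphology import Morphology, Section, discretize, parse_swc
from .rxd import Reaction, Region, RxdModel

FIXTURES = ("ball_and_stick", "random_tree", "ring_network", "test_cylinder",
            "circadian")


# ---------------------------------------------------------------------------
# SWC text


def ball_and_stick_swc() -> str:
    """Soma (2 samples, r=10) + dendrite (9 samples to x=220, r=1): 11 samples."""
    lines = ["# ball and stick fixture",
             "1 1 0 0 0 10 -1",
             "2 1 20 0 0 10 1"]
    for k in range(1, 10):
        x = 20 + 200.0 * k / 9
        lines.append(f"{k + 2} 3 {x:g} 0 0 1 {k + 1}")
    return "\n".join(lines) + "\n"


def test_cylinder_swc() -> str:
    """Unbranched cylinder, 200 um long, 2 um diameter."""
    return ("# test cylinder 200 um x 2 um\n"
            "1 3 0 0 0 1 -1\n"
            "2 3 200 0 0 1 1\n")


def random_tree_swc(seed: int = 0, n_branches: int = 6) -> str:
    """Random passive branching tree rooted at a small soma."""
    rng = np.random.default_rng(seed)
    lines = ["# random tree fixture", "1 1 0 0 0 5 -1"]
    nid = 2
    tips = [(1, np.zeros(3))]
    for _ in range(n_branches):
        parent, pos = tips[rng.integers(len(tips))]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        nsamp = int(rng.integers(3, 6))
        step = rng.uniform(8.0, 20.0)
        radius = rng.uniform(0.5, 1.5)
        cur = pos
        for k in range(nsamp):
            cur = cur + direction * step
            lines.append(f"{nid} 3 {cur[0]:.3f} {cur[1]:.3f} {cur[2]:.3f} "
                         f"{radius:.3f} {parent}")
            parent = nid
            nid += 1
        tips.append((parent, cur))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# in-memory builders


def build_ball_and_stick(stim_amp: float = 0.5, stim_onset: float = 1.0,
                         stim_dur: float = 3.0, nseg_dend: int = 11):
    """Model: hh soma + passive dendrite + somatic current step + detector."""
    morph = parse_swc(ball_and_stick_swc(), label="ball_and_stick.swc")
    soma = morph.root
    dend = [s.id for s in morph.sections if s.id != soma][0]
    cell = discretize(morph, nseg={soma: 1, dend: nseg_dend})
    model = Model()
    ci = model.add_cell(cell)
    model.insert(ci, soma, "hh")
    model.insert(ci, dend, "pas", g=0.0005, e=-65.0)
    model.place(ci, soma, 0.5, "stim", onset=stim_onset, dur=stim_dur,
                amp=stim_amp)
    model.add_detector(ci, soma, 0.5, threshold=-20.0)
    return model, {"cell": ci, "soma": soma, "dend": dend}


def build_ring(n_cells: int = 8, weight: float = 0.05, delay: float = 2.0,
               nseg_dend: int = 11):
    """Ring of ball-and-stick cells: soma spike -> next cell's dendritic
    synapse; cell 0 is kicked by one strong event at t = 1 ms."""
    morph = parse_swc(ball_and_stick_swc(), label="ball_and_stick.swc")
    soma = morph.root
    dend = [s.id for s in morph.sections if s.id != soma][0]
    model = Model()
    syns = []
    for k in range(n_cells):
        cell = discretize(morph, nseg={soma: 1, dend: nseg_dend})
        ci = model.add_cell(cell)
        model.insert(ci, soma, "hh")
        model.insert(ci, dend, "pas", g=0.0005, e=-65.0)
        syns.append(model.place(ci, dend, 0.5, "expsyn", tau=2.0, e=0.0))
        model.add_detector(ci, soma, 0.5, threshold=-20.0)
    for k in range(n_cells):
        model.connect(k, syns[(k + 1) % n_cells], weight=weight, delay=delay)
    model.drive(syns[0], [1.0], weight)
    return model, {"soma": soma, "dend": dend, "synapses": syns}


def build_test_cylinder(nseg: int = 1001, ra: float = 100.0, cm: float = 1.0):
    """DiscretizedCell for the 200 um x 2 um cylinder at ``nseg`` segments."""
    sec = Section(id=0, parent_id=None, parent_position=0.0,
                  points=np.array([[0.0, 0.0, 0.0, 2.0],
                                   [200.0, 0.0, 0.0, 2.0]]), name="cyl")
    return discretize(Morphology([sec], cell_id="test_cylinder"),
                      nseg=nseg, ra=ra, cm=cm)


# ---------------------------------------------------------------------------
# circadian reaction fixture (Leloup-Goldbeter PER/TIM oscillator)

#: parameters, nM and hours (vs/vm/ks/vd in nM/h, K in nM, k in 1/h)
CIRCADIAN_PARAMS = {
    "vsP": 1.1, "vmP": 1.0, "KmP": 0.2, "KIP": 1.0, "ksP": 0.9,
    "vdP": 2.2, "KdP": 0.2,
    "vsT": 1.0, "vmT": 0.7, "KmT": 0.2, "KIT": 1.0, "ksT": 0.9,
    "vdT": 3.0, "KdT": 0.2,
    "kdn": 0.01, "k1": 0.6, "k2": 0.2, "k3": 1.2, "k4": 0.6,
    "V1P": 8.0, "V2P": 1.0, "V3P": 8.0, "V4P": 1.0,
    "V1T": 8.0, "V2T": 1.0, "V3T": 8.0, "V4T": 1.0,
    "K1P": 2.0, "K2P": 2.0, "K3P": 2.0, "K4P": 2.0,
    "K1T": 2.0, "K2T": 2.0, "K3T": 2.0, "K4T": 2.0,
    "nH": 4,
}

CIRCADIAN_SPECIES = ("MP", "P0", "P1", "P2", "MT", "T0", "T1", "T2", "C", "CN")

#: 21 rate processes: (reactants, products, rate template)
CIRCADIAN_REACTIONS = [
    ({}, {"MP": 1}, "{vsP} * {KIP}**{nH} / ({KIP}**{nH} + CN**{nH})"),
    ({"MP": 1}, {}, "{vmP} * MP / ({KmP} + MP)"),
    ({}, {"P0": 1}, "{ksP} * MP"),
    ({"P0": 1}, {"P1": 1}, "{V1P} * P0 / ({K1P} + P0)"),
    ({"P1": 1}, {"P0": 1}, "{V2P} * P1 / ({K2P} + P1)"),
    ({"P1": 1}, {"P2": 1}, "{V3P} * P1 / ({K3P} + P1)"),
    ({"P2": 1}, {"P1": 1}, "{V4P} * P2 / ({K4P} + P2)"),
    ({"P2": 1}, {}, "{vdP} * P2 / ({KdP} + P2)"),
    ({}, {"MT": 1}, "{vsT} * {KIT}**{nH} / ({KIT}**{nH} + CN**{nH})"),
    ({"MT": 1}, {}, "{vmT} * MT / ({KmT} + MT)"),
    ({}, {"T0": 1}, "{ksT} * MT"),
    ({"T0": 1}, {"T1": 1}, "{V1T} * T0 / ({K1T} + T0)"),
    ({"T1": 1}, {"T0": 1}, "{V2T} * T1 / ({K2T} + T1)"),
    ({"T1": 1}, {"T2": 1}, "{V3T} * T1 / ({K3T} + T1)"),
    ({"T2": 1}, {"T1": 1}, "{V4T} * T2 / ({K4T} + T2)"),
    ({"T2": 1}, {}, "{vdT} * T2 / ({KdT} + T2)"),
    ({"P2": 1, "T2": 1}, {"C": 1}, "{k3} * P2 * T2"),
    ({"C": 1}, {"P2": 1, "T2": 1}, "{k4} * C"),
    ({"C": 1}, {"CN": 1}, "{k1} * C"),
    ({"CN": 1}, {"C": 1}, "{k2} * CN"),
    ({"CN": 1}, {}, "{kdn} * CN"),
]

#: starting concentrations (nM); the limit cycle is reached after a
#: transient of ~100 h from here
CIRCADIAN_INITIAL = {"MP": 0.1, "P0": 0.1, "P1": 0.1, "P2": 0.1,
                     "MT": 0.1, "T0": 0.1, "T1": 0.1, "T2": 0.1,
                     "C": 0.2, "CN": 1.0}


def build_circadian() -> RxdModel:
    """Point RxD model of the PER/TIM oscillator (units: nM, hours)."""
    model = RxdModel()
    region = Region(kind="point", name="cytosol+nucleus")
    for name in CIRCADIAN_SPECIES:
        model.declare_species(name, region, initial=CIRCADIAN_INITIAL[name])
    for reac, prod, rate in CIRCADIAN_REACTIONS:
        model.add_reaction(Reaction(reactants=dict(reac), products=dict(prod),
                                    rate_f=rate.format(**CIRCADIAN_PARAMS),
                                    mass_action=False))
    return model


def circadian_yaml() -> str:
    """On-disk form of the circadian fixture (species/reactions/initials)."""
    doc = {
        "kind": "point_reactions",
        "units": {"concentration": "nM", "time": "hour"},
        "species": list(CIRCADIAN_SPECIES),
        "initial": {k: float(v) for k, v in CIRCADIAN_INITIAL.items()},
        "reactions": [
            {"reactants": dict(reac), "products": dict(prod),
             "rate": rate.format(**CIRCADIAN_PARAMS)}
            for reac, prod, rate in CIRCADIAN_REACTIONS],
        "sim": {"dt_hours": 0.005, "transient_hours": 100.0,
                "record_hours": 30.0},
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_reaction_yaml(text: str) -> RxdModel:
    """Rebuild a point RxD model from its YAML form."""
    doc = yaml.safe_load(text)
    model = RxdModel()
    region = Region(kind="point")
    for name in doc["species"]:
        model.declare_species(name, region,
                              initial=float(doc["initial"].get(name, 0.0)))
    for entry in doc["reactions"]:
        model.add_reaction(Reaction(
            reactants={k: int(v) for k, v in (entry.get("reactants") or {}).items()},
            products={k: int(v) for k, v in (entry.get("products") or {}).items()},
            rate_f=entry["rate"], mass_action=False))
    return model


# ---------------------------------------------------------------------------
# on-disk generation


def _write_mechanisms(outdir: Path, names) -> list[str]:
    files = []
    for name in names:
        path = outdir / f"{name}.mod"
        path.write_text(SOURCES[name])
        files.append(path.name)
    return files


def gen_fixture(name: str, outdir, seed: int = 0, params: dict | None = None):
    """Write a named fixture's files into ``outdir``; returns the file list.

    Deterministic per (name, seed, params).
    """
    params = dict(params or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "ball_and_stick":
        (outdir / "ball_and_stick.swc").write_text(ball_and_stick_swc())
        mods = _write_mechanisms(outdir, ["hh", "pas", "stim"])
        cfg = {
            "morphology": {"file": "ball_and_stick.swc", "nseg": {0: 1, 1: 11}},
            "mechanisms": [{"file": f} for f in mods],
            "cells": 1,
            "placements": [
                {"cell": 0, "section": 0, "mech": "hh"},
                {"cell": 0, "section": 1, "mech": "pas",
                 "params": {"g": 0.0005, "e": -65.0}},
            ],
            "point_processes": [
                {"id": "stim0", "cell": 0, "section": 0, "x": 0.5,
                 "mech": "stim",
                 "params": {"onset": 1.0, "dur": 3.0,
                            "amp": float(params.get("amp", 0.5))}},
            ],
            "detectors": [{"cell": 0, "section": 0, "x": 0.5, "threshold": -20.0}],
            "recordings": [{"kind": "v", "cell": 0, "section": 0, "x": 0.5,
                            "name": "v_soma"}],
            "sim": {"dt": 0.025, "tstop": 10.0, "v_init": -65.0,
                    "celsius": 6.3, "seed": seed, "backend": "reference"},
            "outputs": {"recordings": "recordings.csv", "raster": "raster.txt"},
        }
    elif name == "random_tree":
        (outdir / "random_tree.swc").write_text(random_tree_swc(seed))
        mods = _write_mechanisms(outdir, ["pas", "stim"])
        cfg = {
            "morphology": {"file": "random_tree.swc", "nseg": 3},
            "mechanisms": [{"file": f} for f in mods],
            "cells": 1,
            "placements": [{"cell": 0, "section": "all", "mech": "pas"}],
            "point_processes": [
                {"id": "stim0", "cell": 0, "section": 0, "x": 0.5,
                 "mech": "stim", "params": {"onset": 1.0, "dur": 5.0, "amp": 0.2}}],
            "detectors": [],
            "recordings": [{"kind": "v", "cell": 0, "section": 0, "x": 0.5,
                            "name": "v_root"}],
            "sim": {"dt": 0.025, "tstop": 10.0, "v_init": -65.0,
                    "celsius": 6.3, "seed": seed, "backend": "reference"},
            "outputs": {"recordings": "recordings.csv", "raster": "raster.txt"},
        }
    elif name == "ring_network":
        n_cells = int(params.get("n_cells", 8))
        (outdir / "ball_and_stick.swc").write_text(ball_and_stick_swc())
        mods = _write_mechanisms(outdir, ["hh", "pas", "expsyn"])
        cfg = {
            "morphology": {"file": "ball_and_stick.swc", "nseg": {0: 1, 1: 11}},
            "mechanisms": [{"file": f} for f in mods],
            "cells": n_cells,
            "placements": (
                [{"cell": k, "section": 0, "mech": "hh"} for k in range(n_cells)]
                + [{"cell": k, "section": 1, "mech": "pas",
                    "params": {"g": 0.0005, "e": -65.0}} for k in range(n_cells)]),
            "point_processes": [
                {"id": f"syn{k}", "cell": k, "section": 1, "x": 0.5,
                 "mech": "expsyn", "params": {"tau": 2.0, "e": 0.0}}
                for k in range(n_cells)],
            "detectors": [{"cell": k, "section": 0, "x": 0.5, "threshold": -20.0}
                          for k in range(n_cells)],
            "connections": [
                {"source": k, "target": f"syn{(k + 1) % n_cells}",
                 "weight": 0.05, "delay": 2.0} for k in range(n_cells)],
            "drives": [{"target": "syn0", "times": [1.0], "weight": 0.05}],
            "recordings": [{"kind": "v", "cell": 0, "section": 0, "x": 0.5,
                            "name": "v_cell0"}],
            "sim": {"dt": 0.025, "tstop": 60.0, "v_init": -65.0,
                    "celsius": 6.3, "seed": seed, "backend": "reference"},
            "outputs": {"recordings": "recordings.csv", "raster": "raster.txt"},
        }
    elif name == "test_cylinder":
        (outdir / "test_cylinder.swc").write_text(test_cylinder_swc())
        mods = _write_mechanisms(outdir, ["pas", "stim"])
        cfg = {
            "morphology": {"file": "test_cylinder.swc", "nseg": 1001},
            "mechanisms": [{"file": f} for f in mods],
            "cells": 1,
            "placements": [{"cell": 0, "section": 0, "mech": "pas",
                            "params": {"g": 0.001, "e": -65.0}}],
            "point_processes": [
                {"id": "stim0", "cell": 0, "section": 0, "x": 0.0,
                 "mech": "stim", "params": {"onset": 0.0, "dur": 1e9,
                                            "amp": 0.1}}],
            "detectors": [],
            "recordings": [
                {"kind": "v", "cell": 0, "section": 0, "x": 0.0, "name": "v_0"},
                {"kind": "v", "cell": 0, "section": 0, "x": 0.5, "name": "v_mid"},
                {"kind": "v", "cell": 0, "section": 0, "x": 1.0, "name": "v_L"}],
            "sim": {"dt": 0.1, "tstop": 100.0, "v_init": -65.0,
                    "celsius": 6.3, "seed": seed, "backend": "reference"},
            "outputs": {"recordings": "recordings.csv", "raster": "raster.txt"},
        }
    elif name == "circadian":
        (outdir / "circadian.yaml").write_text(circadian_yaml())
        return ["circadian.yaml"]
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    files = sorted(p.name for p in outdir.iterdir())
    return files
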