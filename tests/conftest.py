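"""Shared fixtures: small cells and models built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from cajal.engine import Model, SimConfig, Simulation
from cajal.morphology import Morphology, Section, discretize


def make_cylinder_cell(length=200.0, diam=2.0, nseg=101, ra=100.0, cm=1.0):
    sec = Section(id=0, parent_id=None, parent_position=0.0,
                  points=np.array([[0.0, 0.0, 0.0, diam],
                                   [length, 0.0, 0.0, diam]]), name="cyl")
    return discretize(Morphology([sec]), nseg=nseg, ra=ra, cm=cm)


def make_soma_cell(diam=18.8):
    """Single-compartment cylinder with L = d (sphere-equivalent surface)."""
    sec = Section(id=0, parent_id=None, parent_position=0.0,
                  points=np.array([[0.0, 0.0, 0.0, diam],
                                   [diam, 0.0, 0.0, diam]]), name="soma")
    return discretize(Morphology([sec]), nseg=1)


def make_y_morphology(trunk=200.0, branch_a=100.0, branch_b=50.0):
    trunk_sec = Section(id=0, parent_id=None, parent_position=0.0,
                        points=np.array([[0, 0, 0, 2], [trunk, 0, 0, 2.0]],
                                        dtype=float))
    a = Section(id=1, parent_id=0, parent_position=1.0,
                points=np.array([[trunk, 0, 0, 1], [trunk, branch_a, 0, 1.0]],
                                dtype=float))
    b = Section(id=2, parent_id=0, parent_position=1.0,
                points=np.array([[trunk, 0, 0, 1], [trunk, -branch_b, 0, 1.0]],
                                dtype=float))
    return Morphology([trunk_sec, a, b])


@pytest.fixture
def soma_hh_sim():
    """Single hh compartment with a 0.5 nA step and a spike detector."""
    def factory(dt=0.025, tstop=10.0, amp=0.5, onset=1.0, dur=3.0):
        model = Model()
        ci = model.add_cell(make_soma_cell())
        model.insert(ci, 0, "hh")
        model.place(ci, 0, 0.5, "stim", onset=onset, dur=dur, amp=amp)
        model.add_detector(ci, 0, 0.5, threshold=-20.0)
        sim = Simulation(model, SimConfig(dt=dt, tstop=tstop))
        sim.record_v(ci, 0, 0.5, name="v_soma")
        return sim
    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
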