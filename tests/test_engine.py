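"""Engine: build/init/step semantics, dual-backend parity, transfer."""

import heapq

import numpy as np
import pytest

from cajal.engine import (Model, SimConfig, Simulation, advance_step, build,
                          finitialize, to_compact, to_reference, to_transfer,
                          apply_transfer)
from cajal.errors import ConsistencyError
from cajal.fixtures import build_ball_and_stick, build_ring
from conftest import make_cylinder_cell


def bare_cable_model(nseg=10):
    model = Model()
    model.add_cell(make_cylinder_cell(length=100.0, diam=2.0, nseg=nseg))
    return model


class TestBuild:
    def test_hh_instances_only_on_soma(self):
        model, info = build_ball_and_stick()
        state = build(model, SimConfig())
        hh_nodes = {inst.node for inst in state.inst_by_mech["hh"]}
        start, nseg = model.cells[0].section_ranges[info["soma"]]
        assert hh_nodes == set(range(start, start + nseg))

    def test_empty_model_advances_time_only(self):
        state = build(bare_cable_model(), SimConfig(dt=0.025))
        finitialize(state, -65.0)
        v0 = list(state.v)
        advance_step(state)
        assert state.t == pytest.approx(0.025)
        np.testing.assert_allclose(state.v, v0)

    def test_ring_fixture_record_count(self):
        model, _ = build_ring(n_cells=4, nseg_dend=11)
        state = build(model, SimConfig())
        per_cell = model.cells[0].n
        assert len(state.records) == 4 * per_cell

    def test_unknown_section_placement_is_key_error(self):
        model = bare_cable_model()
        with pytest.raises(KeyError):
            model.insert(0, 99, "pas")


class TestFinitialize:
    def test_hh_states_at_steady_state(self, soma_hh_sim):
        sim = soma_hh_sim()
        sim.finitialize(-65.0)
        inst = sim.state.inst_by_mech["hh"][0]
        v = -65.0
        am = 0.1 * (v + 40) / (1 - np.exp(-(v + 40) / 10))
        bm = 4 * np.exp(-(v + 65) / 18)
        assert inst.vals["m"] == pytest.approx(am / (am + bm), rel=1e-12)

    def test_idempotent(self, soma_hh_sim):
        sim = soma_hh_sim()
        sim.finitialize(-65.0)
        img1 = to_transfer(sim.state)
        sim.finitialize(-65.0)
        img2 = to_transfer(sim.state)
        np.testing.assert_array_equal(img1.v, img2.v)
        for mech in img1.mech_vals:
            for var in img1.mech_vals[mech]:
                np.testing.assert_array_equal(img1.mech_vals[mech][var],
                                              img2.mech_vals[mech][var])

    def test_resting_stability_without_stimulus(self, soma_hh_sim):
        sim = soma_hh_sim(amp=0.0)
        sim.finitialize(-65.0)
        for _ in range(1000):
            advance_step(sim.state)
        assert abs(sim.state.v[0] - (-65.0)) <= 0.5


class TestAdvanceStep:
    def test_event_at_exact_half_step_delivered_now(self):
        model = bare_cable_model()
        syn = model.place(0, 0, 0.5, "expsyn")
        state = build(model, SimConfig(dt=0.1))
        finitialize(state, -65.0)
        heapq.heappush(state.queue, (0.05, 0, syn, 0.002))  # t + dt/2 exactly
        advance_step(state)
        assert state.pp_index[syn].vals["g"] > 0.0

    def test_event_after_half_step_deferred(self):
        model = bare_cable_model()
        syn = model.place(0, 0, 0.5, "expsyn")
        state = build(model, SimConfig(dt=0.1))
        finitialize(state, -65.0)
        heapq.heappush(state.queue, (0.0501, 0, syn, 0.002))
        advance_step(state)
        assert state.pp_index[syn].vals["g"] == 0.0
        advance_step(state)
        assert state.pp_index[syn].vals["g"] > 0.0

    def test_charge_conservation_bare_cable(self):
        """Axial redistribution conserves total charge sum C_i V_i."""
        model = bare_cable_model(nseg=20)
        state = build(model, SimConfig(dt=0.025))
        finitialize(state, -65.0)
        v = np.linspace(-80.0, -40.0, 20)
        state.set_v(v)
        c = model.c_nF
        q0 = float(c @ v)
        for _ in range(50):
            qa = float(c @ np.array(state.v))
            advance_step(state)
            qb = float(c @ np.array(state.v))
            assert abs(qb - qa) <= 1e-9 * abs(qa)
        assert abs(float(c @ np.array(state.v)) - q0) <= 1e-7 * abs(q0)

    def test_timing_table_has_exact_phase_names(self, soma_hh_sim):
        sim = soma_hh_sim()
        sim.finitialize()
        sim.psolve(1.0, "compact")
        assert set(sim.timing) == {
            "event delivery", "current calculation", "matrix solver",
            "state update", "spike detection/exchange", "data transfer"}


class TestTransfer:
    def test_roundtrip_is_bit_identical(self, soma_hh_sim):
        sim = soma_hh_sim()
        sim.finitialize()
        sim.psolve(1.0, "reference")
        before = to_transfer(sim.state)
        compact = to_compact(sim.state, sim.ordering)
        to_reference(compact, sim.state)
        after = to_transfer(sim.state)
        np.testing.assert_array_equal(before.v, after.v)
        for mech in before.mech_vals:
            for var, arr in before.mech_vals[mech].items():
                np.testing.assert_array_equal(arr, after.mech_vals[mech][var])
        assert before.events == after.events
        assert before.t == after.t

    def test_queue_multiset_preserved(self):
        model = bare_cable_model()
        syn = model.place(0, 0, 0.5, "expsyn")
        model.drive(syn, [3.0, 4.0, 5.0], 0.001)
        state = build(model, SimConfig())
        finitialize(state, -65.0)
        compact = to_compact(state)
        triples_ref = sorted((t, tgt, w) for t, _s, tgt, w in state.queue)
        triples_cmp = sorted((t, tgt, w) for t, _s, tgt, w in compact.queue)
        assert triples_ref == triples_cmp
        assert len(triples_cmp) == 3

    def test_compact_state_arrays_follow_permutation(self):
        """hh m-values are contiguous, ordered by permuted node index."""
        model, info = build_ring(n_cells=3, nseg_dend=5)
        state = build(model, SimConfig())
        finitialize(state, -65.0)
        compact = to_compact(state)
        data = compact.mech_data["hh"]
        assert np.all(np.diff(data["nodes"]) >= 0)
        # explicit gather oracle: reference m values by permuted order
        ref_m = np.array([inst.vals["m"] for inst in state.inst_by_mech["hh"]])
        ref_nodes = np.array([inst.node for inst in state.inst_by_mech["hh"]])
        order = np.argsort(compact.ordering.inv[ref_nodes], kind="stable")
        np.testing.assert_array_equal(data["vals"]["m"], ref_m[order])

    def test_shape_mismatch_raises_consistency_error(self):
        model_a = bare_cable_model(nseg=10)
        model_b = bare_cable_model(nseg=11)
        state_a = build(model_a, SimConfig())
        state_b = build(model_b, SimConfig())
        finitialize(state_a, -65.0)
        img = to_transfer(state_a)
        with pytest.raises(ConsistencyError):
            apply_transfer(img, state_b)

    def test_events_beyond_switch_time_survive_and_deliver(self):
        model = bare_cable_model()
        syn = model.place(0, 0, 0.5, "expsyn")
        model.drive(syn, [0.8], 0.003)
        config = SimConfig(dt=0.1, tstop=2.0)
        sim = Simulation(model, config)
        sim.finitialize(-65.0)
        sim.psolve(0.5, "reference")
        assert len(sim.state.queue) == 1
        sim.psolve(2.0, "compact")  # event delivered inside the compact run
        assert len(sim.state.queue) == 0
        assert sim.state.pp_index[syn].vals["g"] > 0.0


class TestPsolve:
    def test_tstop_equal_t_is_noop(self, soma_hh_sim):
        sim = soma_hh_sim()
        sim.finitialize()
        n0 = len(sim.recorders[0].times)
        sim.psolve(0.0)
        assert len(sim.recorders[0].times) == n0

    def test_tstop_before_t_rejected(self, soma_hh_sim):
        sim = soma_hh_sim()
        sim.finitialize()
        sim.psolve(1.0)
        with pytest.raises(ValueError):
            sim.psolve(0.5)

    def test_backend_parity_on_voltage_and_state(self, soma_hh_sim):
        runs = {}
        for backend in ("reference", "compact"):
            sim = soma_hh_sim(dt=0.025, tstop=8.0)
            m_rec = sim.record_var((0, 0, 0.5, "hh"), "m", name="m")
            sim.finitialize(-65.0)
            sim.psolve(8.0, backend)
            runs[backend] = (np.array(sim.recorders[0].values),
                             np.array(m_rec.values), sim.spikes)
        v_ref, m_ref, sp_ref = runs["reference"]
        v_cmp, m_cmp, sp_cmp = runs["compact"]
        np.testing.assert_allclose(v_cmp, v_ref, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(m_cmp, m_ref, rtol=1e-8, atol=1e-10)
        assert sp_ref == sp_cmp

    def test_midrun_switch_matches_single_backend(self, soma_hh_sim):
        sim_a = soma_hh_sim(tstop=10.0)
        sim_a.finitialize(-65.0)
        sim_a.psolve(0.5, "reference")
        sim_a.psolve(10.0, "compact")
        sim_b = soma_hh_sim(tstop=10.0)
        sim_b.finitialize(-65.0)
        sim_b.psolve(10.0, "compact")
        va = np.array(sim_a.recorders[0].values)
        vb = np.array(sim_b.recorders[0].values)
        assert np.max(np.abs(va - vb)) <= 1e-6
        ta = [t for t, _ in sim_a.spikes]
        tb = [t for t, _ in sim_b.spikes]
        assert len(ta) == len(tb)
        assert all(abs(x - y) <= 0.025 + 1e-12 for x, y in zip(ta, tb))

    def test_repeat_runs_are_byte_identical(self, soma_hh_sim):
        def run_bytes():
            sim = soma_hh_sim(tstop=3.0)
            sim.finitialize(-65.0)
            sim.psolve(3.0, "compact")
            return np.array(sim.recorders[0].values).tobytes()

        assert run_bytes() == run_bytes()
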