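"""Networking: spike detection, event scheduling, stimulus streams."""

import numpy as np
import pytest

from cajal.engine import Model, SimConfig, Simulation
from cajal.fixtures import build_ring
from cajal.network import (Connection, StimSource, detect_spikes, schedule,
                           stim_times)
from conftest import make_soma_cell


class TestDetectSpikes:
    def test_constant_subthreshold_no_spikes(self):
        spikes, _ = detect_spikes([-60.0], [-60.0], -20.0, t=1.0, dt=0.1)
        assert spikes == []

    def test_crossing_fires_at_step_end(self):
        spikes, above = detect_spikes([-60.0], [-10.0], -20.0, t=1.0, dt=0.1)
        assert spikes == [(1.1, 0)]
        assert above[0]

    def test_rearm_requires_falling_below(self):
        above = None
        spikes1, above = detect_spikes([-60.0], [-10.0], -20.0, 0.0, 0.1, above)
        spikes2, above = detect_spikes([-10.0], [-5.0], -20.0, 0.1, 0.1, above)
        spikes3, above = detect_spikes([-5.0], [-40.0], -20.0, 0.2, 0.1, above)
        spikes4, above = detect_spikes([-40.0], [0.0], -20.0, 0.3, 0.1, above)
        assert len(spikes1) == 1 and spikes2 == [] and spikes3 == []
        assert len(spikes4) == 1

    def test_engine_raster_matches_offline_threshold_scan(self, soma_hh_sim):
        sim = soma_hh_sim(tstop=10.0, amp=0.5, dur=8.0)
        sim.finitialize(-65.0)
        sim.psolve(10.0)
        trace = np.array(sim.recorders[0].values)
        above = None
        offline = []
        for k in range(len(trace) - 1):
            sp, above = detect_spikes([trace[k]], [trace[k + 1]], -20.0,
                                      k * 0.025, 0.025, above)
            offline.extend(sp)
        assert len(offline) == len(sim.spikes)
        for (t_off, _), (t_eng, _) in zip(offline, sim.spikes):
            assert t_off == pytest.approx(t_eng, abs=1e-9)


class TestScheduleDeliver:
    def test_delay_added(self):
        conn = Connection(source_gid=0, target=3, weight=0.1, delay=1.0)
        ev = schedule(conn, spike_time=5.0, seq=7)
        assert ev.time == 6.0 and ev.target == 3 and ev.weight == 0.1

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            Connection(source_gid=0, target=0, weight=0.1, delay=-1.0)

    def test_fifo_on_equal_times(self):
        a = schedule(Connection(0, 1, 0.1, 1.0), 5.0, seq=0)
        b = schedule(Connection(0, 2, 0.2, 1.0), 5.0, seq=1)
        assert sorted([b, a]) == [a, b]

    def test_simultaneous_weights_add(self):
        model = Model()
        model.add_cell(make_soma_cell())
        syn = model.place(0, 0, 0.5, "expsyn", tau=2.0)
        model.drive(syn, [0.51], 0.001)
        model.drive(syn, [0.51], 0.002)
        sim = Simulation(model, SimConfig(dt=0.1, tstop=2.0))
        sim.finitialize(-65.0)
        sim.psolve(0.6)
        g = sim.state.pp_index[syn].vals["g"]
        # both events land in the step from 0.5 to 0.6 (window (0.5, 0.55]),
        # add, then decay over that step
        assert g == pytest.approx(0.003 * np.exp(-0.1 / 2.0), rel=1e-9)

    def test_expsyn_decay_matches_exact_update(self):
        model = Model()
        model.add_cell(make_soma_cell())
        syn = model.place(0, 0, 0.5, "expsyn", tau=2.0)
        model.drive(syn, [0.2], 0.01)
        sim = Simulation(model, SimConfig(dt=0.1, tstop=5.0))
        rec = sim.record_var(syn, "g", name="g")
        sim.finitialize(-65.0)
        sim.psolve(5.0)
        g = np.array(rec.values)
        t = np.array(rec.times)
        # delivered in the step ending at 0.3 (window (0.1, 0.25] misses 0.2;
        # the step from 0.2 to 0.3 delivers it), then pure exponential decay
        k0 = int(np.argmax(g > 0))
        expected = g[k0] * np.exp(-(t[k0 + 1:] - t[k0]) / 2.0)
        np.testing.assert_allclose(g[k0 + 1:], expected, rtol=1e-9)

    def test_ring_first_spikes_monotone_in_gid(self):
        model, _ = build_ring(n_cells=5)
        sim = Simulation(model, SimConfig(dt=0.025, tstop=40.0))
        sim.finitialize(-65.0)
        sim.psolve(40.0, "compact")
        first = {}
        for t, gid in sorted(sim.spikes):
            first.setdefault(gid, t)
        assert sorted(first) == list(range(5))
        times = [first[g] for g in range(5)]
        assert all(b > a for a, b in zip(times, times[1:]))
        hops = np.diff(times)
        np.testing.assert_allclose(hops, hops[0], atol=0.025 + 1e-9)

    def test_min_delay_no_same_step_delivery(self):
        model = Model()
        model.add_cell(make_soma_cell())
        model.insert(0, 0, "hh")
        syn = model.place(0, 0, 0.5, "expsyn")
        model.place(0, 0, 0.5, "stim", onset=1.0, dur=2.0, amp=0.5)
        model.add_detector(0, 0, 0.5, threshold=-20.0)
        model.connect(0, syn, weight=0.001, delay=0.025)  # delay == dt
        sim = Simulation(model, SimConfig(dt=0.025, tstop=5.0))
        sim.finitialize(-65.0)
        sim.psolve(5.0)
        assert len(sim.spikes) >= 1
        spike_t = sim.spikes[0][0]
        # delivery at spike_t + delay lies beyond the window of the step
        # that created it, so g is still zero right after that step
        assert sim.state.pp_index[syn].vals["g"] >= 0.0


class TestStimTimes:
    def test_stim_source_drives_synapse_in_engine(self):
        model = Model()
        model.add_cell(make_soma_cell())
        syn = model.place(0, 0, 0.5, "expsyn", tau=2.0)
        src = StimSource(kind="regular", start=1.0, interval=1.0, count=3)
        model.drive(syn, src, weight=0.001)
        sim = Simulation(model, SimConfig(dt=0.1, tstop=5.0))
        sim.finitialize(-65.0)
        assert len(sim.state.queue) == 3
        sim.psolve(5.0)
        assert len(sim.state.queue) == 0
        assert sim.state.pp_index[syn].vals["g"] > 0.0

    def test_regular_train(self):
        src = StimSource(kind="regular", start=10.0, interval=5.0, count=3)
        np.testing.assert_allclose(stim_times(src), [10.0, 15.0, 20.0])

    def test_same_key_reproduces_sequence(self):
        a = StimSource(kind="poisson", start=0.0, interval=10.0, count=50,
                       gid=7, stream=2, seed=42)
        b = StimSource(kind="poisson", start=0.0, interval=10.0, count=50,
                       gid=7, stream=2, seed=42)
        np.testing.assert_array_equal(stim_times(a), stim_times(b))

    def test_different_keys_differ(self):
        a = StimSource(kind="poisson", start=0.0, interval=10.0, count=50,
                       gid=7, stream=2, seed=42)
        b = StimSource(kind="poisson", start=0.0, interval=10.0, count=50,
                       gid=8, stream=2, seed=42)
        assert not np.array_equal(stim_times(a), stim_times(b))

    def test_call_order_independence(self):
        keys = [(g, s) for g in range(5) for s in range(2)]
        fwd = {k: stim_times(StimSource("poisson", 0.0, 5.0, 20,
                                        gid=k[0], stream=k[1], seed=1))
               for k in keys}
        rev = {k: stim_times(StimSource("poisson", 0.0, 5.0, 20,
                                        gid=k[0], stream=k[1], seed=1))
               for k in reversed(keys)}
        for k in keys:
            np.testing.assert_array_equal(fwd[k], rev[k])

    def test_poisson_statistics(self):
        n = 100_000
        src = StimSource(kind="poisson", start=0.0, interval=10.0, count=n,
                         gid=1, stream=0, seed=3)
        times = stim_times(src)
        assert np.all(np.diff(times) > 0)
        intervals = np.diff(np.concatenate([[0.0], times]))
        se = 10.0 / np.sqrt(n)
        assert abs(intervals.mean() - 10.0) <= 3 * se

    def test_invalid_kind_and_interval(self):
        with pytest.raises(ValueError):
            StimSource(kind="gamma", start=0.0, interval=1.0, count=1)
        with pytest.raises(ValueError):
            StimSource(kind="regular", start=0.0, interval=0.0, count=1)
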