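"""State archive: byte determinism, layout, extensions, resume equality."""

import struct
import zlib

import numpy as np
import pytest

from cajal.engine import Model, SimConfig, Simulation
from cajal.errors import (ConflictError, ConsistencyError,
                          UnsupportedExtensionError)
from cajal.rxd import Region, RxdModel
from cajal.state_io import (ExtensionEntry, attach_rxd, inspect_state,
                            register_extension, registered_extensions,
                            restore_state, save_state, serialize_state)
from conftest import make_soma_cell


def hh_sim(tstop=10.0):
    model = Model()
    model.add_cell(make_soma_cell())
    model.insert(0, 0, "hh")
    model.place(0, 0, 0.5, "stim", onset=1.0, dur=3.0, amp=0.5)
    model.add_detector(0, 0, 0.5)
    sim = Simulation(model, SimConfig(dt=0.025, tstop=tstop))
    sim.record_v(0, 0, 0.5, name="v")
    return sim


class TestBasePayload:
    def test_repeat_save_is_byte_identical_and_trailerless(self, tmp_path):
        sim = hh_sim()
        sim.finitialize(-65.0)
        sim.psolve(2.0)
        a = serialize_state(sim)
        b = serialize_state(sim)
        assert a == b
        version = struct.unpack("<I", a[4:8])[0]
        assert version == 0  # no extensions -> no trailer

    def test_base_payload_length_matches_layout_table(self):
        sim = hh_sim()
        sim.finitialize(-65.0)
        data = serialize_state(sim)
        n_v = 1
        mechs = sim.model.instances
        var_bytes = 0
        name_bytes = 0
        for mech, entries in mechs.items():
            spec = sim.model.mechanisms[mech]["spec"]
            name_bytes += 4 + len(mech) + 12  # name + n_inst(u64) + n_var(u32)
            for var in spec.instance_vars():
                name_bytes += 4 + len(var)
                var_bytes += 8 * len(entries)
        n_events = len(sim.state.queue)
        expected = (4 + 4 + 8  # magic, version, t
                    + 8 + 8 * n_v  # n_comp + voltages
                    + 4 + name_bytes + var_bytes  # mechanism block
                    + 8 + 32 * n_events  # event block
                    + 8  # seq counter
                    + 4 + len(sim.model.detectors))  # detector flags
        assert len(data) == expected

    def test_inspect_reports_header(self, tmp_path):
        sim = hh_sim()
        sim.finitialize(-65.0)
        sim.psolve(1.0)
        path = tmp_path / "s.bin"
        save_state(sim, path)
        info = inspect_state(path)
        assert info["t"] == pytest.approx(1.0)
        assert info["n_comp"] == 1
        assert "hh" in info["mechanisms"]
        assert info["extensions"] == []


class TestRestore:
    def test_save_restore_resume_matches_uninterrupted(self, tmp_path):
        sim_a = hh_sim()
        sim_a.finitialize(-65.0)
        sim_a.psolve(5.0)
        path = tmp_path / "mid.bin"
        save_state(sim_a, path)
        sim_a.psolve(10.0)
        v_full = np.array(sim_a.recorders[0].values)

        sim_b = hh_sim()
        sim_b.finitialize(-65.0)
        restore_state(sim_b, path)
        assert sim_b.state.t == pytest.approx(5.0)
        sim_b.psolve(10.0)
        v_resumed = np.array(sim_b.recorders[0].values)
        # overlap region 5 -> 10 ms is bit-identical
        tail = len(v_resumed) - 1  # resumed: t=0 sample + 200 steps
        assert v_resumed[1:].tobytes() == v_full[-tail:].tobytes()

    def test_restore_into_larger_model_is_consistency_error(self, tmp_path):
        sim = hh_sim()
        sim.finitialize(-65.0)
        path = tmp_path / "s.bin"
        save_state(sim, path)
        other = Model()
        other.add_cell(make_soma_cell())
        other.add_cell(make_soma_cell())  # one extra compartment
        other.insert(0, 0, "hh")
        sim2 = Simulation(other, SimConfig())
        sim2.finitialize()
        with pytest.raises(ConsistencyError):
            restore_state(sim2, path)

    def test_unknown_extension_error_names_it(self, tmp_path):
        sim = hh_sim()
        sim.finitialize(-65.0)
        data = serialize_state(sim)
        # forge a version-1 archive with an unknown extension record
        payload = b"\x00" * 4
        trailer = (struct.pack("<I", 1) + struct.pack("<I", 3) + b"foo"
                   + struct.pack("<Q", len(payload)) + payload)
        forged = data[:4] + struct.pack("<I", 1) + data[8:] + trailer
        path = tmp_path / "forged.bin"
        path.write_bytes(forged)
        sim2 = hh_sim()
        sim2.finitialize(-65.0)
        with pytest.raises(UnsupportedExtensionError, match="foo"):
            restore_state(sim2, path)


class TestExtensions:
    def test_duplicate_registration_conflicts(self):
        name = "dup-test-ext"
        register_extension(ExtensionEntry(name, lambda sim: None,
                                          lambda sim, b: None))
        try:
            with pytest.raises(ConflictError):
                register_extension(ExtensionEntry(name, lambda sim: None,
                                                  lambda sim, b: None))
        finally:
            from cajal import state_io

            state_io._registry.pop(name, None)

    def test_rxd_registers_on_species_declaration_not_import(self):
        import cajal.rxd  # noqa: F401  (import alone must not register)
        from cajal import state_io

        state_io._registry.pop("rxd", None)
        assert "rxd" not in registered_extensions()
        model = RxdModel()
        model.declare_species("ca", Region(kind="point"), initial=0.1)
        assert "rxd" in registered_extensions()

    def test_model_with_species_gets_rxd_trailer(self, tmp_path):
        sim = hh_sim()
        rxd_model = RxdModel()
        rxd_model.declare_species("ca", Region(kind="point"), initial=2.5)
        attach_rxd(sim, rxd_model)
        sim.finitialize(-65.0)
        path = tmp_path / "with_rxd.bin"
        save_state(sim, path)
        info = inspect_state(path)
        assert info["extensions"] == ["rxd"]

    def test_model_without_species_has_no_trailer(self, tmp_path):
        # the extension is registered globally by the previous declarations,
        # but a model with no RxD states writes no trailer
        sim = hh_sim()
        sim.finitialize(-65.0)
        data = serialize_state(sim)
        assert struct.unpack("<I", data[4:8])[0] == 0

    def test_rxd_payload_zlib_roundtrip_and_length(self, tmp_path):
        sim = hh_sim()
        rxd_model = RxdModel()
        sp = rxd_model.declare_species("ip3", Region(kind="point"),
                                       initial=0.25)
        attach_rxd(sim, rxd_model)
        sim.finitialize(-65.0)
        path = tmp_path / "rxd.bin"
        save_state(sim, path)
        raw = path.read_bytes()
        # trailer ends the file: ... "rxd", u64 length, zlib payload
        idx = raw.rfind(b"rxd") + 3
        length = struct.unpack("<Q", raw[idx:idx + 8])[0]
        payload = raw[idx + 8:idx + 8 + length]
        plain = zlib.decompress(payload)
        # one model, one species, one region with one f64 value
        sp.values[0][0] = 9.0
        restore_state(sim, path)
        assert sp.values[0][0] == 0.25
        # decompressed data embeds exactly 8 bytes of concentration data
        assert plain.endswith(struct.pack("<d", 0.25))
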