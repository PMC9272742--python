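"""Versioned binary state archive with registered save extensions.

Layout (all little-endian; strings are u32-length-prefixed UTF-8):

====================  =====================================================
field                 contents
====================  =====================================================
magic                 ``b"CAJS"``
version (u32)         0 = base payload only, 1 = extension trailer present
t (f64)               simulation clock (ms)
n_comp (u64)          compartment count, then n_comp f64 voltages (mV)
n_mech (u32)          then per mechanism: name, n_inst (u64), n_var (u32),
                      per variable: name + n_inst f64 values
n_events (u64)        per event: time f64, seq i64, target u64, weight f64
seq (i64)             event sequence counter
n_det (u32)           per detector: u8 above-threshold flag
[version 1 only]      n_ext (u32), per extension: identifier string,
                      payload length (u64), payload bytes
====================  =====================================================

Archives of models using no extensions carry no trailer (version 0) and are
byte-identical across repeat saves of the same state.  Extension payloads
are produced/consumed by registered :class:`ExtensionEntry` callbacks; the
reaction-diffusion extension registers itself when the first species is
declared (importing :mod:`cajal.rxd` alone does not register anything) and
zlib-compresses its concatenated concentration arrays.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .engine import Simulation, TransferImage, apply_transfer, to_transfer
from .errors import ConflictError, ConsistencyError, UnsupportedExtensionError

MAGIC = b"CAJS"


@dataclass
class ExtensionEntry:
    identifier: str
    serialize: Callable  # (Simulation) -> bytes | None (None = not present)
    restore: Callable  # (Simulation, bytes) -> None


_registry: dict[str, ExtensionEntry] = {}


def register_extension(entry: ExtensionEntry) -> None:
    if entry.identifier in _registry:
        raise ConflictError(
            f"save extension {entry.identifier!r} already registered")
    _registry[entry.identifier] = entry


def registered_extensions() -> tuple[str, ...]:
    return tuple(_registry)


def _reset_registry_for_tests() -> None:
    _registry.clear()
    global _rxd_hooked
    _rxd_hooked = False


# -- primitive writers/readers ----------------------------------------------


def _w_str(parts, s: str) -> None:
    raw = s.encode()
    parts.append(struct.pack("<I", len(raw)))
    parts.append(raw)


def _w_f64(parts, arr) -> None:
    parts.append(np.asarray(arr, dtype="<f8").tobytes())


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ConsistencyError("truncated archive")
        out = self.data[self.pos:self.pos + n]
        self.pos += n
        return out

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]

    def u64(self) -> int:
        return struct.unpack("<Q", self.take(8))[0]

    def i64(self) -> int:
        return struct.unpack("<q", self.take(8))[0]

    def f64(self) -> float:
        return struct.unpack("<d", self.take(8))[0]

    def f64s(self, n: int) -> np.ndarray:
        return np.frombuffer(self.take(8 * n), dtype="<f8").astype(float)

    def string(self) -> str:
        return self.take(self.u32()).decode()


# -- save / restore ----------------------------------------------------------


def serialize_state(sim: Simulation) -> bytes:
    """Archive bytes for a simulation's current state."""
    img = to_transfer(sim.state)
    ext_records = []
    for name in sorted(_registry):
        payload = _registry[name].serialize(sim)
        if payload is not None:
            ext_records.append((name, payload))
    version = 1 if ext_records else 0
    parts: list[bytes] = [MAGIC, struct.pack("<I", version),
                          struct.pack("<d", img.t),
                          struct.pack("<Q", len(img.v))]
    _w_f64(parts, img.v)
    mechs = list(img.mech_vals)
    parts.append(struct.pack("<I", len(mechs)))
    for mech in mechs:
        vals = img.mech_vals[mech]
        names = list(vals)
        n_inst = len(next(iter(vals.values()))) if names else 0
        _w_str(parts, mech)
        parts.append(struct.pack("<QI", n_inst, len(names)))
        for nm in names:
            _w_str(parts, nm)
            _w_f64(parts, vals[nm])
    parts.append(struct.pack("<Q", len(img.events)))
    for tt, seq, target, weight in img.events:
        parts.append(struct.pack("<dqQd", tt, seq, target, weight))
    parts.append(struct.pack("<q", img.seq))
    parts.append(struct.pack("<I", len(img.det_above)))
    parts.append(bytes(1 if flag else 0 for flag in img.det_above))
    if version == 1:
        parts.append(struct.pack("<I", len(ext_records)))
        for name, payload in ext_records:
            _w_str(parts, name)
            parts.append(struct.pack("<Q", len(payload)))
            parts.append(payload)
    return b"".join(parts)


def save_state(sim: Simulation, path) -> None:
    with open(path, "wb") as fh:
        fh.write(serialize_state(sim))


def _parse(data: bytes):
    rd = _Reader(data)
    if rd.take(4) != MAGIC:
        raise ConsistencyError("not a cajal state archive")
    version = rd.u32()
    if version not in (0, 1):
        raise ConsistencyError(f"unsupported archive version {version}")
    t = rd.f64()
    n_comp = rd.u64()
    v = rd.f64s(n_comp)
    mech_vals: dict[str, dict[str, np.ndarray]] = {}
    for _ in range(rd.u32()):
        mech = rd.string()
        n_inst = rd.u64()
        n_var = rd.u32()
        mech_vals[mech] = {rd.string(): rd.f64s(n_inst) for _ in range(n_var)}
    events = []
    for _ in range(rd.u64()):
        tt, seq, target, weight = struct.unpack("<dqQd", rd.take(32))
        events.append((tt, seq, target, weight))
    seq = rd.i64()
    det = [bool(b) for b in rd.take(rd.u32())]
    extensions = []
    if version == 1:
        for _ in range(rd.u32()):
            name = rd.string()
            length = rd.u64()
            extensions.append((name, rd.take(length)))
    img = TransferImage(t=t, v=v, mech_vals=mech_vals, events=events,
                        seq=seq, spikes=[], det_above=det)
    return img, extensions


def inspect_state(path) -> dict:
    """Header summary: t, counts, extension ids (for the CLI)."""
    with open(path, "rb") as fh:
        img, extensions = _parse(fh.read())
    return {
        "t": img.t,
        "n_comp": len(img.v),
        "mechanisms": {m: {nm: len(arr) for nm, arr in vals.items()}
                       for m, vals in img.mech_vals.items()},
        "n_events": len(img.events),
        "extensions": [name for name, _ in extensions],
    }


def restore_state(sim: Simulation, path) -> None:
    """Replace a simulation's state from an archive.

    The archive must match the constructed model (same compartment count,
    mechanisms, instance counts); resuming after restore is bit-identical
    to the uninterrupted run.
    """
    with open(path, "rb") as fh:
        img, extensions = _parse(fh.read())
    for name, _payload in extensions:
        if name not in _registry:
            raise UnsupportedExtensionError(
                f"archive uses unknown save extension {name!r}")
    apply_transfer(img, sim.state)  # raises ConsistencyError on mismatch
    for name, payload in extensions:
        _registry[name].restore(sim, payload)


# -- reaction-diffusion extension -------------------------------------------


def attach_rxd(sim: Simulation, model) -> None:
    """Associate an RxD model with a simulation so its concentrations are
    archived through the "rxd" save extension."""
    if not hasattr(sim, "rxd_models"):
        sim.rxd_models = []
    sim.rxd_models.append(model)


def _rxd_serialize(sim: Simulation) -> bytes | None:
    models = getattr(sim, "rxd_models", [])
    if not models or not any(m.species for m in models):
        return None
    parts: list[bytes] = [struct.pack("<I", len(models))]
    for model in models:
        parts.append(struct.pack("<I", len(model.species)))
        for sp in model.species:
            _w_str(parts, sp.name)
            parts.append(struct.pack("<I", len(sp.values)))
            for ri in sorted(sp.values):
                arr = sp.values[ri]
                parts.append(struct.pack("<Q", len(arr)))
                _w_f64(parts, arr)
    return zlib.compress(b"".join(parts))


def _rxd_restore(sim: Simulation, payload: bytes) -> None:
    rd = _Reader(zlib.decompress(payload))
    models = getattr(sim, "rxd_models", [])
    n_models = rd.u32()
    if n_models != len(models):
        raise ConsistencyError(
            f"archive has {n_models} RxD models, simulation has {len(models)}")
    for model in models:
        n_sp = rd.u32()
        if n_sp != len(model.species):
            raise ConsistencyError("RxD species count mismatch")
        for sp in model.species:
            name = rd.string()
            if name != sp.name:
                raise ConsistencyError(
                    f"RxD species order mismatch: {name!r} vs {sp.name!r}")
            for _ in range(rd.u32()):
                n = rd.u64()
                ri = sorted(sp.values)[_]
                if n != len(sp.values[ri]):
                    raise ConsistencyError("RxD node count mismatch")
                sp.values[ri] = rd.f64s(n)


_rxd_hooked = False


def _hook_rxd_registration() -> None:
    """Arrange for the "rxd" extension to register itself the first time a
    model declares a species (not at import time)."""
    global _rxd_hooked
    if _rxd_hooked:
        return
    from .rxd import on_first_species

    def _register(_model):
        if "rxd" not in _registry:
            register_extension(ExtensionEntry("rxd", _rxd_serialize, _rxd_restore))

    on_first_species(_register)
    _rxd_hooked = True


_hook_rxd_registration()
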