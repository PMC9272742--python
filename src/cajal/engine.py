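"""Dual-backend simulation engine with two-way in-memory model transfer.

Two interchangeable executions of the same model:

* the *reference* backend keeps an array-of-structures layout — one record
  per compartment holding its voltage and its co-located mechanism
  instances — and runs the scalar kernel translations;
* the *compact* backend holds every variable in a contiguous per-variable
  array under a node permutation (structure-of-arrays) and runs the
  vectorized kernel translations.

A :class:`TransferImage` snapshots everything that defines the dynamical
state — voltages, every mechanism variable, the clock, and the pending
event queue — and moves it losslessly (bit-for-bit for stored arrays) in
either direction, so a run may switch backend at any step boundary.

Step phase order (fixed-dt, staggered):

1. event delivery — events with delivery time in ``(t, t + dt/2]``;
2. current calculation — mechanism (g, i) with g = di/dv;
3. matrix solver — implicit-Euler voltage update via the Hines solver;
4. state update — mechanism states advanced with V(t+dt);
5. spike detection/exchange — threshold crossings enqueue connection events.

Wall time per phase is accumulated in a timing table under exactly those
names (plus "data transfer" for backend moves); it is reporting-only.
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, NumericError
from .mechdsl import builtin_library, generate_kernels, parse_mechanism
from .mechdsl.spec import MechanismSpec
from .morphology import DiscretizedCell
from .network import Connection, StimSource, stim_times
from .solver import Ordering, assemble_voltage_system, hines_solve, make_ordering

PHASES = ("event delivery", "current calculation", "matrix solver",
          "state update", "spike detection/exchange", "data transfer")

_EVENT_EPS = 1e-9  # ms, tolerance on the delivery-window boundary


@dataclass
class SimConfig:
    dt: float = 0.025  # ms
    tstop: float = 5.0  # ms
    v_init: float = -65.0  # mV
    celsius: float = 6.3
    seed: int = 0
    backend: str = "reference"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tstop < 0:
            raise ValueError("tstop must be >= 0")


# ---------------------------------------------------------------------------
# model definition


@dataclass
class _PointProcess:
    pp_id: int
    cell: int
    section: int
    x: float
    mech: str
    params: dict


@dataclass
class _Detector:
    gid: int
    node: int  # global compartment index
    threshold: float


class Model:
    """Cells, compiled mechanisms, placements, connections, stimuli."""

    def __init__(self):
        self.cells: list[DiscretizedCell] = []
        self._offsets: list[int] = []
        self.mechanisms: dict[str, dict] = {}
        self.density: list[tuple[int, int, str, dict]] = []
        self.points: list[_PointProcess] = []
        self.detectors: list[_Detector] = []
        self.connections: list[Connection] = []
        self.event_sources: list[tuple[int, object, float]] = []  # pp, times|StimSource, weight
        self._finalized = False

    # -- construction ------------------------------------------------------
    def add_cell(self, cell: DiscretizedCell) -> int:
        self._offsets.append(sum(c.n for c in self.cells))
        self.cells.append(cell)
        self._finalized = False
        return len(self.cells) - 1

    def use(self, mech) -> str:
        """Compile a mechanism (builtin name, DSL source, or spec) once."""
        if isinstance(mech, str):
            lib = builtin_library()
            if mech in lib:
                spec = lib[mech][1]
            elif "{" in mech:
                spec = parse_mechanism(mech)
            else:
                raise KeyError(f"unknown mechanism {mech!r}")
        elif isinstance(mech, MechanismSpec):
            spec = mech
        else:
            raise TypeError("mech must be a name, DSL source, or MechanismSpec")
        if spec.name not in self.mechanisms:
            self.mechanisms[spec.name] = {
                "spec": spec,
                "reference": generate_kernels(spec, "reference"),
                "compact": generate_kernels(spec, "compact"),
            }
        return spec.name

    def insert(self, cell: int, section: int, mech, **params) -> None:
        name = self.use(mech)
        if self.mechanisms[name]["spec"].kind != "density":
            raise ValueError(f"{name} is a point process; use place()")
        if section not in self.cells[cell].section_ranges:
            raise KeyError(f"cell {cell} has no section {section}")
        self.density.append((cell, section, name, dict(params)))

    def place(self, cell: int, section: int, x: float, mech, **params) -> int:
        name = self.use(mech)
        if self.mechanisms[name]["spec"].kind != "point_process":
            raise ValueError(f"{name} is a density mechanism; use insert()")
        if section not in self.cells[cell].section_ranges:
            raise KeyError(f"cell {cell} has no section {section}")
        pp = _PointProcess(len(self.points), cell, section, x, name, dict(params))
        self.points.append(pp)
        return pp.pp_id

    def add_detector(self, cell: int, section: int, x: float,
                     threshold: float = -20.0) -> int:
        node = self.global_index(cell, section, x)
        self.detectors.append(_Detector(gid=cell, node=node, threshold=threshold))
        return cell

    def connect(self, source_gid: int, target_pp: int, weight: float,
                delay: float) -> Connection:
        conn = Connection(source_gid=source_gid, target=target_pp,
                          weight=weight, delay=delay)
        self.connections.append(conn)
        return conn

    def drive(self, target_pp: int, times, weight: float) -> None:
        """Feed a fixed spike-time train (or StimSource) into a synapse."""
        self.event_sources.append((target_pp, times, weight))

    # -- global arrays -----------------------------------------------------
    def global_index(self, cell: int, section: int, x: float) -> int:
        return self._offsets[cell] + self.cells[cell].locate(section, x)

    def finalize(self):
        if self._finalized:
            return
        n = sum(c.n for c in self.cells)
        self.n_comp = n
        parent = np.full(n, -1, dtype=np.int64)
        self.c_nF = np.empty(n)
        self.g_axial = np.empty(n)
        self.area = np.empty(n)
        self.comp_cell = np.empty(n, dtype=np.int64)
        for ci, cell in enumerate(self.cells):
            off = self._offsets[ci]
            sl = slice(off, off + cell.n)
            parent[sl] = np.where(cell.parent_index >= 0,
                                  cell.parent_index + off, -1)
            self.c_nF[sl] = cell.c_nF
            self.g_axial[sl] = cell.g_axial
            self.area[sl] = cell.area
            self.comp_cell[sl] = ci
        self.parent = parent
        # canonical instance enumeration: density placements then points,
        # in declaration order; this is the reference-order layout contract
        self.instances: dict[str, list[tuple[int, int | None, dict]]] = {}
        for cell, section, name, params in self.density:
            dcell = self.cells[cell]
            start, nseg = dcell.section_ranges[section]
            for j in range(nseg):
                node = self._offsets[cell] + start + j
                self.instances.setdefault(name, []).append((node, None, params))
        for pp in self.points:
            node = self.global_index(pp.cell, pp.section, pp.x)
            self.instances.setdefault(pp.mech, []).append(
                (node, pp.pp_id, pp.params))
        self._finalized = True


# ---------------------------------------------------------------------------
# backend states


@dataclass
class _Instance:
    mech: str
    node: int
    pp_id: int | None
    scale: float  # area*1e-2 for density (S/cm^2 -> uS), 1 for point
    vals: dict[str, float]


class ReferenceState:
    """Array-of-structures backend state: one record per compartment."""

    layout = "reference"

    def __init__(self, model: Model, config: SimConfig):
        model.finalize()
        self.model = model
        self.config = config
        self.t = 0.0
        self.records: list[list[_Instance]] = [[] for _ in range(model.n_comp)]
        self.v = [float(config.v_init)] * model.n_comp
        self.inst_by_mech: dict[str, list[_Instance]] = {}
        self.pp_index: dict[int, _Instance] = {}
        for mech, entries in model.instances.items():
            spec = model.mechanisms[mech]["spec"]
            for node, pp_id, params in entries:
                vals = spec.default_values()
                vals.update(params)
                scale = model.area[node] * 1e-2 if spec.kind == "density" else 1.0
                inst = _Instance(mech, node, pp_id, scale, vals)
                self.records[node].append(inst)
                self.inst_by_mech.setdefault(mech, []).append(inst)
                if pp_id is not None:
                    self.pp_index[pp_id] = inst
        self.queue: list = []
        self.seq = 0
        self.spikes: list[tuple[float, int]] = []
        self.det_above = [False] * len(model.detectors)
        self.timing = {p: 0.0 for p in PHASES}

    # -- phase hooks -------------------------------------------------------
    def kernels(self, mech):
        return self.model.mechanisms[mech]["reference"]

    def deliver(self, pp_id, weight):
        inst = self.pp_index[pp_id]
        nr = self.kernels(inst.mech).net_receive
        if nr is None:
            raise KeyError(f"target mechanism {inst.mech} has no NET_RECEIVE")
        nr(inst.vals, weight, self.t)

    def eval_currents(self):
        n = self.model.n_comp
        g = np.zeros(n)
        i_rhs = np.zeros(n)
        celsius, t = self.config.celsius, self.t
        for node in range(n):
            vn = self.v[node]
            for inst in self.records[node]:
                gk, ik = self.kernels(inst.mech).current(inst.vals, vn, celsius, t)
                gu = gk * inst.scale
                g[node] += gu
                i_rhs[node] += gu * vn - ik * inst.scale
        return g, i_rhs

    def solve_voltage(self, g, i_rhs, dt):
        m = self.model
        sys = assemble_voltage_system(m.parent, m.c_nF, m.g_axial, dt, g,
                                      i_rhs, np.array(self.v))
        return hines_solve(sys)

    def set_v(self, vnew):
        self.v = [float(x) for x in vnew]

    def get_v(self, node):
        return self.v[node]

    def update_states(self, dt):
        celsius, t = self.config.celsius, self.t + dt
        for mech, insts in self.inst_by_mech.items():
            kern = self.kernels(mech).state
            for inst in insts:
                kern(inst.vals, self.v[inst.node], dt, celsius, t)

    def detector_v(self):
        return [self.v[d.node] for d in self.model.detectors]

    def init_mechanisms(self):
        celsius = self.config.celsius
        for insts in self.inst_by_mech.values():
            for inst in insts:
                self.kernels(inst.mech).init(inst.vals, self.v[inst.node],
                                             celsius, 0.0)

    def get_var(self, mech, ref_pos, var):
        return self.inst_by_mech[mech][ref_pos].vals[var]


class CompactState:
    """Structure-of-arrays backend state under a node permutation."""

    layout = "compact"

    def __init__(self, model: Model, config: SimConfig, ordering: Ordering):
        model.finalize()
        self.model = model
        self.config = config
        self.ordering = ordering
        self.t = 0.0
        self.parent = ordering.permute_parent(model.parent)
        self.c_nF = ordering.gather(model.c_nF)
        self.g_axial_perm = self._permute_axial()
        self.v = np.full(model.n_comp, config.v_init, dtype=float)
        self.mech_data: dict[str, dict] = {}
        self.pp_pos: dict[int, tuple[str, int]] = {}
        for mech, entries in model.instances.items():
            spec = model.mechanisms[mech]["spec"]
            nodes_ref = np.array([e[0] for e in entries], dtype=np.int64)
            perm_nodes = ordering.inv[nodes_ref]
            order = np.argsort(perm_nodes, kind="stable")  # ref-pos -> rank
            names = spec.instance_vars()
            vals = {}
            for name in names:
                col = np.empty(len(entries))
                for rpos, (node, pp_id, params) in enumerate(entries):
                    dv = spec.default_values()
                    col[rpos] = params.get(name, dv[name])
                vals[name] = col[order]
            scale = np.array(
                [model.area[e[0]] * 1e-2 if spec.kind == "density" else 1.0
                 for e in entries])[order]
            data = {"nodes": perm_nodes[order], "order": order,
                    "vals": vals, "scale": scale}
            self.mech_data[mech] = data
            for rpos, (node, pp_id, params) in enumerate(entries):
                if pp_id is not None:
                    rank = int(np.flatnonzero(order == rpos)[0])
                    self.pp_pos[pp_id] = (mech, rank)
        self.queue: list = []
        self.seq = 0
        self.spikes: list[tuple[float, int]] = []
        self.det_above = [False] * len(model.detectors)
        self.det_nodes = [int(ordering.inv[d.node]) for d in model.detectors]
        self.timing = {p: 0.0 for p in PHASES}

    def _permute_axial(self):
        # g_axial is indexed by the child node; permuting nodes keeps the
        # child's coupling attached to the child's new index
        return self.ordering.gather(self.model.g_axial)

    def kernels(self, mech):
        return self.model.mechanisms[mech]["compact"]

    def deliver(self, pp_id, weight):
        mech, rank = self.pp_pos[pp_id]
        nr = self.kernels(mech).net_receive
        if nr is None:
            raise KeyError(f"target mechanism {mech} has no NET_RECEIVE")
        nr(self.mech_data[mech]["vals"], rank, weight, self.t)

    def eval_currents(self):
        n = self.model.n_comp
        g = np.zeros(n)
        i_rhs = np.zeros(n)
        celsius, t = self.config.celsius, self.t
        for mech, data in self.mech_data.items():
            vloc = self.v[data["nodes"]]
            gk, ik = self.kernels(mech).current(data["vals"], vloc, celsius, t)
            gu = gk * data["scale"]
            np.add.at(g, data["nodes"], gu)
            np.add.at(i_rhs, data["nodes"], gu * vloc - ik * data["scale"])
        return g, i_rhs

    def solve_voltage(self, g, i_rhs, dt):
        sys = assemble_voltage_system(self.parent, self.c_nF, self.g_axial_perm,
                                      dt, g, i_rhs, self.v)
        return hines_solve(sys)

    def set_v(self, vnew):
        self.v = np.asarray(vnew, dtype=float)

    def get_v(self, node):
        return float(self.v[self.ordering.inv[node]])

    def update_states(self, dt):
        celsius, t = self.config.celsius, self.t + dt
        for mech, data in self.mech_data.items():
            vloc = self.v[data["nodes"]]
            self.kernels(mech).state(data["vals"], vloc, dt, celsius, t)

    def detector_v(self):
        return [float(self.v[j]) for j in self.det_nodes]

    def init_mechanisms(self):
        celsius = self.config.celsius
        for mech, data in self.mech_data.items():
            self.kernels(mech).init(data["vals"], self.v[data["nodes"]],
                                    celsius, 0.0)

    def get_var(self, mech, ref_pos, var):
        data = self.mech_data[mech]
        rank = int(np.flatnonzero(data["order"] == ref_pos)[0])
        return float(data["vals"][var][rank])


# ---------------------------------------------------------------------------
# transfer image


@dataclass
class TransferImage:
    """Serialized snapshot: V, all mechanism variables, clock, events."""

    t: float
    v: np.ndarray  # reference (unpermuted) node order
    mech_vals: dict[str, dict[str, np.ndarray]]  # ref instance order
    events: list[tuple[float, int, int, float]]  # (time, seq, target, weight)
    seq: int
    spikes: list[tuple[float, int]]
    det_above: list[bool]


def to_transfer(state) -> TransferImage:
    """Snapshot either backend into a reference-ordered image."""
    model = state.model
    if state.layout == "reference":
        v = np.array(state.v, dtype=float)
        mech_vals = {}
        for mech, insts in state.inst_by_mech.items():
            names = model.mechanisms[mech]["spec"].instance_vars()
            mech_vals[mech] = {
                nm: np.array([inst.vals[nm] for inst in insts]) for nm in names}
    else:
        v = state.ordering.scatter(state.v)
        mech_vals = {}
        for mech, data in state.mech_data.items():
            names = model.mechanisms[mech]["spec"].instance_vars()
            inv_order = np.argsort(data["order"], kind="stable")
            mech_vals[mech] = {nm: data["vals"][nm][inv_order].copy()
                               for nm in names}
    events = [(ev[0], ev[1], ev[2], ev[3]) for ev in sorted(state.queue)]
    return TransferImage(t=state.t, v=v, mech_vals=mech_vals, events=events,
                         seq=state.seq, spikes=list(state.spikes),
                         det_above=list(state.det_above))


def apply_transfer(image: TransferImage, state) -> None:
    """Write an image into either backend state (shape-checked)."""
    model = state.model
    if len(image.v) != model.n_comp:
        raise ConsistencyError(
            f"image has {len(image.v)} compartments, model has {model.n_comp}")
    for mech, vals in image.mech_vals.items():
        if mech not in model.instances:
            raise ConsistencyError(f"image mechanism {mech!r} not in model")
        n_inst = len(model.instances[mech])
        for nm, arr in vals.items():
            if len(arr) != n_inst:
                raise ConsistencyError(
                    f"{mech}.{nm}: {len(arr)} values for {n_inst} instances")
    state.t = image.t
    state.seq = image.seq
    state.spikes = list(image.spikes)
    state.det_above = list(image.det_above)
    state.queue = [(e[0], e[1], e[2], e[3]) for e in image.events]
    heapq.heapify(state.queue)
    if state.layout == "reference":
        state.v = [float(x) for x in image.v]
        for mech, insts in state.inst_by_mech.items():
            for nm, arr in image.mech_vals[mech].items():
                for inst, val in zip(insts, arr):
                    inst.vals[nm] = float(val)
    else:
        state.v = state.ordering.gather(image.v)
        for mech, data in state.mech_data.items():
            for nm, arr in image.mech_vals[mech].items():
                data["vals"][nm] = np.asarray(arr, dtype=float)[data["order"]].copy()


def to_compact(ref: ReferenceState, ordering: Ordering | None = None) -> CompactState:
    """Transpose a reference state into the compact layout (lossless)."""
    t0 = time.perf_counter()
    if ordering is None:
        ordering = make_ordering(ref.model.parent, ref.model.comp_cell,
                                 "cell_interleaved")
    compact = CompactState(ref.model, ref.config, ordering)
    apply_transfer(to_transfer(ref), compact)
    compact.timing = ref.timing
    ref.timing["data transfer"] += time.perf_counter() - t0
    return compact


def to_reference(compact: CompactState, ref: ReferenceState) -> ReferenceState:
    """Copy a compact state back into a reference state built from the
    same model; a subsequent reference run continues seamlessly."""
    t0 = time.perf_counter()
    if compact.model is not ref.model and compact.model.n_comp != ref.model.n_comp:
        raise ConsistencyError("compact and reference states use different models")
    apply_transfer(to_transfer(compact), ref)
    ref.timing = compact.timing
    ref.timing["data transfer"] += time.perf_counter() - t0
    return ref


# ---------------------------------------------------------------------------
# stepping


def build(model: Model, config: SimConfig) -> ReferenceState:
    """Instantiate the reference-backend state for a model (t = 0)."""
    return ReferenceState(model, config)


def finitialize(state, v_init: float | None = None) -> None:
    """V := v_init everywhere, run INITIAL kernels, clear queue, t := 0.

    Stimulus trains declared on the model are (re)scheduled here.
    """
    config = state.config
    if v_init is None:
        v_init = config.v_init
    n = state.model.n_comp
    state.set_v(np.full(n, float(v_init)))
    state.t = 0.0
    state.queue = []
    state.seq = 0
    state.spikes = []
    state.init_mechanisms()
    for pp_id, times, weight in state.model.event_sources:
        if isinstance(times, StimSource):
            times = stim_times(times)
        for tt in np.atleast_1d(np.asarray(times, dtype=float)):
            heapq.heappush(state.queue, (float(tt), state.seq, pp_id, weight))
            state.seq += 1
    state.det_above = [v >= d.threshold for v, d in
                       zip(state.detector_v(), state.model.detectors)]


def advance_step(state) -> None:
    """One fixed-dt step through the five phases (see module docstring)."""
    model = state.model
    dt = state.config.dt
    t = state.t

    t0 = time.perf_counter()
    horizon = t + dt / 2 + _EVENT_EPS
    while state.queue and state.queue[0][0] <= horizon:
        _tt, _seq, pp_id, weight = heapq.heappop(state.queue)
        state.deliver(pp_id, weight)
    t1 = time.perf_counter()
    state.timing["event delivery"] += t1 - t0

    g, i_rhs = state.eval_currents()
    t2 = time.perf_counter()
    state.timing["current calculation"] += t2 - t1

    v_prev_det = state.detector_v()
    vnew = state.solve_voltage(g, i_rhs, dt)
    if not np.all(np.isfinite(vnew)):
        bad = int(np.flatnonzero(~np.isfinite(vnew))[0])
        raise NumericError(f"non-finite voltage at compartment {bad}, t={t}")
    state.set_v(vnew)
    t3 = time.perf_counter()
    state.timing["matrix solver"] += t3 - t2

    state.update_states(dt)
    t4 = time.perf_counter()
    state.timing["state update"] += t4 - t3

    v_now_det = state.detector_v()
    for k, det in enumerate(model.detectors):
        above = state.det_above[k]
        vp, vn = v_prev_det[k], v_now_det[k]
        if (not above) and vp < det.threshold <= vn:
            spike_t = t + dt
            state.spikes.append((spike_t, det.gid))
            for conn in model.connections:
                if conn.source_gid == det.gid:
                    heapq.heappush(state.queue,
                                   (spike_t + conn.delay, state.seq,
                                    conn.target, conn.weight))
                    state.seq += 1
        state.det_above[k] = vn >= det.threshold
    state.t = t + dt
    state.timing["spike detection/exchange"] += time.perf_counter() - t4


# ---------------------------------------------------------------------------
# recording + top-level driver


@dataclass
class Recorder:
    kind: str  # 'v' | 'var'
    name: str
    node: int | None = None  # global compartment index (kind 'v')
    mech: str | None = None
    ref_pos: int | None = None
    var: str | None = None
    times: list = field(default_factory=list)
    values: list = field(default_factory=list)

    def sample(self, state):
        self.times.append(state.t)
        if self.kind == "v":
            self.values.append(state.get_v(self.node))
        else:
            self.values.append(state.get_var(self.mech, self.ref_pos, self.var))


class Simulation:
    """Owns the reference master state, recorders, and backend switching."""

    def __init__(self, model: Model, config: SimConfig,
                 ordering_scheme: str = "cell_interleaved"):
        model.finalize()
        self.model = model
        self.config = config
        self.state = build(model, config)
        self.ordering = make_ordering(model.parent, model.comp_cell,
                                      ordering_scheme)
        self.recorders: list[Recorder] = []

    # -- recording ---------------------------------------------------------
    def record_v(self, cell: int, section: int, x: float, name=None) -> Recorder:
        node = self.model.global_index(cell, section, x)
        rec = Recorder(kind="v", name=name or f"v[{cell}][{section}]({x})",
                       node=node)
        self.recorders.append(rec)
        return rec

    def record_var(self, pp_or_loc, var: str, name=None) -> Recorder:
        """Record a mechanism variable: pass a point-process id or a tuple
        ``(cell, section, x, mech)`` for a density mechanism."""
        if isinstance(pp_or_loc, int):
            pp_id = pp_or_loc
            for mech, entries in self.model.instances.items():
                for rpos, (node, pid, params) in enumerate(entries):
                    if pid == pp_id:
                        rec = Recorder(kind="var", name=name or f"{mech}[{pp_id}].{var}",
                                       mech=mech, ref_pos=rpos, var=var)
                        self.recorders.append(rec)
                        return rec
            raise KeyError(f"unknown point process {pp_id}")
        cell, section, x, mech = pp_or_loc
        node = self.model.global_index(cell, section, x)
        for rpos, (nd, pid, params) in enumerate(self.model.instances[mech]):
            if nd == node and pid is None:
                rec = Recorder(kind="var", name=name or f"{mech}@{node}.{var}",
                               mech=mech, ref_pos=rpos, var=var)
                self.recorders.append(rec)
                return rec
        raise KeyError(f"no {mech} instance at that location")

    # -- control -----------------------------------------------------------
    def finitialize(self, v_init=None):
        finitialize(self.state, v_init)
        for rec in self.recorders:
            rec.times.clear()
            rec.values.clear()
            rec.sample(self.state)

    def psolve(self, tstop: float, backend: str | None = None):
        """Advance to tstop on the requested backend.

        A compact run transfers the model in, steps, and transfers every
        variable and pending event back (so the reference state is always
        authoritative between calls).
        """
        backend = backend or self.config.backend
        dt = self.config.dt
        if tstop < self.state.t - 1e-9:
            raise ValueError("tstop is before the current time")
        nsteps = int(round((tstop - self.state.t) / dt))
        if abs(self.state.t + nsteps * dt - tstop) > 1e-6:
            raise ValueError("tstop must be a multiple of dt from current t")
        if nsteps == 0:
            return
        if backend == "reference":
            run_state = self.state
        elif backend == "compact":
            run_state = to_compact(self.state, self.ordering)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        for _ in range(nsteps):
            advance_step(run_state)
            for rec in self.recorders:
                rec.sample(run_state)
        if backend == "compact":
            to_reference(run_state, self.state)

    @property
    def spikes(self):
        return list(self.state.spikes)

    @property
    def timing(self):
        return dict(self.state.timing)
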