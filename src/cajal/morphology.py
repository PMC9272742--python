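"""Morphologies: SWC ingestion, validation, and cable discretization.

A :class:`Morphology` is a tree of :class:`Section` objects.  Each section is
a polyline of ``(x, y, z, diam)`` samples in micrometres; consecutive samples
bound truncated cones (frusta), which is the geometric model used both for
membrane-area integration here and for voxelization in :mod:`cajal.rxd`.

Discretization follows the standard cable convention: each section is split
into ``nseg`` compartments of equal arc length with centers at fractions
``(2i - 1) / (2 nseg)``; membrane area is the lateral frustum surface
integrated over the compartment span, and the axial conductance between two
adjacent compartment centers is the reciprocal of the series resistance
``ra * int dx / (pi r(x)^2)`` accumulated over the two half-compartments
(units: see :mod:`cajal.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Section:
    """Unbranched neurite run described by >=2 (x, y, z, diam) samples."""

    id: int
    parent_id: int | None
    parent_position: float  # fraction in [0, 1] along the parent section
    points: np.ndarray  # shape (n, 4): x, y, z, diameter, all um
    nseg: int = 1
    name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise ValueError("section points must have shape (n, 4)")
        if len(self.points) < 2:
            raise ValueError(f"section {self.id}: needs at least 2 points")
        if np.any(self.points[:, 3] <= 0):
            raise ValueError(f"section {self.id}: non-positive diameter")
        if self.nseg < 1:
            raise ValueError(f"section {self.id}: nseg must be >= 1")
        if not (0.0 <= self.parent_position <= 1.0):
            raise ValueError(f"section {self.id}: parent_position outside [0, 1]")

    # -- arc-length parameterization -------------------------------------
    @property
    def seg_lengths(self) -> np.ndarray:
        d = np.diff(self.points[:, :3], axis=0)
        return np.sqrt((d * d).sum(axis=1))

    @property
    def length(self) -> float:
        return float(self.seg_lengths.sum())

    def radius_at(self, s: float) -> float:
        """Radius (um) at arc-length position ``s`` (um from the 0 end)."""
        cum = np.concatenate([[0.0], np.cumsum(self.seg_lengths)])
        radii = self.points[:, 3] / 2.0
        return float(np.interp(s, cum, radii))


@dataclass
class Morphology:
    """Validated tree of sections."""

    sections: list[Section]
    cell_id: str = "cell"

    def __post_init__(self):
        self._by_id = {s.id: s for s in self.sections}
        if len(self._by_id) != len(self.sections):
            raise TopologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise TopologyError(f"expected exactly one root section, found {len(roots)}")
        self.root = roots[0].id
        # tree check: every parent exists, no cycles
        for s in self.sections:
            seen = {s.id}
            cur = s
            while cur.parent_id is not None:
                if cur.parent_id not in self._by_id:
                    raise TopologyError(
                        f"section {cur.id} references undefined parent {cur.parent_id}")
                cur = self._by_id[cur.parent_id]
                if cur.id in seen:
                    raise TopologyError(f"cycle through section {cur.id}")
                seen.add(cur.id)

    def section(self, sec_id: int) -> Section:
        return self._by_id[sec_id]

    def children(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sec_id]

    def dfs_order(self) -> list[Section]:
        """Sections in parent-before-child (pre-)order."""
        out, stack = [], [self._by_id[self.root]]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(sorted(self.children(s.id), key=lambda c: -c.id))
        return out


@dataclass
class Compartment:
    index: int
    section_id: int
    center_fraction: float
    length: float  # um
    area: float  # um^2, lateral frustum surface
    volume: float  # um^3
    cm: float  # uF/cm^2
    ra: float  # ohm*cm
    g_axial_parent: float  # uS; 0 for the root compartment


@dataclass
class DiscretizedCell:
    """Topologically ordered compartments of one cell (parent[i] < i)."""

    morphology: Morphology
    compartments: list[Compartment]
    parent_index: np.ndarray  # int, -1 for root
    section_ranges: dict[int, tuple[int, int]]  # sec id -> (start, nseg)
    # vectorized views used by the engine and rxd
    length: np.ndarray = field(default=None)  # um
    area: np.ndarray = field(default=None)  # um^2
    volume: np.ndarray = field(default=None)  # um^3
    c_nF: np.ndarray = field(default=None)  # nF
    g_axial: np.ndarray = field(default=None)  # uS to parent
    axial_area: np.ndarray = field(default=None)  # um^2 cross-section toward parent
    axial_dist: np.ndarray = field(default=None)  # um, center-to-center

    @property
    def n(self) -> int:
        return len(self.compartments)

    def locate(self, sec_id: int, x: float) -> int:
        """Global index of the compartment nearest to fraction ``x`` of a section.

        Section ends (x = 0 or 1) map to the nearest compartment center.
        """
        start, nseg = self.section_ranges[sec_id]
        j = int(min(nseg - 1, max(0, math.floor(x * nseg))))
        return start + j


# ---------------------------------------------------------------------------
# frustum integrals along a section


def _piecewise(sec: Section):
    cum = np.concatenate([[0.0], np.cumsum(sec.seg_lengths)])
    radii = sec.points[:, 3] / 2.0
    return cum, radii


def _integrate(sec: Section, s0: float, s1: float, kind: str) -> float:
    """Integrate a frustum quantity over arc span [s0, s1] of a section.

    kind: 'area' (lateral slant surface), 'volume', or 'invr2'
    (``int ds / (pi r^2)``, exact for linear radius: dl / (pi ra rb)).
    """
    cum, radii = _piecewise(sec)
    total = 0.0
    for k in range(len(cum) - 1):
        a, b = cum[k], cum[k + 1]
        lo, hi = max(a, s0), min(b, s1)
        if hi <= lo:
            continue
        piece = b - a
        if piece == 0.0:
            continue
        m = (radii[k + 1] - radii[k]) / piece
        ra = radii[k] + m * (lo - a)
        rb = radii[k] + m * (hi - a)
        dl = hi - lo
        if kind == "area":
            total += math.pi * (ra + rb) * dl * math.sqrt(1.0 + m * m)
        elif kind == "volume":
            total += math.pi / 3.0 * (ra * ra + ra * rb + rb * rb) * dl
        elif kind == "invr2":
            total += dl / (math.pi * ra * rb)
        else:  # pragma: no cover
            raise ValueError(kind)
    return total


# ---------------------------------------------------------------------------
# SWC reading


def read_swc(path) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    Soma samples (type 1) are contracted to a single section: the sample
    polyline is kept but given the uniform diameter that preserves the
    summed frustum surface (a single sample becomes a cylinder with
    ``L = d = 2 r``, which preserves the sphere surface ``pi d^2``).
    Unbranched runs of non-soma samples become sections split at branch
    points; each section's first point is its parent sample's coordinate.
    """
    with open(path) as fh:
        return parse_swc(fh.read(), label=str(path))


def parse_swc(text: str, label: str = "<swc>") -> Morphology:
    """Parse SWC text (see :func:`read_swc`)."""
    path = label
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}: line {ln}: expected 7 columns")
        nid, typ = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if r <= 0:
            raise ValueError(f"{path}: line {ln}: non-positive radius")
        if nid in rows:
            raise TopologyError(f"{path}: duplicate sample id {nid}")
        rows[nid] = (typ, x, y, z, r, parent)
        order.append(nid)

    if not rows:
        raise ValueError(f"{path}: empty SWC file")
    roots = [nid for nid in order if rows[nid][5] == -1]
    if len(roots) == 0:
        raise TopologyError(f"{path}: no root sample")
    if len(roots) > 1:
        raise TopologyError(f"{path}: multiple root samples {roots}")
    for nid in order:
        parent = rows[nid][5]
        if parent != -1:
            if parent not in rows or order.index(parent) >= order.index(nid):
                raise TopologyError(
                    f"{path}: sample {nid} references undefined parent {parent}")
        if parent == nid:
            raise TopologyError(f"{path}: sample {nid} is its own parent")

    children: dict[int, list[int]] = {nid: [] for nid in order}
    for nid in order:
        p = rows[nid][5]
        if p != -1:
            children[p].append(nid)

    soma_ids = [nid for nid in order if rows[nid][0] == 1]
    sections: list[Section] = []
    sec_of_sample: dict[int, tuple[int, float]] = {}  # sample -> (section id, fraction)
    next_sec = 0

    if soma_ids:
        pts = np.array([[rows[i][1], rows[i][2], rows[i][3], 2 * rows[i][4]]
                        for i in soma_ids])
        seglen = np.sqrt((np.diff(pts[:, :3], axis=0) ** 2).sum(axis=1)) if len(pts) > 1 \
            else np.array([])
        arc = float(seglen.sum()) if len(seglen) else 0.0
        if arc == 0.0:
            # point soma -> sphere-surface-equivalent cylinder L = d
            x, y, z, r = rows[soma_ids[0]][1:5]
            d = 2 * r
            pts = np.array([[x - r, y, z, d], [x + r, y, z, d]])
            for i in soma_ids:
                sec_of_sample[i] = (next_sec, 0.5)
        else:
            radii = pts[:, 3] / 2.0
            surf = sum(math.pi * (radii[k] + radii[k + 1])
                       * math.sqrt(seglen[k] ** 2 + (radii[k + 1] - radii[k]) ** 2)
                       for k in range(len(seglen)))
            d_eq = surf / (math.pi * arc)
            cum = np.concatenate([[0.0], np.cumsum(seglen)])
            pts = pts.copy()
            pts[:, 3] = d_eq
            for i, s in zip(soma_ids, cum):
                sec_of_sample[i] = (next_sec, float(s / arc))
        sections.append(Section(id=next_sec, parent_id=None, parent_position=0.0,
                                points=pts, name="soma"))
        next_sec += 1

    # section start samples: non-soma samples whose parent is -1, soma, or a
    # branch point (parent with != 1 non-soma children)
    def is_start(nid):
        p = rows[nid][5]
        if p == -1 or rows[p][0] == 1:
            return True
        return len(children[p]) != 1

    starts = [nid for nid in order if rows[nid][0] != 1 and is_start(nid)]
    # walk in sample order so parents are processed before children
    for start in starts:
        chain = [start]
        cur = start
        while len(children[cur]) == 1 and rows[children[cur][0]][0] != 1:
            cur = children[cur][0]
            chain.append(cur)
        p = rows[start][5]
        pts = []
        if p != -1:
            px, py, pz, pr = rows[p][1:5]
            # at the soma, use the child's own diameter for the lead point to
            # avoid a spurious taper from the soma radius
            lead_d = 2 * rows[start][4] if rows[p][0] == 1 else 2 * pr
            pts.append([px, py, pz, lead_d])
        pts.extend([[rows[i][1], rows[i][2], rows[i][3], 2 * rows[i][4]] for i in chain])
        if len(pts) < 2:
            pts = [pts[0], pts[0]]
        if p == -1:
            parent_sec, ppos = None, 0.0
        else:
            parent_sec, ppos = sec_of_sample[p]
        sec = Section(id=next_sec, parent_id=parent_sec, parent_position=ppos,
                      points=np.array(pts, dtype=float),
                      name=f"neurite[{next_sec}]")
        sections.append(sec)
        cum = np.concatenate([[0.0], np.cumsum(sec.seg_lengths)])
        offset = 1 if p != -1 else 0
        L = sec.length
        for k, nid in enumerate(chain):
            frac = float(cum[k + offset] / L) if L > 0 else 1.0
            sec_of_sample[nid] = (next_sec, frac)
        next_sec += 1

    return Morphology(sections=sections)


# ---------------------------------------------------------------------------
# discretization


def discretize(m: Morphology, nseg=1, cm=1.0, ra=100.0) -> DiscretizedCell:
    """Discretize a morphology into topologically ordered compartments.

    ``nseg`` is an int applied to every section or a mapping section id ->
    nseg; likewise ``cm`` (uF/cm^2) and ``ra`` (ohm*cm) may be scalars or
    per-section mappings.
    """
    def per_section(v, sid, default):
        if isinstance(v, dict):
            return v.get(sid, default)
        return v

    comps: list[Compartment] = []
    parent = []
    ranges: dict[int, tuple[int, int]] = {}
    ax_area, ax_dist = [], []

    for sec in m.dfs_order():
        n = int(per_section(nseg, sec.id, 1))
        if n < 1:
            raise ValueError(f"section {sec.id}: nseg must be >= 1")
        L = sec.length
        if L <= 0:
            raise ValueError(f"section {sec.id}: zero-length section")
        sec_cm = float(per_section(cm, sec.id, 1.0))
        sec_ra = float(per_section(ra, sec.id, 100.0))
        start = len(comps)
        ranges[sec.id] = (start, n)
        dx = L / n
        for j in range(n):
            s0, s1 = j * dx, (j + 1) * dx
            area = _integrate(sec, s0, s1, "area")
            vol = _integrate(sec, s0, s1, "volume")
            idx = len(comps)
            if j > 0:
                p_idx = idx - 1
                # series resistance across the two half-compartments
                inv = _integrate(sec, s0 - dx / 2, s0, "invr2") \
                    + _integrate(sec, s0, s0 + dx / 2, "invr2")
                r_mohm = sec_ra * inv * 1e-2
                a_cross = math.pi * sec.radius_at(s0) ** 2
                d_cc = dx
            elif sec.parent_id is not None:
                psec = m.section(sec.parent_id)
                p_start, p_n = ranges[sec.parent_id]
                p_ra = float(per_section(ra, psec.id, 100.0))
                pf = sec.parent_position
                pj = min(p_n - 1, int(pf * p_n))
                p_idx = p_start + pj
                p_dx = psec.length / p_n
                p_center = (pj + 0.5) * p_dx
                attach = pf * psec.length
                inv_child = _integrate(sec, 0.0, dx / 2, "invr2")
                inv_par = abs(_integrate(psec, min(p_center, attach),
                                         max(p_center, attach), "invr2"))
                r_mohm = (sec_ra * inv_child + p_ra * inv_par) * 1e-2
                a_cross = math.pi * sec.radius_at(0.0) ** 2
                d_cc = dx / 2 + abs(p_center - attach)
            else:
                p_idx = -1
                r_mohm = 0.0
                a_cross = 0.0
                d_cc = 0.0
            g_ax = 1.0 / r_mohm if r_mohm > 0 else 0.0
            comps.append(Compartment(index=idx, section_id=sec.id,
                                     center_fraction=(2 * j + 1) / (2 * n),
                                     length=dx, area=area, volume=vol,
                                     cm=sec_cm, ra=sec_ra,
                                     g_axial_parent=g_ax))
            parent.append(p_idx)
            ax_area.append(a_cross)
            ax_dist.append(d_cc)

    cell = DiscretizedCell(
        morphology=m, compartments=comps,
        parent_index=np.array(parent, dtype=np.int64),
        section_ranges=ranges)
    cell.length = np.array([c.length for c in comps])
    cell.area = np.array([c.area for c in comps])
    cell.volume = np.array([c.volume for c in comps])
    cell.c_nF = np.array([c.cm * c.area * 1e-5 for c in comps])
    cell.g_axial = np.array([c.g_axial_parent for c in comps])
    cell.axial_area = np.array(ax_area)
    cell.axial_dist = np.array(ax_dist)
    if np.any(cell.parent_index >= np.arange(cell.n)):
        raise TopologyError("discretization broke topological ordering")
    return cell


# ---------------------------------------------------------------------------
# path distance


def path_distance(cell: DiscretizedCell | Morphology, a, b) -> float:
    """Arc-length distance (um) between two points ``(section_id, fraction)``.

    Both points must be on the same cell.  Symmetric; zero iff a == b.
    """
    m = cell.morphology if isinstance(cell, DiscretizedCell) else cell

    def chain(loc):
        """[(sec_id, arc position um, accumulated um below this entry)]"""
        sec_id, x = loc
        if sec_id not in m._by_id:
            raise KeyError(f"unknown section {sec_id}")
        if not (0.0 <= x <= 1.0):
            raise ValueError("fraction outside [0, 1]")
        out = []
        sec = m.section(sec_id)
        pos = x * sec.length
        acc = 0.0
        while True:
            out.append((sec.id, pos, acc))
            if sec.parent_id is None:
                return out
            acc += pos  # distance from current point to this section's 0 end
            parent = m.section(sec.parent_id)
            pos = sec.parent_position * parent.length
            sec = parent

    ca, cb = chain(a), chain(b)
    pos_b = {sid: (p, acc) for sid, p, acc in cb}
    for sid, p_a, acc_a in ca:
        if sid in pos_b:
            p_b, acc_b = pos_b[sid]
            return acc_a + acc_b + abs(p_a - p_b)
    raise ValueError("points are on different cells")  # unreachable on one tree
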