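"""Spikes, delayed connections, and reproducible stimulus streams.

Spike convention: a detector fires when the voltage crosses its threshold
from below between two consecutive solves; the spike time is the end of the
step (no sub-dt interpolation).  A detector re-arms only after the voltage
falls back below threshold.

Stimulus streams are counter-based: every draw is a pure function of the
stream key (gid, stream id, seed) and the draw counter, never of call
order or process layout — the Random123/Philox contract.  numpy's Philox
bit generator provides the keyed counter-based engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(order=True)
class Event:
    """A pending synaptic delivery.  Ordered by (time, seq) — FIFO on ties."""

    time: float
    seq: int
    target: int = field(compare=False)  # point-process id
    weight: float = field(compare=False)


@dataclass
class Connection:
    """Spike source -> point-process target with weight and delay (ms)."""

    source_gid: int
    target: int  # point-process id
    weight: float
    delay: float

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("connection delay must be >= 0")


def schedule(conn: Connection, spike_time: float, seq: int) -> Event:
    """Event for one spike through one connection (delivery = spike + delay)."""
    return Event(time=spike_time + conn.delay, seq=seq,
                 target=conn.target, weight=conn.weight)


def detect_spikes(v_prev, v_now, threshold: float, t: float, dt: float,
                  above=None):
    """Threshold-crossing scan over compartment arrays.

    Returns ``(spikes, above)`` where ``spikes`` is a list of ``(time,
    compartment)`` pairs with time = t + dt, and ``above`` is the updated
    re-arm mask (a compartment only fires again after dropping below
    threshold).
    """
    v_prev = np.atleast_1d(np.asarray(v_prev, dtype=float))
    v_now = np.atleast_1d(np.asarray(v_now, dtype=float))
    if v_prev.shape != v_now.shape:
        raise ValueError("v_prev and v_now must have equal length")
    if above is None:
        above = v_prev >= threshold
    fired = (~above) & (v_prev < threshold) & (v_now >= threshold)
    above = v_now >= threshold
    return [(t + dt, int(j)) for j in np.flatnonzero(fired)], above


# ---------------------------------------------------------------------------
# counter-based stimulus streams


@dataclass
class StimSource:
    """Regular or Poisson spike-time source keyed by (gid, stream id)."""

    kind: str  # 'regular' | 'poisson'
    start: float  # ms
    interval: float  # ms (mean interval for poisson)
    count: int
    gid: int = 0
    stream: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("regular", "poisson"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.interval <= 0:
            raise ValueError("interval must be positive")


def _uniforms(key: tuple[int, int, int], n: int) -> np.ndarray:
    """n uniforms in (0, 1) from a Philox stream keyed by (gid, stream, seed).

    Draw k depends only on the key and k, so any evaluation order, chunking
    or process layout yields the same sequence.
    """
    gid, stream, seed = (int(x) & 0xFFFFFFFFFFFFFFFF for x in key)
    k0 = ((gid << 32) ^ stream) & 0xFFFFFFFFFFFFFFFF
    k1 = (seed ^ 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    bitgen = np.random.Philox(key=np.array([k0, k1], dtype=np.uint64))
    raw = np.random.Generator(bitgen).bit_generator.random_raw(n)
    return (raw >> np.uint64(11)).astype(np.float64) * (2.0 ** -53) + 2.0 ** -54


def stim_times(src: StimSource) -> np.ndarray:
    """Ordered spike times (ms) of a stimulus source."""
    if src.count <= 0:
        return np.empty(0)
    if src.kind == "regular":
        return src.start + src.interval * np.arange(src.count)
    u = _uniforms((src.gid, src.stream, src.seed), src.count)
    intervals = -src.interval * np.log(u)
    return src.start + np.cumsum(intervals)
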