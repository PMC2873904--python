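"""Time-dependent MeAsp concentration in the flow chamber.

Concentration step changes in the experiment are not instantaneous: the
finite flow speed makes the concentration relax exponentially toward the
new level, with separate rate constants for addition (``k_rise``) and
removal (``k_fall``).  A protocol is an ambient concentration plus an
ordered list of timed ADD/REMOVE events; between events the
concentration relaxes from its value at the last event toward the
current target (ambient plus the cumulative deltas).  ``k = inf`` gives
a perfect (instantaneous) step.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np

__all__ = ["Event", "StepProtocol", "concentration", "dL_dt"]

EventKind = Literal["ADD", "REMOVE"]


@dataclasses.dataclass(frozen=True)
class Event:
    t: float  # event time [s]
    kind: EventKind
    delta: float  # concentration change magnitude [mM], positive


@dataclasses.dataclass(frozen=True)
class StepProtocol:
    """Ambient concentration plus timed exponential addition/removal events."""

    L_ambient: float  # mM
    events: tuple[Event, ...]
    k_rise: float  # 1/s; math.inf = perfect step
    k_fall: float  # 1/s; math.inf = perfect step
    t_end: float  # s

    def __post_init__(self) -> None:
        if self.L_ambient < 0:
            raise ValueError("ambient concentration must be non-negative")
        if self.k_rise <= 0 or self.k_fall <= 0:
            raise ValueError("flow rate constants must be positive (inf allowed)")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        times = [e.t for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(e.t <= 0 or e.t >= self.t_end for e in events):
            raise ValueError("event times must lie strictly inside (0, t_end)")
        if any(e.delta < 0 for e in events):
            raise ValueError("event deltas must be non-negative")
        if any(e.kind not in ("ADD", "REMOVE") for e in events):
            raise ValueError("event kind must be ADD or REMOVE")
        # targets must never go negative
        level = self.L_ambient
        for e in events:
            level += e.delta if e.kind == "ADD" else -e.delta
            if level < -1e-12:
                raise ValueError(f"event at t={e.t} s drives the target below zero")

    @classmethod
    def add_remove(cls, L_ambient: float, delta: float, t_add: float,
                   t_remove: float, k_rise: float, k_fall: float,
                   t_end: float) -> "StepProtocol":
        """Single added-then-removed step, the experiments' standard protocol."""
        return cls(
            L_ambient=L_ambient,
            events=(Event(t_add, "ADD", delta), Event(t_remove, "REMOVE", delta)),
            k_rise=k_rise, k_fall=k_fall, t_end=t_end,
        )

    # -- segment bookkeeping -------------------------------------------------

    def segments(self) -> list[tuple[float, float, float, float, float]]:
        """Piecewise description: (t_start, t_stop, L_start, target, k).

        ``L(t) = target + (L_start - target) * exp(-k (t - t_start))`` on
        each half-open segment [t_start, t_stop); L is continuous across
        segment boundaries for finite k.
        """
        segs = []
        t0, L0, target = 0.0, self.L_ambient, self.L_ambient
        k = math.inf
        for e in self.events:
            segs.append((t0, e.t, L0, target, k))
            # value just before the event (continuity for finite k)
            L_pre = target + (L0 - target) * _expdecay(k, e.t - t0)
            target = target + (e.delta if e.kind == "ADD" else -e.delta)
            target = max(target, 0.0)
            k = self.k_rise if e.kind == "ADD" else self.k_fall
            t0, L0 = e.t, L_pre
        segs.append((t0, self.t_end, L0, target, k))
        return segs


def _expdecay(k: float, dt) -> float:
    if math.isinf(k):
        return np.where(np.asarray(dt) > 0, 0.0, 1.0) if np.ndim(dt) else (0.0 if dt > 0 else 1.0)
    return np.exp(-k * np.asarray(dt)) if np.ndim(dt) else math.exp(-k * dt)


def concentration(t, protocol: StepProtocol):
    """MeAsp concentration L(t) [mM]; right-continuous at event instants."""
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0) | (t_arr > protocol.t_end)):
        raise ValueError("time outside the protocol window [0, t_end]")
    out = np.empty_like(t_arr, dtype=float)
    for t0, t1, L0, target, k in protocol.segments():
        sel = (t_arr >= t0) & (t_arr < t1) if t1 < protocol.t_end else (t_arr >= t0)
        if not np.any(sel):
            continue
        if math.isinf(k):
            # perfect step, right-continuous: already at the target at t0
            out[sel] = target
        else:
            out[sel] = target + (L0 - target) * np.exp(-k * (t_arr[sel] - t0))
    return out if out.ndim else float(out)


def dL_dt(t, protocol: StepProtocol):
    """Analytic dL/dt [mM/s]; right-derivative convention at event instants."""
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0) | (t_arr > protocol.t_end)):
        raise ValueError("time outside the protocol window [0, t_end]")
    out = np.zeros_like(t_arr, dtype=float)
    for t0, t1, L0, target, k in protocol.segments():
        sel = (t_arr >= t0) & (t_arr < t1) if t1 < protocol.t_end else (t_arr >= t0)
        if not np.any(sel) or math.isinf(k):
            continue
        out[sel] = k * (target - L0) * np.exp(-k * (t_arr[sel] - t0))
    return out if out.ndim else float(out)
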