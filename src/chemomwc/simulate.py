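"""Coupled ligand/methylation dynamics of the dynamic MWC model.

The downstream phosphorylation cascade is fast compared to adaptation,
so the pathway activity measured by FRET is proxied by the receptor
complex activity evaluated algebraically from the static MWC model at
every instant; the only dynamical variable is the methylation level m:

    dm/dt = R(A) - B(A),   A = A(m, L(t); N)

with L(t) from the flow protocol.  The complex size N is fixed for a
protocol at the value for the ambient the cells start adapted to.

The integration restarts at protocol events so the stiff-capable
adaptive solver never steps across a discontinuity in dL/dt.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .adaptation import AdaptationModelSpec, adapted_methylation, dm_dt, steady_state
from .protocol import Event, StepProtocol, concentration
from .receptor import (
    ComplexState,
    ReceptorComplexParams,
    activity,
    complex_size,
    free_energy,
)

__all__ = [
    "TimeCourse",
    "IntegratorConfig",
    "simulate",
    "initial_response",
    "halfway_recovery_time",
    "dose_response",
    "static_response",
    "squared_error",
]


@dataclasses.dataclass(frozen=True)
class IntegratorConfig:
    """Tolerances for the stiff-capable adaptive solver (one scalar ODE,
    so tight tolerances cost essentially nothing)."""

    rtol: float = 1e-9
    atol: float = 1e-11
    method: str = "LSODA"


@dataclasses.dataclass
class TimeCourse:
    """Aligned series of time, concentration, methylation and activity."""

    t: np.ndarray  # s
    L: np.ndarray  # mM
    m: np.ndarray  # methyl groups per dimer
    A: np.ndarray  # activity in [0, 1]
    A_norm: np.ndarray  # activity / adapted pre-stimulus activity
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        if not all(len(x) == n for x in (self.L, self.m, self.A, self.A_norm)):
            raise ValueError("TimeCourse columns must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "L": self.L, "m": self.m, "A": self.A, "A_norm": self.A_norm}
        )


def _activity_of_m(m: float, L: float, N: float,
                   params: ReceptorComplexParams) -> float:
    state = ComplexState(m=max(m, 0.0), L=L, N=N)
    return activity(free_energy(state, params))


def simulate(protocol: StepProtocol, params: ReceptorComplexParams,
             spec: AdaptationModelSpec, a: float, *,
             dt_sample: float = 0.2, N: float | None = None,
             m0: float | None = None,
             integrator: IntegratorConfig | None = None) -> TimeCourse:
    """Integrate the dynamic MWC model along a flow protocol.

    The initial condition is the model's own adapted state at the
    protocol ambient: for precise kinetics the methylation level solving
    activity = a; for imprecise kinetics the root of dm/dt in m.  An
    explicit ``m0`` starts the integration from a displaced methylation
    level instead (A_norm stays normalized by the adapted activity).
    """
    integ = integrator or IntegratorConfig()
    if N is None:
        N = complex_size(protocol.L_ambient, params)
    adapted = steady_state(spec, params, protocol.L_ambient, a_hint=a, N=N)
    A0 = adapted.a
    if m0 is None:
        m0 = adapted.m_adapted

    t_grid = np.arange(0.0, protocol.t_end + dt_sample / 2, dt_sample)
    t_grid = t_grid[t_grid <= protocol.t_end]
    m_out = np.empty_like(t_grid)

    segs = protocol.segments()
    y = m0
    for t0, t1, L0, target, k in segs:
        sel = (t_grid >= t0) & (t_grid < t1) if t1 < protocol.t_end else (t_grid >= t0)
        t_eval = t_grid[sel]

        if math.isinf(k):
            def L_of(t: float, _target=target) -> float:
                return _target
        else:
            def L_of(t: float, _t0=t0, _L0=L0, _target=target, _k=k) -> float:
                return _target + (_L0 - _target) * math.exp(-_k * (t - _t0))

        def rhs(t: float, yv: np.ndarray, _L_of=L_of) -> list[float]:
            A = _activity_of_m(float(yv[0]), _L_of(t), N, params)
            return [dm_dt(A, max(float(yv[0]), 0.0), spec)]

        # append the exact segment end so the restart value comes for free
        if t_eval.size == 0 or t_eval[-1] < t1:
            te = np.append(t_eval, t1)
        else:
            te = t_eval
        sol = solve_ivp(
            rhs, (t0, t1), [y], method=integ.method, t_eval=te,
            rtol=integ.rtol, atol=integ.atol, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed on segment [{t0}, {t1}] "
                f"(target {target} mM): {sol.message}"
            )
        m_out[sel] = sol.y[0][: t_eval.size]
        y = float(sol.y[0, -1])

    L_out = np.asarray(concentration(t_grid, protocol))
    A_out = np.array([
        _activity_of_m(m, L, N, params) for m, L in zip(m_out, L_out)
    ])
    if np.any((A_out < -1e-9) | (A_out > 1 + 1e-9)):
        raise RuntimeError("activity left [0, 1] beyond tolerance")
    return TimeCourse(
        t=t_grid, L=L_out, m=np.maximum(m_out, 0.0), A=A_out,
        A_norm=A_out / A0,
        meta={
            "protocol": protocol, "a": a, "A0": A0, "m0": m0, "N": N,
            "model": spec, "dt_sample": dt_sample,
        },
    )


def _event_window(protocol: StepProtocol, event_time: float,
                  window: float | None) -> float:
    """Post-event search window: 5/k of the relevant flow constant."""
    if window is not None:
        return window
    ev = next((e for e in protocol.events if e.t == event_time), None)
    if ev is None:
        raise ValueError(f"no protocol event at t={event_time}")
    k = protocol.k_rise if ev.kind == "ADD" else protocol.k_fall
    return 5.0 / k if math.isfinite(k) else 5.0


def initial_response(tc: TimeCourse, event_time: float,
                     window: float | None = None) -> float:
    """Normalized initial response amplitude |A_norm extremum - pre-event|.

    The extremum is searched from the event time to event time + 5/k of
    the relevant flow constant (before substantial adaptation sets in).
    """
    protocol: StepProtocol = tc.meta["protocol"]
    w = _event_window(protocol, event_time, window)
    pre = tc.A_norm[tc.t < event_time]
    pre_val = float(pre[-1]) if len(pre) else float(tc.A_norm[0])
    sel = (tc.t >= event_time) & (tc.t <= event_time + w)
    if not np.any(sel):
        raise ValueError("empty post-event search window")
    dev = tc.A_norm[sel] - pre_val
    return float(np.max(np.abs(dev)))


def halfway_recovery_time(tc: TimeCourse, event_time: float,
                          until: float | None = None) -> float:
    """Time after the event for A_norm to return halfway to its pre-event value."""
    pre = tc.A_norm[tc.t < event_time]
    pre_val = float(pre[-1]) if len(pre) else float(tc.A_norm[0])
    sel = tc.t >= event_time
    if until is not None:
        sel &= tc.t <= until
    t_post, dev = tc.t[sel], tc.A_norm[sel] - pre_val
    i_ext = int(np.argmax(np.abs(dev)))
    target = abs(dev[i_ext]) / 2.0
    after = np.abs(dev[i_ext:]) <= target
    if not np.any(after):
        raise ValueError("activity did not recover halfway within the window")
    return float(t_post[i_ext:][np.argmax(after)] - event_time)


def static_response(L_ambient: float, delta: float, direction: str,
                    params: ReceptorComplexParams, a: float) -> float:
    """Closed-form initial response of the static MWC model (frozen m).

    For ADD the cells are adapted at ``L_ambient`` (complex size
    N(L_ambient)); for REMOVE they are adapted at the stepped-up
    concentration with the interpolated complex size N(L_ambient+delta).
    """
    if direction == "ADD":
        L_pre, L_post = L_ambient, L_ambient + delta
    elif direction == "REMOVE":
        L_pre, L_post = L_ambient + delta, L_ambient
    else:
        raise ValueError("direction must be ADD or REMOVE")
    N = complex_size(L_pre, params)
    m_ad = adapted_methylation(L_pre, a, params, N=N)
    A_post = _activity_of_m(m_ad, L_post, N, params)
    return abs(A_post / a - 1.0)


def dose_response(ambients, deltas, params: ReceptorComplexParams,
                  spec: AdaptationModelSpec, a: float, *,
                  k_rise: float, k_fall: float, models=("STATIC", "DYNAMIC"),
                  dt_sample: float = 0.2, t_event: float = 20.0,
                  integrator: IntegratorConfig | None = None) -> pd.DataFrame:
    """Dose-response table: initial response amplitude per (ambient, step).

    Addition points start adapted at the ambient; removal points start
    adapted at ambient+delta (with the correspondingly interpolated
    complex size) and step back down, as in the experimental protocol.
    Returns a DataFrame with columns ambient, delta, direction, model,
    response.
    """
    rows = []
    for L0 in ambients:
        for delta in deltas:
            if delta <= 0:
                raise ValueError("step sizes must be positive")
            for direction in ("ADD", "REMOVE"):
                for model in models:
                    if model == "STATIC":
                        resp = static_response(L0, delta, direction, params, a)
                    elif model == "DYNAMIC":
                        k_min = min(k_rise, k_fall)
                        t_end = t_event + (5.0 / k_min + 10.0
                                           if math.isfinite(k_min) else 15.0)
                        if direction == "ADD":
                            proto = StepProtocol(
                                L_ambient=L0,
                                events=(Event(t_event, "ADD", delta),),
                                k_rise=k_rise, k_fall=k_fall, t_end=t_end,
                            )
                        else:
                            proto = StepProtocol(
                                L_ambient=L0 + delta,
                                events=(Event(t_event, "REMOVE", delta),),
                                k_rise=k_rise, k_fall=k_fall, t_end=t_end,
                            )
                        tc = simulate(proto, params, spec, a,
                                      dt_sample=dt_sample, integrator=integrator)
                        resp = initial_response(tc, t_event)
                    else:
                        raise ValueError("model must be STATIC or DYNAMIC")
                    rows.append(dict(ambient=L0, delta=delta,
                                     direction=direction, model=model,
                                     response=resp))
    return pd.DataFrame(rows)


def squared_error(model_curve: pd.DataFrame, data_curve: pd.DataFrame) -> float:
    """Sum of squared differences of normalized responses on matched grids."""
    keys = ["ambient", "delta", "direction"]
    merged = model_curve.merge(data_curve, on=keys, suffixes=("_model", "_data"))
    if len(merged) != len(model_curve) or len(merged) != len(data_curve):
        raise ValueError("dose-response grids do not match")
    diff = merged["response_model"].to_numpy() - merged["response_data"].to_numpy()
    return float(np.sum(diff**2))
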