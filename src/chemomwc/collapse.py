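"""Data-collapse analysis of adaptation time courses.

For precise adaptation at constant ligand concentration, the rate of
activity change dA/dt is a function g(A) of the activity alone, so every
adaptation time course — whatever the size, direction or number of steps
— collapses onto the one curve g(A).  This module extracts the (A,
dA/dt) point cloud from time courses the way the measurements are
processed (block-average smoothing, difference quotient, onset delay),
transforms it to an effective dm/dt, fits the methylation rate constant
g_R of a named adaptation model, and quantifies the difference between
two collapse sets with a binned permutation test.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .adaptation import dm_dt, get_model
from .receptor import ReceptorComplexParams
from .simulate import TimeCourse

__all__ = [
    "CollapseSet",
    "PermutationResult",
    "smooth",
    "rate_of_change",
    "extract_collapse",
    "effective_dm_dt",
    "model_curve",
    "fit_gR",
    "permutation_test",
]


@dataclasses.dataclass
class CollapseSet:
    """(A, dA/dt) point cloud with per-point step metadata.

    ``points`` columns: A, dAdt, ambient, delta, direction, N.
    """

    points: pd.DataFrame
    strain: str = ""

    def __post_init__(self) -> None:
        required = {"A", "dAdt", "ambient", "delta", "direction", "N"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"collapse points missing columns: {sorted(missing)}")
        vals = self.points[["A", "dAdt"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("collapse points must be finite")

    def merged(self, other: "CollapseSet") -> "CollapseSet":
        return CollapseSet(
            points=pd.concat([self.points, other.points], ignore_index=True),
            strain=self.strain or other.strain,
        )


@dataclasses.dataclass
class PermutationResult:
    unpermuted_error: float
    permuted_errors: np.ndarray
    n_pairs: int
    n_permutations: int
    seed: int
    bins: np.ndarray  # bin edges

    def __post_init__(self) -> None:
        if len(self.permuted_errors) != self.n_permutations:
            raise ValueError("permuted_errors length must equal n_permutations")


def smooth(t: np.ndarray, x: np.ndarray, window: int = 20):
    """Non-overlapping block means of ``window`` consecutive points.

    Block timestamps are block-mean times; a tail shorter than the
    window is dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    n_blocks = len(t) // window
    if n_blocks == 0:
        return np.empty(0), np.empty(0)
    t_b = t[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    x_b = x[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    return t_b, x_b


def rate_of_change(t: np.ndarray, x: np.ndarray, pairing: str = "mid"):
    """Difference-quotient derivative (x[i+1]-x[i])/(t[i+1]-t[i]).

    Returns (x_paired, dxdt).  ``pairing`` chooses the abscissa each
    derivative is attributed to: "mid" (mean of the two points; the
    forward difference of block means is second-order accurate there) or
    "left" (point i).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 points for a difference quotient")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    dxdt = np.diff(x) / dt
    if pairing == "mid":
        x_pair = 0.5 * (x[:-1] + x[1:])
    elif pairing == "left":
        x_pair = x[:-1]
    else:
        raise ValueError("pairing must be 'mid' or 'left'")
    return x_pair, dxdt


def extract_collapse(tc: TimeCourse, onset_delay: float = 10.0,
                     window: int = 20, pairing: str = "mid",
                     strain: str = "") -> CollapseSet:
    """Per-event (A, dA/dt) extraction from a time course.

    Each post-event segment is truncated by ``onset_delay`` seconds
    (discarding the flow-dominated transient), block-smoothed, and
    differenced.  Segments too short to yield a derivative are skipped
    with a warning.
    """
    protocol = tc.meta["protocol"]
    events = list(protocol.events)
    if not events:
        raise ValueError("time course has no protocol events to segment on")
    N = tc.meta["N"]
    rows = []
    bounds = [e.t for e in events] + [float(tc.t[-1]) + 1e-9]
    for ev, t_next in zip(events, bounds[1:]):
        sel = (tc.t >= ev.t + onset_delay) & (tc.t < t_next)
        t_seg, A_seg = tc.t[sel], tc.A[sel]
        t_b, A_b = smooth(t_seg, A_seg, window)
        if len(t_b) < 2:
            warnings.warn(
                f"segment after {ev.kind} at t={ev.t:g}s too short for "
                f"delay={onset_delay}s and window={window}; no points",
                stacklevel=2,
            )
            continue
        A_pair, dAdt = rate_of_change(t_b, A_b, pairing=pairing)
        for Ai, gi in zip(A_pair, dAdt):
            rows.append(dict(A=Ai, dAdt=gi, ambient=protocol.L_ambient,
                             delta=ev.delta, direction=ev.kind, N=N))
    if not rows:
        warnings.warn("no collapse points extracted from time course", stacklevel=2)
    return CollapseSet(
        points=pd.DataFrame(
            rows, columns=["A", "dAdt", "ambient", "delta", "direction", "N"]
        ),
        strain=strain,
    )


def effective_dm_dt(cs: CollapseSet, params: ReceptorComplexParams,
                    guard: float = 1e-4) -> CollapseSet:
    """Divide each dA/dt by dA/dm(A, N) to estimate the methylation rate.

    Points with A(1-A) < ``guard`` (saturated activity, dA/dm ~ 0) are
    dropped.  For segments whose activity change is purely adaptation
    the result is proportional to dm/dt.
    """
    pts = cs.points.copy()
    A = pts["A"].to_numpy(dtype=float)
    N = pts["N"].to_numpy(dtype=float)
    keep = A * (1 - A) >= guard
    pts = pts.loc[keep].copy()
    dAdm = -params.fm_slope * N[keep] * A[keep] * (1 - A[keep])
    pts["dmdt"] = pts["dAdt"].to_numpy(dtype=float) / dAdm
    return CollapseSet(points=pts, strain=cs.strain)


def _unit_psi(A: np.ndarray, N: np.ndarray, model_name: str, a: float,
              params: ReceptorComplexParams) -> np.ndarray:
    """g(A)/g_R for the named precise model: the fit design vector."""
    spec = get_model(model_name, g_R=1.0, a=a)
    return -params.fm_slope * N * A * (1 - A) * np.asarray(dm_dt(A, np.zeros_like(A), spec))


def model_curve(model_name: str, a: float, g_R: float, N: float,
                params: ReceptorComplexParams) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic collapse curve g(A) of a named precise model."""
    def g(A):
        A = np.asarray(A, dtype=float)
        return g_R * _unit_psi(A, np.full_like(A, N), model_name, a, params)
    return g


def fit_gR(cs: CollapseSet, a: float, model_name: str,
           params: ReceptorComplexParams) -> tuple[float, float]:
    """One-parameter least squares of a model's g(A) against collapse points.

    The demethylation constant is slaved to g_R through the adapted
    activity, so the model curve is linear in g_R and the fit is closed
    form.  Returns (g_R_hat, residual sum of squares).
    """
    if len(cs.points) < 3:
        raise ValueError("need at least 3 collapse points to fit g_R")
    A = cs.points["A"].to_numpy(dtype=float)
    y = cs.points["dAdt"].to_numpy(dtype=float)
    N = cs.points["N"].to_numpy(dtype=float)
    psi = _unit_psi(np.clip(A, 0.0, 1.0), N, model_name, a, params)
    denom = float(psi @ psi)
    if denom == 0.0:
        raise ValueError("degenerate design: model curve vanishes on all points")
    g_R_hat = float(psi @ y) / denom
    resid = float(np.sum((y - g_R_hat * psi) ** 2))
    return g_R_hat, resid


def _default_bins(A1: np.ndarray, A2: np.ndarray, n_bins: int) -> np.ndarray:
    """Exactly ``n_bins`` bins over the shared activity range, each holding
    at least one point from each set.

    Greedy left-to-right cuts give the maximal number of covered bins;
    adjacent bins are then merged (smallest combined width first) down to
    ``n_bins``, so every permutation draws a pair from every bin.
    """
    lo = max(A1.min(), A2.min())
    hi = min(A1.max(), A2.max())
    if not hi > lo:
        raise ValueError("collapse sets share no activity range to bin")
    s1 = A1[(A1 >= lo) & (A1 <= hi)]
    s2 = A2[(A2 >= lo) & (A2 <= hi)]
    vals = np.concatenate([s1, s2])
    labels = np.concatenate([np.ones(len(s1)), 2 * np.ones(len(s2))])
    order = np.argsort(vals, kind="stable")
    vals, labels = vals[order], labels[order]
    # greedy: cut as soon as the open bin has seen both labels
    cuts: list[float] = []
    seen: set[float] = set()
    for i, lab in enumerate(labels):
        seen.add(lab)
        if len(seen) == 2 and i + 1 < len(vals):
            cuts.append(0.5 * (vals[i] + vals[i + 1]))
            seen = set()
    if seen != {1.0, 2.0} and cuts:
        cuts.pop()  # tail bin lacks one set: merge it into the previous bin
    edges = np.array([lo, *cuts, hi])
    if len(edges) - 1 < n_bins:
        raise ValueError(
            f"cannot form {n_bins} bins each populated by both sets "
            f"(at most {len(edges) - 1} possible)"
        )
    while len(edges) - 1 > n_bins:
        widths = np.diff(edges)
        j = int(np.argmin(widths[:-1] + widths[1:]))  # merge narrowest pair
        edges = np.delete(edges, j + 1)
    return edges


def permutation_test(csA: CollapseSet, csB: CollapseSet,
                     modelA: Callable, modelB: Callable,
                     bin_edges: Sequence[float] | None = None,
                     n_pairs: int = 4, n_permutations: int = 100,
                     seed: int = 0, n_bins: int = 4) -> PermutationResult:
    """Binned permutation test of the difference between two collapse sets.

    Each permutation swaps one randomly chosen point between the sets in
    each of ``n_pairs`` randomly chosen bins; the statistic is the sum of
    squared errors of each (swapped) set against its own model curve.
    If the unpermuted error sits below the whole permuted distribution,
    the two data sets are significantly different and each matches its
    own model.
    """
    A1 = csA.points["A"].to_numpy(dtype=float)
    y1 = csA.points["dAdt"].to_numpy(dtype=float)
    A2 = csB.points["A"].to_numpy(dtype=float)
    y2 = csB.points["dAdt"].to_numpy(dtype=float)
    edges = (np.asarray(bin_edges, dtype=float) if bin_edges is not None
             else _default_bins(A1, A2, n_bins))
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing with at least one bin")
    nb = len(edges) - 1
    if n_pairs > nb:
        raise ValueError(f"n_pairs={n_pairs} exceeds the {nb} available bins")

    # residual of every point under its own and under the other model
    own1 = (y1 - np.asarray(modelA(A1))) ** 2
    cross1 = (y1 - np.asarray(modelB(A1))) ** 2  # if moved into set B
    own2 = (y2 - np.asarray(modelB(A2))) ** 2
    cross2 = (y2 - np.asarray(modelA(A2))) ** 2
    e0 = float(own1.sum() + own2.sum())

    # indices of swappable points per bin (interior bins half-open, last closed)
    idx1, idx2 = [], []
    for b in range(nb):
        hi_cmp = (A1 <= edges[b + 1]) if b == nb - 1 else (A1 < edges[b + 1])
        i1 = np.where((A1 >= edges[b]) & hi_cmp)[0]
        hi_cmp2 = (A2 <= edges[b + 1]) if b == nb - 1 else (A2 < edges[b + 1])
        i2 = np.where((A2 >= edges[b]) & hi_cmp2)[0]
        if len(i1) == 0 or len(i2) == 0:
            raise ValueError(f"bin {b} [{edges[b]:.3g}, {edges[b+1]:.3g}] lacks "
                             "points from one of the sets")
        idx1.append(i1)
        idx2.append(i2)

    rng = np.random.default_rng(seed)
    errors = np.empty(n_permutations)
    for p in range(n_permutations):
        bins_chosen = (np.arange(nb) if n_pairs == nb
                       else rng.choice(nb, size=n_pairs, replace=False))
        e = e0
        for b in bins_chosen:
            i = rng.choice(idx1[b])
            j = rng.choice(idx2[b])
            # point i leaves set A for set B and vice versa
            e += (cross1[i] - own1[i]) + (cross2[j] - own2[j])
        errors[p] = e
    return PermutationResult(
        unpermuted_error=e0, permuted_errors=errors, n_pairs=n_pairs,
        n_permutations=n_permutations, seed=seed, bins=edges,
    )
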