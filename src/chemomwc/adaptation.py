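"""Methylation/demethylation adaptation kinetics of receptor complexes.

Adaptation is modelled as an ODE for the average methylation level ``m``
per receptor dimer, driven only by the complex activity ``A`` (the
Barkai-Leibler condition for robust precise adaptation):

    dm/dt = R(A) - B(A)

where ``R`` is the CheR-catalysed methylation rate of inactive receptors
and ``B`` the CheB-catalysed demethylation rate of active receptors.
Three model families are implemented:

``POWER``
    R = g_R * (1 - A),  B = g_B * A**h.  The exponent ``h`` counts the
    layers of demethylation feedback: h=1 no CheB-P feedback, h=2 linear
    CheB-P feedback, h=3 cooperative feedback of two CheB-P molecules
    (the headline model; its strong activity dependence makes
    demethylation of active receptors much faster than methylation of
    inactive ones).

``MICHAELIS``
    Ultrasensitive enzyme-saturation kinetics,
    R = g_R (1-A) / (K_R + 1-A),  B = g_B A / (K_B + A), with one extra
    factor of A on B for linear CheB-P feedback (``mm_feedback``).

``CHEB_MUTANT``
    Non-phosphorylatable CheB: the only activity dependence of
    demethylation is CheB binding to active receptors, B = g_B * A.

Imprecise adaptation multiplies both rates by site-availability
efficiencies of the methylation level: methylation needs free sites
(M_max - m), demethylation needs occupied sites (m), and either rate is
linearly reduced once fewer than ``m_c`` sites are available:

    R *= clip((M_max - m) / m_c, 0, 1),   B *= clip(m / m_c, 0, 1).

The steady state of a precise model fixes the demethylation constant:
``g_B = solve_gB(g_R, a, spec)`` makes the adapted activity ``a`` the
unique interior fixed point.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .receptor import (
    ComplexState,
    ReceptorComplexParams,
    activity,
    complex_size,
    free_energy,
    ligand_energy,
)

__all__ = [
    "AdaptationModelSpec",
    "AdaptedState",
    "MODEL_NAMES",
    "get_model",
    "dm_dt",
    "solve_gB",
    "adapted_methylation",
    "methylation_at_activity",
    "collapse_function",
    "fixed_points",
    "steady_state",
]

Family = Literal["POWER", "MICHAELIS", "CHEB_MUTANT"]


@dataclasses.dataclass(frozen=True)
class AdaptationModelSpec:
    """One member of the adaptation-kinetics model family."""

    family: Family
    g_R: float  # methylation rate constant [methyl groups / s]
    g_B: float | None = None  # demethylation rate constant [methyl groups / s]
    h: int = 3  # demethylation activity exponent (POWER family)
    K_R: float = math.nan  # Michaelis constant of methylation [activity units]
    K_B: float = math.nan  # Michaelis constant of demethylation [activity units]
    mm_feedback: bool = False  # linear CheB-P feedback on the Michaelis B term
    imprecise: bool = False
    M_max: float = math.nan  # methylatable sites per dimer (imprecise model)
    m_c: float = math.nan  # sites needed for full (de)methylation efficiency

    def __post_init__(self) -> None:
        if self.family not in ("POWER", "MICHAELIS", "CHEB_MUTANT"):
            raise ValueError(f"unknown adaptation family {self.family!r}")
        if self.g_R <= 0:
            raise ValueError("g_R must be positive")
        if self.g_B is not None and self.g_B <= 0:
            raise ValueError("g_B must be positive")
        if self.family == "POWER" and self.h not in (1, 2, 3):
            raise ValueError("POWER family exponent h must be 1, 2 or 3")
        if self.family == "MICHAELIS" and not (self.K_R > 0 and self.K_B > 0):
            raise ValueError("MICHAELIS family requires K_R, K_B > 0")
        if self.imprecise and not (0 <= self.m_c < self.M_max):
            raise ValueError("imprecise model requires 0 <= m_c < M_max")

    def with_gB(self, a: float) -> "AdaptationModelSpec":
        """Return a copy whose g_B balances the kinetics at adapted activity a."""
        return dataclasses.replace(self, g_B=solve_gB(self.g_R, a, self))


@dataclasses.dataclass(frozen=True)
class AdaptedState:
    """Adapted (steady-state) activity and the methylation level realizing it."""

    a: float
    m_adapted: float

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError("adapted activity must lie strictly in (0, 1)")
        if self.m_adapted < 0:
            raise ValueError("adapted methylation level must be non-negative")


# ---------------------------------------------------------------------------
# model registry

#: defaults used by get_model when the caller does not override them; the
#: reference values live in the packaged configuration (see chemomwc.config)
_REGISTRY: dict[str, dict] = {
    "power-h3": dict(family="POWER", h=3),
    "power-h2": dict(family="POWER", h=2),
    "power-h1": dict(family="POWER", h=1),
    "mm-feedback": dict(family="MICHAELIS", mm_feedback=True),
    "mm-nofeedback": dict(family="MICHAELIS", mm_feedback=False),
    "cheb-mutant": dict(family="CHEB_MUTANT"),
}

MODEL_NAMES = tuple(_REGISTRY)


def get_model(name: str, *, g_R: float | None = None, a: float | None = None,
              imprecise: bool = False, **overrides) -> AdaptationModelSpec:
    """Build a registered adaptation model by name.

    Parameters
    ----------
    name
        One of ``MODEL_NAMES``.
    g_R
        Methylation rate constant; defaults to the reference configuration.
    a
        If given, ``g_B`` is solved so that ``a`` is the adapted activity.
    imprecise
        Enable the site-availability (imprecise-adaptation) factors.
    overrides
        Any other :class:`AdaptationModelSpec` field.
    """
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown adaptation model {name!r}; registered models: "
            + ", ".join(MODEL_NAMES)
        )
    from . import config  # deferred: config imports nothing from here at module load

    defaults = config.reference_adaptation_defaults()
    kwargs = dict(_REGISTRY[name])
    kwargs.setdefault("K_R", defaults["K_R"])
    kwargs.setdefault("K_B", defaults["K_B"])
    kwargs["g_R"] = defaults["g_R"] if g_R is None else g_R
    kwargs["imprecise"] = imprecise
    if imprecise:
        kwargs.setdefault("M_max", defaults["M_max"])
        kwargs.setdefault("m_c", defaults["m_c"])
    kwargs.update(overrides)
    spec = AdaptationModelSpec(**kwargs)
    if a is not None:
        spec = spec.with_gB(a)
    return spec


# ---------------------------------------------------------------------------
# kinetics

def _rates(A, spec: AdaptationModelSpec):
    """Methylation and demethylation rates (R, B) before imprecision factors."""
    if spec.g_B is None:
        raise ValueError("g_B is unset; call spec.with_gB(a) or solve_gB first")
    A = np.asarray(A, dtype=float)
    if np.any((A < 0) | (A > 1)):
        raise ValueError("activity A must lie in [0, 1]")
    if spec.family == "POWER":
        R = spec.g_R * (1.0 - A)
        B = spec.g_B * A**spec.h
    elif spec.family == "CHEB_MUTANT":
        R = spec.g_R * (1.0 - A)
        B = spec.g_B * A
    else:  # MICHAELIS
        R = spec.g_R * (1.0 - A) / (spec.K_R + (1.0 - A))
        B = spec.g_B * A / (spec.K_B + A)
        if spec.mm_feedback:
            B = B * A
    return R, B


def _site_factors(m, spec: AdaptationModelSpec):
    """Imprecise-adaptation efficiency factors (methylation, demethylation)."""
    m = np.asarray(m, dtype=float)
    f_meth = np.clip((spec.M_max - m) / spec.m_c, 0.0, 1.0)
    f_demeth = np.clip(m / spec.m_c, 0.0, 1.0)
    return f_meth, f_demeth


def dm_dt(A, m, spec: AdaptationModelSpec):
    """Rate of change of the methylation level [methyl groups / s]."""
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0):
        raise ValueError("methylation level m must be non-negative")
    R, B = _rates(A, spec)
    if spec.imprecise:
        f_meth, f_demeth = _site_factors(m_arr, spec)
        R = R * f_meth
        B = B * f_demeth
    out = R - B
    return out if np.ndim(out) else float(out)


def solve_gB(g_R: float, a: float, spec: AdaptationModelSpec) -> float:
    """Demethylation constant balancing the kinetics at adapted activity ``a``.

    Closed forms: POWER g_B = g_R (1-a)/a**h; CHEB_MUTANT g_B = g_R (1-a)/a;
    MICHAELIS g_B = g_R (1-a)/(K_R+1-a) * (K_B+a)/a**(2 if feedback else 1).
    The imprecise site factors are deliberately ignored: the reference model
    keeps the same rate constants with and without imprecision.
    """
    if not 0.0 < a < 1.0:
        raise ValueError("adapted activity a must lie strictly in (0, 1)")
    if g_R <= 0:
        raise ValueError("g_R must be positive")
    if spec.family == "POWER":
        return g_R * (1.0 - a) / a**spec.h
    if spec.family == "CHEB_MUTANT":
        return g_R * (1.0 - a) / a
    power = 2 if spec.mm_feedback else 1
    return g_R * (1.0 - a) / (spec.K_R + 1.0 - a) * (spec.K_B + a) / a**power


# ---------------------------------------------------------------------------
# adapted state and data collapse

def adapted_methylation(L_ambient: float, a: float,
                        params: ReceptorComplexParams,
                        N: float | None = None) -> float:
    """Methylation level at which the complex activity equals ``a``.

    Inverts A = 1/(1+exp(F)) in m:  f(m) = ln((1-a)/a)/N - ligand_energy(L),
    then m = (f - fm_intercept)/fm_slope.  ``N`` defaults to the adapted
    complex size at ``L_ambient``.
    """
    if not 0.0 < a < 1.0:
        raise ValueError("adapted activity a must lie strictly in (0, 1)")
    if N is None:
        N = complex_size(L_ambient, params)
    f = math.log((1.0 - a) / a) / N - ligand_energy(L_ambient, params)
    m = (f - params.fm_intercept) / params.fm_slope
    if m < 0:
        raise ValueError(
            f"adapted methylation is negative (m={m:.4g}) at ambient "
            f"{L_ambient} mM, a={a}: model inconsistency at this ambient"
        )
    return m


def methylation_at_activity(A: float, L: float, params: ReceptorComplexParams,
                            N: float) -> float:
    """Methylation level giving activity ``A`` at concentration ``L`` (clipped at 0)."""
    if not 0.0 < A < 1.0:
        raise ValueError("activity must lie strictly in (0, 1) to invert")
    f = math.log((1.0 - A) / A) / N - ligand_energy(L, params)
    return max(0.0, (f - params.fm_intercept) / params.fm_slope)


def collapse_function(A, spec: AdaptationModelSpec,
                      params: ReceptorComplexParams, L_ambient: float):
    """Adaptation-only rate of activity change g(A) = dA/dm * dm/dt  [1/s].

    For precise models g depends only on A (and the complex size N at the
    ambient):  g(A) = -fm_slope * N * A(1-A) * dm_dt(A).  For imprecise
    models the methylation level entering the site factors is recovered by
    inverting the activity at ``L_ambient``.
    """
    A = np.asarray(A, dtype=float)
    N = complex_size(L_ambient, params)
    dAdm = -params.fm_slope * N * A * (1.0 - A)
    if spec.imprecise:
        Af = np.atleast_1d(A)
        m = np.array([
            methylation_at_activity(float(x), L_ambient, params, N)
            if 0.0 < x < 1.0 else 0.0
            for x in Af
        ]).reshape(A.shape)
    else:
        m = np.zeros_like(A)  # irrelevant for precise kinetics
    out = dAdm * dm_dt(A, m, spec)
    return out if out.ndim else float(out)


def fixed_points(spec: AdaptationModelSpec, params: ReceptorComplexParams,
                 L_ambient: float, grid: float = 1e-4,
                 merge_tol: float = 1e-8) -> list[float]:
    """Zeros of the collapse function on [0, 1] (precise models only).

    Sign-change scan on a uniform grid followed by bisection polishing to
    1e-10.  The saturated endpoints A=0 and A=1 are always fixed points.
    """
    if spec.imprecise:
        raise ValueError(
            "fixed_points is defined for precise models only; the imprecise "
            "model's fixed points live in the full (A, m) system"
        )
    g = lambda A: collapse_function(A, spec, params, L_ambient)
    xs = np.arange(0.0, 1.0 + grid / 2, grid)
    ys = np.asarray(g(xs))
    roots = [0.0, 1.0]
    for i in range(len(xs) - 1):
        lo, hi = xs[i], xs[i + 1]
        ylo, yhi = ys[i], ys[i + 1]
        if ylo == 0.0 and lo not in (0.0,):
            roots.append(float(lo))
        elif ylo * yhi < 0:
            roots.append(float(brentq(g, lo, hi, xtol=1e-10)))
    roots.sort()
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > merge_tol:
            merged.append(r)
    return merged


def steady_state(spec: AdaptationModelSpec, params: ReceptorComplexParams,
                 L_ambient: float, a_hint: float,
                 N: float | None = None) -> AdaptedState:
    """Adapted state of the model at a constant ambient concentration.

    For precise models this is exactly (a_hint, adapted_methylation): the
    kinetics balance at a_hint by construction of g_B.  For imprecise models
    the interior zero of dm/dt(A(m), m) is root-found in m.
    """
    if N is None:
        N = complex_size(L_ambient, params)
    if not spec.imprecise:
        m = adapted_methylation(L_ambient, a_hint, params, N=N)
        return AdaptedState(a=a_hint, m_adapted=m)

    def rhs(m: float) -> float:
        A = activity(free_energy(ComplexState(m=m, L=L_ambient, N=N), params))
        return dm_dt(A, m, spec)

    # bracket the interior root: rhs > 0 at m=0 (pure methylation of an
    # inactive-site-free receptor is impossible -> rhs(0) = R(A(0)) >= 0)
    lo, hi = 0.0, spec.M_max
    if rhs(lo) <= 0:
        raise ValueError("imprecise kinetics have no methylating branch at m=0")
    if rhs(hi) >= 0:
        # methylation saturates exactly at M_max
        m_star = hi
    else:
        m_star = brentq(rhs, lo, hi, xtol=1e-12)
    A_star = activity(free_energy(ComplexState(m=m_star, L=L_ambient, N=N), params))
    return AdaptedState(a=float(A_star), m_adapted=float(m_star))
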