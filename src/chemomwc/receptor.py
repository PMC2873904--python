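"""Static MWC model of mixed Tar/Tsr chemoreceptor complexes.

A receptor complex of ``N`` strongly coupled dimers is a two-state
(on/off) allosteric unit.  Its activity is the Boltzmann probability of
the on state,

    A = 1 / (1 + exp(F)),

where ``F`` (in units of kT) is the free-energy difference between the
on and off states,

    F = N * [ f(m)
              + nu_a * ln((1 + L/K_off_a) / (1 + L/K_on_a))
              + nu_s * ln((1 + L/K_off_s) / (1 + L/K_on_s)) ].

``f(m) = fm_intercept + fm_slope * m`` is the per-dimer methylation free
energy (methylation lowers F and so raises activity, fm_slope < 0); the
log terms are per-dimer ligand free energies of Tar (``a``) and Tsr
(``s``) for the attractant MeAsp, which favours the off state because
K_off < K_on.  The number of dimers per complex grows roughly linearly
with the ambient concentration the cells are adapted to,
``N(L0) = N0 + c * L0``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "ReceptorComplexParams",
    "ComplexState",
    "methylation_energy",
    "ligand_energy",
    "free_energy",
    "activity",
    "dA_dm",
    "dA_dL",
    "complex_size",
]

#: exponent clamp: beyond this the logistic is exactly 0 or 1 in double precision
_EXP_CLAMP = 700.0


@dataclasses.dataclass(frozen=True)
class ReceptorComplexParams:
    """Constants of the static MWC model for mixed Tar/Tsr complexes.

    Concentrations in mM, energies in kT, complex size in dimers.
    """

    nu_a: float  # fraction of Tar dimers per complex
    nu_s: float  # fraction of Tsr dimers per complex
    K_off_a: float  # MeAsp dissociation constant, Tar off state [mM]
    K_on_a: float  # MeAsp dissociation constant, Tar on state [mM]
    K_off_s: float  # MeAsp dissociation constant, Tsr off state [mM]
    K_on_s: float  # MeAsp dissociation constant, Tsr on state [mM]
    fm_intercept: float  # f(m) intercept [kT]
    fm_slope: float  # f(m) slope [kT per methyl group], negative
    size_intercept: float  # N0 [dimers]
    size_slope: float  # c [dimers per mM ambient]

    def __post_init__(self) -> None:
        for name in ("K_off_a", "K_on_a", "K_off_s", "K_on_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not self.K_off_a < self.K_on_a:
            raise ValueError("attractant requires K_off_a < K_on_a")
        if not self.K_off_s < self.K_on_s:
            raise ValueError("attractant requires K_off_s < K_on_s")
        if not 0.0 <= self.nu_a <= 1.0:
            raise ValueError("nu_a must lie in [0, 1]")
        if not math.isclose(self.nu_a + self.nu_s, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("nu_a + nu_s must equal 1")
        if self.fm_slope >= 0:
            raise ValueError("fm_slope must be negative (methylation favours the on state)")
        if self.size_intercept < 1:
            raise ValueError("complex size intercept must be >= 1 dimer")


@dataclasses.dataclass(frozen=True)
class ComplexState:
    """Instantaneous state of one receptor complex."""

    m: float  # average methylation level per dimer [methyl groups]
    L: float  # MeAsp concentration [mM]
    N: float  # complex size [dimers]

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("methylation level m must be non-negative")
        if self.L < 0:
            raise ValueError("ligand concentration L must be non-negative")
        if self.N < 1:
            raise ValueError("complex size N must be >= 1")


def methylation_energy(m, params: ReceptorComplexParams):
    """Per-dimer methylation free energy f(m) = fm_intercept + fm_slope*m [kT]."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("methylation level m must be non-negative")
    out = params.fm_intercept + params.fm_slope * m
    return out if out.ndim else float(out)


def ligand_energy(L, params: ReceptorComplexParams):
    """Per-dimer ligand free energy of the mixed complex [kT]; >= 0 for attractant."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration L must be non-negative")
    term_a = np.log1p(L / params.K_off_a) - np.log1p(L / params.K_on_a)
    term_s = np.log1p(L / params.K_off_s) - np.log1p(L / params.K_on_s)
    out = params.nu_a * term_a + params.nu_s * term_s
    return out if out.ndim else float(out)


def free_energy(state: ComplexState, params: ReceptorComplexParams) -> float:
    """On/off free-energy difference F of the complex [kT]."""
    return state.N * (
        methylation_energy(state.m, params) + ligand_energy(state.L, params)
    )


def activity(F):
    """Complex activity A = 1/(1 + exp(F)), the probability of the on state.

    Beyond |F| = 700 the logistic is saturated past double precision; the
    exact 0/1 limits are returned instead of overflowing.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("free energy must be finite")
    out = 1.0 / (1.0 + np.exp(np.clip(F, -_EXP_CLAMP, _EXP_CLAMP)))
    out = np.where(F >= _EXP_CLAMP, 0.0, np.where(F <= -_EXP_CLAMP, 1.0, out))
    return out if out.ndim else float(out)


def _activity_of(state: ComplexState, params: ReceptorComplexParams) -> float:
    return activity(free_energy(state, params))


def dA_dm(state: ComplexState, params: ReceptorComplexParams) -> float:
    """Analytic dA/dm = -A(1-A) * N * fm_slope  [per methyl group]; positive."""
    A = _activity_of(state, params)
    return -A * (1.0 - A) * state.N * params.fm_slope


def dA_dL(state: ComplexState, params: ReceptorComplexParams) -> float:
    """Analytic dA/dL [per mM]; negative for an attractant.

    dF/dL per dimer is nu_a*(1/(K_off_a+L) - 1/(K_on_a+L)) + (same for Tsr),
    and dA/dL = -A(1-A) * N * dF/dL.
    """
    A = _activity_of(state, params)
    L = state.L
    dF = state.N * (
        params.nu_a * (1.0 / (params.K_off_a + L) - 1.0 / (params.K_on_a + L))
        + params.nu_s * (1.0 / (params.K_off_s + L) - 1.0 / (params.K_on_s + L))
    )
    return -A * (1.0 - A) * dF


def complex_size(L_ambient, params: ReceptorComplexParams):
    """Adapted complex size N = N0 + c*L_ambient [dimers], continuous-valued."""
    L_ambient = np.asarray(L_ambient, dtype=float)
    if np.any(L_ambient < 0):
        raise ValueError("ambient concentration must be non-negative")
    N = params.size_intercept + params.size_slope * L_ambient
    if np.any(N < 1):
        raise ValueError("complex size fell below 1 dimer for the requested ambient")
    return N if N.ndim else float(N)
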