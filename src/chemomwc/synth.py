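"""Synthetic FRET-like experiments with known ground truth.

Generates the measurement campaigns the analysis pipeline expects:
adapted cells stimulated by added-then-removed MeAsp concentration
steps, sampled at the strain's time resolution, with additive Gaussian
noise on the normalized activity, emitted as a FRET-ratio series through
the inverse of the ratio->activity transform.  The ground-truth time
course is always returned alongside the noisy series, so parameter
recovery can be scored exactly.

Strain presets (from the reference configuration):

=============  =====  ============  ==================================
preset         a      dt_sample     campaign
=============  =====  ============  ==================================
WT1            1/3    0.2 s         ambient 0.1 mM; steps 0.03, 0.05,
                                    0.1, 0.4, 2 mM added then removed
WT2            1/2    1 s           ambient 0; step 0.1 mM
CHEB_MUTANT    1/2    1 s           ambient 0; steps 0.05, 0.1 mM
=============  =====  ============  ==================================
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import config
from .adaptation import get_model
from .collapse import CollapseSet, extract_collapse
from .fretio import FretCalibration, activity_to_ratio, ratio_to_activity
from .protocol import StepProtocol
from .receptor import ReceptorComplexParams, complex_size
from .simulate import IntegratorConfig, TimeCourse, simulate

__all__ = [
    "SyntheticExperimentSpec",
    "CAMPAIGNS",
    "campaign_protocol",
    "campaign_specs",
    "ground_truth",
    "noisy_ratio",
    "generate",
    "timecourse_from_ratio",
    "campaign_collapse",
]

#: (ambient [mM], step sizes [mM]) of each strain's reference campaign
CAMPAIGNS: dict[str, tuple[float, tuple[float, ...]]] = {
    "WT1": (0.1, (0.03, 0.05, 0.1, 0.4, 2.0)),
    "WT2": (0.0, (0.1,)),
    "CHEB_MUTANT": (0.0, (0.05, 0.1)),
}

#: independent repeats of the campaign per strain: the analysis pools all
#: time courses of a strain, and the single-step strains need comparable
#: point counts to the five-step wild type
CAMPAIGN_REPEATS: dict[str, int] = {"WT1": 1, "WT2": 3, "CHEB_MUTANT": 2}

#: default additive noise on normalized activity (visually matched to the
#: trace-to-trace scatter of population FRET recordings)
DEFAULT_NOISE_SD = 0.05

_DEFAULT_CALIB = dict(R_sat=1.2, R_0=1.4)


@dataclasses.dataclass(frozen=True)
class SyntheticExperimentSpec:
    """One synthetic experiment: strain preset + protocol + noise + seed."""

    strain: str
    protocol: StepProtocol
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    mode: str = "ratiometric"  # ratio<->activity transform mode

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        config.strain_preset(self.strain)  # validates the name

    @property
    def preset(self) -> dict:
        return config.strain_preset(self.strain)

    @property
    def calibration(self) -> FretCalibration:
        p = self.preset
        return FretCalibration(alpha=p["alpha"], dt_sample=p["dt_sample"],
                               **_DEFAULT_CALIB)


def campaign_protocol(ambient: float, delta: float, k_rise: float,
                      k_fall: float, t_add: float = 50.0,
                      t_adapt: float = 600.0, t_tail: float = 150.0) -> StepProtocol:
    """Added-then-removed step with enough time to re-adapt in between."""
    return StepProtocol.add_remove(
        L_ambient=ambient, delta=delta, t_add=t_add, t_remove=t_add + t_adapt,
        k_rise=k_rise, k_fall=k_fall, t_end=t_add + t_adapt + t_tail,
    )


def campaign_specs(strain: str, seed: int = 0,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   n_repeats: int | None = None) -> list[SyntheticExperimentSpec]:
    """The strain's reference campaign, one spec per step size and repeat."""
    if strain not in CAMPAIGNS:
        raise KeyError(f"no reference campaign for strain {strain!r}")
    ambient, deltas = CAMPAIGNS[strain]
    if n_repeats is None:
        n_repeats = CAMPAIGN_REPEATS[strain]
    p = config.strain_preset(strain)
    specs = []
    for i, delta in enumerate(list(deltas) * n_repeats):
        sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        specs.append(SyntheticExperimentSpec(
            strain=strain,
            protocol=campaign_protocol(ambient, delta, p["k_rise"], p["k_fall"]),
            noise_sd=noise_sd, seed=sub,
        ))
    return specs


def ground_truth(strain: str, protocol: StepProtocol,
                 params: ReceptorComplexParams | None = None,
                 integrator: IntegratorConfig | None = None) -> TimeCourse:
    """Noise-free simulation of the strain's model along the protocol."""
    params = params or config.reference_receptor_params()
    p = config.strain_preset(strain)
    spec = get_model(p["model"], a=p["a"])
    tc = simulate(protocol, params, spec, p["a"], dt_sample=p["dt_sample"],
                  integrator=integrator)
    tc.meta["strain"] = strain
    return tc


def noisy_ratio(truth: TimeCourse, noise_sd: float, seed: int,
                calib: FretCalibration, mode: str = "ratiometric") -> pd.DataFrame:
    """Noisy FRET-ratio series: Gaussian noise on A_norm, then the inverse transform."""
    rng = np.random.default_rng(seed)
    A_norm = truth.A_norm + rng.normal(0.0, noise_sd, size=len(truth.A_norm))
    R = activity_to_ratio(A_norm, calib, mode=mode)
    return pd.DataFrame({"t": truth.t, "R": R})


def generate(spec: SyntheticExperimentSpec,
             params: ReceptorComplexParams | None = None,
             truth: TimeCourse | None = None) -> tuple[pd.DataFrame, TimeCourse]:
    """Synthetic FRET experiment: (ratio series, ground-truth time course).

    A pre-computed ``truth`` for the same strain/protocol may be passed to
    amortize the simulation across noise seeds.
    """
    if truth is None:
        truth = ground_truth(spec.strain, spec.protocol, params=params)
    ratio = noisy_ratio(truth, spec.noise_sd, spec.seed, spec.calibration,
                        mode=spec.mode)
    return ratio, truth


def timecourse_from_ratio(ratio: pd.DataFrame, calib: FretCalibration,
                          protocol: StepProtocol, a: float,
                          params: ReceptorComplexParams | None = None,
                          mode: str = "ratiometric",
                          strain: str = "") -> TimeCourse:
    """Reconstruct an activity time course from a measured ratio series.

    The analysis-side inverse of the measurement model: normalized
    activity from the ratio, raw activity as A_norm * a, complex size
    from the protocol ambient.
    """
    params = params or config.reference_receptor_params()
    t = ratio["t"].to_numpy(dtype=float)
    A_norm = np.asarray(ratio_to_activity(ratio["R"].to_numpy(dtype=float),
                                          calib, mode=mode))
    A = np.clip(A_norm * a, 0.0, 1.0)
    N = complex_size(protocol.L_ambient, params)
    return TimeCourse(
        t=t, L=np.zeros_like(t), m=np.zeros_like(t), A=A, A_norm=A_norm,
        meta={"protocol": protocol, "a": a, "N": N, "strain": strain},
    )


def campaign_collapse(strain: str, seed: int = 0,
                      noise_sd: float = DEFAULT_NOISE_SD,
                      params: ReceptorComplexParams | None = None,
                      truths: list[TimeCourse] | None = None,
                      onset_delay: float | None = None,
                      window: int = 20) -> CollapseSet:
    """End-to-end: campaign -> noisy ratios -> reconstructed collapse set.

    ``truths`` (one per campaign step, e.g. from :func:`ground_truth`)
    can be supplied to reuse simulations across noise seeds.

    The default onset delay is flow-aware, max(10 s, 12/k): the delay
    exists to discard flow-dominated dynamics, and with the receptor's
    high ligand sensitivity near ambient the concentration transient
    must decay by many e-foldings before dA/dt is purely adaptation.
    """
    params = params or config.reference_receptor_params()
    p = config.strain_preset(strain)
    if onset_delay is None:
        onset_delay = max(10.0, 12.0 / min(p["k_rise"], p["k_fall"]))
    specs = campaign_specs(strain, seed=seed, noise_sd=noise_sd)
    if truths is None:
        cache: dict[StepProtocol, TimeCourse] = {}
        for s in specs:  # repeats share a protocol, hence one simulation
            if s.protocol not in cache:
                cache[s.protocol] = ground_truth(strain, s.protocol, params=params)
        truths = [cache[s.protocol] for s in specs]
    merged: CollapseSet | None = None
    for s, truth in zip(specs, truths):
        ratio, _ = generate(s, params=params, truth=truth)
        with warnings.catch_warnings():
            # noise below the zero-FRET bound is clamped by design here
            warnings.filterwarnings("ignore", message=".*zero-FRET bound.*")
            tc = timecourse_from_ratio(ratio, s.calibration, s.protocol, p["a"],
                                       params=params, mode=s.mode, strain=strain)
        cs = extract_collapse(tc, onset_delay=onset_delay, window=window,
                              strain=strain)
        merged = cs if merged is None else merged.merged(cs)
    assert merged is not None
    return merged
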