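# Methods

## Model

### Receptor signaling (static MWC model)

Chemoreceptors of *E. coli* cluster into teams of `N` strongly coupled
dimers (mixed Tar/Tsr "complexes") that switch between an active (*on*)
and inactive (*off*) state as one allosteric unit.  The complex
activity is the Boltzmann probability of the on state,

    A = 1 / (1 + exp F),
    F = N [ f(m) + nu_a ln((1 + L/K_off^a)/(1 + L/K_on^a))
                 + nu_s ln((1 + L/K_off^s)/(1 + L/K_on^s)) ]      [kT]

with `L` the MeAsp concentration (mM), `m` the average methylation
level per dimer and `f(m) = fm_intercept + fm_slope·m` the per-dimer
methylation free energy (`fm_slope < 0`: methylation activates).
MeAsp is an attractant, so `K_off < K_on` for both receptor species and
the ligand term raises `F` (lowers activity).  The adapted complex size
grows roughly linearly with the ambient concentration cells are adapted
to, `N(L0) = N0 + c·L0`, and is treated as a continuous positive real.

All constants are configuration (`src/chemomwc/data/reference_params.yaml`),
not code.  The reference values are the ones standard in the MWC
chemotaxis literature: Tar `K_off = 0.02`, `K_on = 0.5` mM; Tsr
`K_off = 100`, `K_on = 1e6` mM; Tar:Tsr = 1:1.4; `f(m) = 1 − 0.5 m` kT;
`N(L0) = 17.5 + 3.35 L0` dimers.

### Adaptation kinetics

Adaptation acts through the methylation level only, with rates that
depend only on activity (the Barkai–Leibler condition for robust
precise adaptation):

    dm/dt = R(A) − B(A).

The model family (registry names in parentheses):

| family | R(A) | B(A) |
|---|---|---|
| cooperative CheB-P feedback (`power-h3`) | g_R (1−A) | g_B A³ |
| linear CheB-P feedback (`power-h2`)      | g_R (1−A) | g_B A² |
| no CheB-P feedback (`power-h1`)          | g_R (1−A) | g_B A  |
| Michaelis–Menten, linear feedback (`mm-feedback`) | g_R (1−A)/(K_R+1−A) | g_B A²/(K_B+A) |
| Michaelis–Menten, no feedback (`mm-nofeedback`)   | g_R (1−A)/(K_R+1−A) | g_B A/(K_B+A) |
| non-phosphorylatable CheB (`cheb-mutant`)         | g_R (1−A) | g_B A |

`g_B` is never free: `solve_gB(g_R, a, spec)` fixes it so the adapted
activity `a` is the steady state (closed form for every family).
Reference rates: `g_R = 0.0069 /s`, which for the headline `power-h3`
model at `a = 1/3` gives `g_B = 18 g_R ≈ 0.124 /s` — demethylation of
active receptors is intrinsically much faster than methylation of
inactive ones, which is the mechanism behind the strong add/remove
asymmetry.  Michaelis constants `K_R = 0.32`, `K_B = 0.30` (activity
units).

Strain presets: WT1 (`a = 1/3`, `power-h3`, 0.2 s sampling), WT2
(`a = 1/2`, `power-h3`, 1 s sampling, reduced CheB expression) and the
CheB-D56E mutant (`a = 1/2`, `cheb-mutant`, 1 s sampling).

### Imprecise adaptation

Large stimuli exhaust the finite pool of methylation sites.  The
imprecise variant multiplies the rates by site-availability
efficiencies

    R *= clip((M_max − m)/m_c, 0, 1),   B *= clip(m/m_c, 0, 1)

i.e. full efficiency while at least `m_c` sites are available and a
linear reduction below.  Defaults `M_max = 4` (a receptor homodimer
carries 8 major sites and only the Tar fraction, about half the
complex, is methylated on MeAsp) and `m_c = 2`.  This choice of form
and constants was made on qualitative grounds and reproduces the three
experimental signatures: progressively lower adapted activity after
progressively larger additions, unchanged adapted activity after
removal back to ambient, and *raised* adapted activity after removal to
buffer (demethylation stalls as occupied sites run out).  A Michaelis
half-saturation form with `M_max = 8·nu_a` was examined first and
rejected: it produces the wrong sign for the buffer signature.
Imprecise simulations start from the imprecise model's own steady state
(root-found in `m`), which is what "adapted to the ambient" means under
that model.

### Ligand flow

Concentration steps in the flow chamber are exponential relaxations
toward the new target, with rate `k_rise` after additions and `k_fall`
after removals (`k = inf` is a perfect step).  Reference calibration:
WT1 `k_rise = 0.35`, `k_fall = 0.45` /s (concentration established over
a few seconds), WT2/mutant scaled by the lower flow speed (0.21,
0.27 /s).  Protocols are event lists; the concentration is continuous
for finite `k` and right-continuous at perfect steps.

### Simulation

The phosphorylation cascade is in quasi-steady state, so FRET activity
is proxied by the algebraic complex activity and the only dynamical
variable is `m`.  The scalar ODE is integrated with LSODA
(`rtol = 1e-9`, `atol = 1e-11`; one state variable makes tight
tolerances free), restarting at protocol events so the solver never
steps over a kink in `dL/dt`.  `N` is fixed per protocol at the
ambient's adapted value; dose–response removal points are therefore
built as separate protocols whose ambient is the stepped-up
concentration, giving them the interpolated complex size.  Halving the
tolerances changes reported response amplitudes by less than 1e-6.

## Data collapse

After a step, at constant `L`, the chain rule gives
`dA/dt = (dA/dm)·(dm/dt) = g(A)` — a function of activity alone (given
`N`).  Every adaptation time course must therefore fall on the one
curve `g(A)`, which has exactly three fixed points (0, `a`, 1), the
interior one attracting.  The extraction mirrors the measurement
processing: non-overlapping 20-point block means, forward difference
quotient between consecutive blocks, and an onset delay discarding the
flow-dominated transient after each event.

Numerical conventions:

- The derivative is paired with the mean of the two block means
  ("mid"), which makes the forward difference second-order accurate;
  the left-endpoint pairing is available as an option.  Tail blocks
  shorter than the window are dropped.
- The default onset delay in `extract_collapse` is 10 s.  The campaign
  analysis (`campaign_collapse`) uses a flow-aware delay,
  `max(10 s, 12/k)`: the Tar off-state affinity (0.02 mM) makes the
  receptor so sensitive near ambient that the decaying concentration
  tail contaminates `dA/dt` for many flow e-foldings; at 12 e-foldings
  the residual is negligible relative to the adaptation signal.  With a
  fixed 10 s delay the fitted `g_R` is biased low by roughly 20%.
- `effective_dm_dt` divides `dA/dt` by `dA/dm = −fm_slope·N·A(1−A)`;
  points with `A(1−A) < 1e-4` are dropped (the division is
  ill-conditioned and the finite-difference estimate itself cannot
  resolve derivatives there).

`fit_gR` exploits that `g_B` is slaved to `g_R` through `a`, so every
model curve is linear in `g_R` and the one-parameter least squares has
a closed form.

## Permutation test

To decide whether two collapse sets (e.g. WT1 vs WT2) differ
significantly and each matches its own model curve, the activity range
shared by both sets is split into `n_pairs = 4` bins; each permutation
swaps one randomly chosen point between the sets in every bin, and the
statistic is the summed squared error of each (swapped) set against its
own model curve.  An unpermuted error below the entire permuted
distribution marks the sets as significantly different.  Default bin
edges are data-driven: bins are grown greedily left-to-right until each
contains at least one point from each set, then merged (narrowest pair
first) down to exactly `n_pairs`, so the test's precondition holds and
every permutation touches every bin.  The RNG is a single-integer-seeded
`numpy` generator.

## Synthetic data

The generator emulates the FRET experiments: a strain preset fixes
`a`, the adaptation model, sampling resolution and flow calibration;
campaigns are added-then-removed steps (WT1: ambient 0.1 mM, steps
0.03, 0.05, 0.1, 0.4, 2 mM; WT2: ambient 0, step 0.1 mM; mutant:
ambient 0, steps 0.05 and 0.1 mM) with 600 s between addition and
removal for re-adaptation.  Single-step strains are repeated (WT2 ×3,
mutant ×2) so their pooled collapse sets populate all comparison bins,
as pooling repeated experiments does in practice.  Gaussian noise of
sd 0.05 is added to the *normalized* activity (matched once to the
visual trace-to-trace scatter of population FRET recordings), and the
series is emitted as a FRET ratio through the inverse measurement
transform.  Ground truth is always returned alongside.

The ratio transform follows from two-channel intensity bookkeeping:
FRET moves intensity from the donor to the acceptor channel scaled by
the fluorescence efficiency ratio `alpha` (0.43), so the pair count is
proportional to `(R − R_sat)/(R + alpha)` and the normalized activity is

    A_norm(R) = (R − R_sat)(R_0 + alpha) / ((R_0 − R_sat)(R + alpha)),

mapping the pre-stimulus ratio `R_0` to 1 and the saturating-attractant
ratio `R_sat` to 0.  A plain linear normalization is available as an
alternative mode.  Ratios beyond the zero-FRET bound (possible once
noise is added) are clamped with a warning.

What the generator does **not** emulate: photon shot noise, slow
baseline drift and photobleaching, cell-to-cell heterogeneity in
expression levels, and run-to-run variability of the flow profile.
Passing recovery tests therefore demonstrate that the analysis pipeline
is consistent and well-conditioned under the model's own assumptions,
not that those assumptions hold for any particular recording.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses five perfect-step courses of 800 s at
0.2 s resolution for the collapse-invariance measurement, 100 noise
seeds for the `g_R` recovery experiment, 1000 seeded runs × 100
permutations for the permutation-test success rate, and 1000 random
receptor states for the derivative oracle — sizes at which the reported
medians and rates are stable to the percent level while the whole
script completes in well under a minute on one CPU.

## Known limitations

- All numeric constants are transcriptions of literature values into
  configuration; analyses at other parameter sets require editing the
  YAML, not the code.
- The imprecise-adaptation site factors are one defensible functional
  form chosen for its qualitative signatures; the data to discriminate
  alternatives (e.g. smooth saturation) are not available here.
- Only complex-average methylation is tracked; per-site bookkeeping,
  assistance neighborhoods and stochastic (Langevin/Gillespie)
  kinetics are out of scope, as are serine stimuli and Tsr minor
  modification sites.
- The joint refit of adaptation rates and complex size against
  dose–response curves is not implemented; `N` and the rate constants
  are fitted/configured separately.
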