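# chemomwc

Dynamic Monod–Wyman–Changeux (MWC) model of chemotaxis signaling in
*Escherichia coli*: receptor-complex activity, methylation/demethylation
adaptation kinetics, flow-chamber stimulus protocols, and the
data-collapse analysis of FRET-like adaptation time courses.

The package is for quantitative biologists who model chemotaxis
signaling or analyze *in vivo* FRET recordings of pathway activity: it
simulates dose–response and step-response experiments, condenses
adaptation time courses into the (A, dA/dt) data collapse, fits and
ranks a family of adaptation models, and tests differences between
data sets with a binned permutation test.  A synthetic-data generator
emulates the FRET experiments end to end, so every pipeline stage is
testable with known ground truth.

## The model

A receptor complex of `N` coupled Tar/Tsr dimers is a two-state
allosteric unit with activity

    A = 1 / (1 + e^F),
    F = N [ f(m) + ν_a ln((1 + L/K_off^a)/(1 + L/K_on^a))
                 + ν_s ln((1 + L/K_off^s)/(1 + L/K_on^s)) ]   (kT)

where `L` is the MeAsp concentration, `m` the average methylation level
per dimer, `f(m)` the linear methylation free energy, and the adapted
complex size grows with ambient concentration, `N(L₀) = N₀ + c·L₀`.
Adaptation closes the loop through the methylation level only:

    dm/dt = g_R (1 − A) − g_B A^h

with `h = 3` for the headline model (CheR methylates inactive
receptors; demethylation requires an active receptor and is sharply
activity-dependent through cooperative CheB-P feedback).  The
demethylation constant is slaved to the adapted activity `a` by the
steady state, `g_B = g_R (1−a)/a^h`.  After a concentration step the
rate of activity change is a function of activity alone,

    dA/dt = (dA/dm)(dm/dt) ≡ g(A),

so all adaptation time courses collapse onto one curve `g(A)` with
fixed points {0, a, 1} — the basis of the analysis.  Michaelis–Menten
("ultrasensitive") variants, a non-regulatable CheB mutant model and an
imprecise-adaptation variant with finite methylation sites are included
(see `docs/methods.md`).

## Worked example

```python
import chemomwc as cm
from chemomwc.simulate import initial_response, halfway_recovery_time
from chemomwc.synth import campaign_collapse
from chemomwc.collapse import fit_gR

params = cm.reference_receptor_params()
a = cm.strain_preset("WT1")["a"]              # adapted activity 1/3
model = cm.get_model("power-h3", a=a)
print(f"g_R = {model.g_R} /s, g_B = {model.g_B:.4f} /s")

# 0.4 mM MeAsp added at t=50 s and removed at t=650 s, 0.1 mM ambient
proto = cm.StepProtocol.add_remove(L_ambient=0.1, delta=0.4, t_add=50,
                                   t_remove=650, k_rise=0.35, k_fall=0.45,
                                   t_end=900)
tc = cm.simulate(proto, params, model, a)
print(f"addition response amplitude:  {initial_response(tc, 50.0):.3f}")
print(f"removal  response amplitude:  {initial_response(tc, 650.0):.3f}")
print(f"halfway recovery: addition {halfway_recovery_time(tc, 50.0, until=650.0):.1f} s, "
      f"removal {halfway_recovery_time(tc, 650.0):.1f} s")

# recover the methylation rate constant from a noisy synthetic campaign
cs = campaign_collapse("WT1", seed=0)
g_hat, resid = fit_gR(cs, a, "power-h3", params)
print(f"fitted g_R from noisy campaign: {g_hat:.5f} /s")
```

prints

```
g_R = 0.0069 /s, g_B = 0.1242 /s
addition response amplitude:  0.998
removal  response amplitude:  1.671
halfway recovery: addition 105.4 s, removal 11.6 s
fitted g_R from noisy campaign: 0.00641 /s
```

The normalized response to the addition is a nearly complete shutdown
of activity (amplitude ≈ 1); the removal overshoot is larger than 1
because activity spikes far above the adapted level.  Recovery after
removal (11.6 s) is an order of magnitude faster than after addition
(105 s): the strong activity-dependence of demethylation makes
adaptation to unfavorable changes ultrafast.  The fitted `g_R` from a
noisy five-step campaign lands within a few percent of the generating
value 0.0069 /s.

The same pipeline is available from the shell:

```
chemomwc synth --strain WT1 --seed 0 --out-dir campaign/
chemomwc collapse --manifest campaign/manifest.csv --out collapse.csv
chemomwc fit --collapse collapse.csv --model power-h3 --a 0.3333333
```

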