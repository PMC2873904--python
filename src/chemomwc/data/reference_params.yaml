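# Reference configuration: static MWC constants, adaptation rate constants,
# flow-chamber calibration and FRET calibration for the three strains.
# Units: concentrations mM, energies kT, time s, complex size dimers.

receptor:
  # Tar:Tsr = 1:1.4, the wild-type ratio of the two MeAsp-binding receptors
  nu_a: 0.4166666666666667
  nu_s: 0.5833333333333333
  # MeAsp dissociation constants (off/on state); attractant: K_off < K_on
  K_off_a: 0.02
  K_on_a: 0.5
  K_off_s: 100.0
  K_on_s: 1.0e+6
  # per-dimer methylation free energy f(m) = 1 - 0.5 m  [kT]
  fm_intercept: 1.0
  fm_slope: -0.5
  # adapted complex size N(L0) = 17.5 + 3.35 L0  [dimers]
  size_intercept: 17.5
  size_slope: 3.35

adaptation:
  # methylation rate constant from the data-collapse fit [methyl groups / s]
  g_R: 0.0069
  # Michaelis constants of the ultrasensitive model family [activity units]
  K_R: 0.32
  K_B: 0.30
  # imprecise adaptation: only Tar receptors methylatable (8 sites per
  # homodimer, about half the complex), efficiency reduced below m_c free sites
  M_max: 4.0
  m_c: 2.0

strains:
  WT1:
    a: 0.3333333333333333   # adapted activity
    model: power-h3
    dt_sample: 0.2          # FRET sampling resolution [s]
    k_rise: 0.35            # flow-chamber exponential rate constants [1/s]
    k_fall: 0.45
    alpha: 0.43             # fluorescence efficiency ratio
  WT2:
    a: 0.5
    model: power-h3
    dt_sample: 1.0
    k_rise: 0.21
    k_fall: 0.27
    alpha: 0.43
  CHEB_MUTANT:
    a: 0.5
    model: cheb-mutant
    dt_sample: 1.0
    k_rise: 0.21
    k_fall: 0.27
    alpha: 0.43

integrator:
  rtol: 1.0e-9
  atol: 1.0e-11
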