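# mblkin

Kinetic analysis of β-lactam hydrolysis by metal-substituted
metallo-β-lactamases (MBLs), built around the chromogenic reporter substrate
nitrocefin.  The package targets the question of whether, and how, swapping
the native Zn(II) cofactor pair for Fe(II) changes the hydrolysis mechanism
of enzymes such as BcII (*Bacillus cereus*) and the clinically relevant
VIM-2: some enzyme–metal combinations show a transient anionic intermediate
absorbing at 665 nm, others do not, and the kinetics decide between a linear
pathway through the intermediate and a branched pathway with a direct
product channel.

It is aimed at enzymologists who work with stopped-flow multiwavelength
absorbance data, plate-reader substrate titrations and inhibitor
dose-response assays, and who want a scriptable, testable replacement for
the usual GUI-driven analysis chain.

## What it computes

**Mass-action schemes.** Nitrocefin (S, λ_max 390 nm) is hydrolysed to a
ring-opened product (P, 485 nm), optionally via an enzyme-bound anionic
intermediate (I, 665 nm):

```
linear:    E + S  <=>[k1][k-1]  ES  ->[k2]  EI  ->[k3]  E + P
branched:  E + S  <=>[k1][k-1]  ES  ->[k2]  E + P      (direct channel)
                                ES  ->[k3]  EI  ->[k4]  E + P
```

Stiff mass-action ODEs (BDF, rtol 1e-8) with exact enzyme and substrate
conservation; units µM, s, cm throughout.

**Trace analysis.** Single-exponential fits A(t) = a·e^(−k·t) + c for the
390/485 nm features; the rise-then-fall double exponential
A(t) = A₁(1−e^(−k_rise·t)) − A₂(1−e^(−k_fall·t)) + c for the transient
665 nm feature; difference spectra and λ_max location.

**Steady state.** Initial-rate extraction (≤10% conversion window) and
nonlinear Michaelis–Menten regression v = V_max·S/(K_m+S), with
k_cat = V_max/[E] and k_cat/K_m with propagated errors.

**Inhibition.** Three-parameter dose-response
a(c) = bottom + (top−bottom)/(1+c/IC₅₀) (Hill slope 1), fitted on
log₁₀ IC₅₀ with delta-method errors, plus IC₅₀ fold changes between enzyme
forms.

**Mechanism discrimination.** Global multiwavelength least-squares fitting
of a candidate scheme to a stopped-flow dataset (log-parameterised rates,
multistart), AICc comparison of linear vs branched fits (the linear scheme
is nested in the branched one), rate-limiting-step attribution and
predicted visibility of the 665 nm intermediate.

**Synthetic data.** Every assay format can be simulated with seeded noise —
stopped-flow photodiode-array matrices (Beer–Lambert forward model,
additive 0.002 AU noise), initial-rate titrations (2-fold dilutions from
400 µM, 2% multiplicative noise) and dose-response curves — so the entire
pipeline is testable without instrument data.

## Worked example

Simulate a di-Fe(II) BcII-like stopped-flow run (branched scheme, 50 µM
enzyme mixed 1:1 with 50 µM nitrocefin) and fit its features:

```python
import mblkin as mk

scheme = mk.build_nitrocefin_scheme("branched")
rates = mk.RateConstantSet({"k1": 1.0, "k-1": 10.0, "k2": 12.0, "k3": 4.0, "k4": 1.4})
chrom = mk.default_chromophores()
ds = mk.simulate_stopped_flow(scheme, rates, chrom, duration=20.0, n_times=400, seed=7)

for wl in (390.0, 485.0):
    fit = mk.fit_single_exponential(mk.extract_wavelength(ds, wl))
    print(f"{wl:.0f} nm  k_obs = {fit.k_obs:.2f} +/- {fit.rate_errors[0]:.2f} s^-1")
fit665 = mk.fit_double_exponential(mk.extract_wavelength(ds, 665.0))
print(f"665 nm  rise = {fit665.k_rise:.1f} s^-1, fall = {fit665.k_fall:.2f} s^-1")
print("rate-limiting step:", mk.rate_limiting_step(scheme, rates))
```

prints

```
390 nm  k_obs = 9.35 +/- 0.10 s^-1
485 nm  k_obs = 3.96 +/- 0.08 s^-1
665 nm  rise = 8.4 s^-1, fall = 1.45 s^-1
rate-limiting step: k4
```

The 390 nm decay tracks substrate consumption, the 485 nm rise product
release, and the 665 nm feature accumulates quickly and decays slowly —
decay of the intermediate (k4 = 1.4 s⁻¹) limits turnover.  Note the
apparent single-exponential rates are observed, not elementary, constants.

The same stages are scriptable from the shell:

```
mblkin simulate --preset bcii-fe-ph7.5 --out run/
mblkin fit-exp run/stopped_flow.csv --out run/
mblkin fit-mechanism run/stopped_flow.csv --out run/
```

`fit-mechanism` fits both schemes and prints the ΔAICc verdict
(distinguishable / indistinguishable) with the rate-limiting step of each.

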