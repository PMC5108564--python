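# Methods

## Reaction schemes and ODE core

Two minimal mass-action networks describe nitrocefin hydrolysis.  Both
share reversible substrate binding E + S ⇌ ES (k1 in µM⁻¹·s⁻¹, k-1 in s⁻¹)
and differ downstream:

* **linear** — ES →(k2) EI →(k3) E + P: every substrate molecule passes
  through the enzyme-bound anionic intermediate, whose decay carries k3;
* **branched** — ES →(k2) E + P in parallel with ES →(k3) EI →(k4) E + P:
  the ES complex partitions between a direct product channel and the
  intermediate channel, whose decay carries k4.

These are the smallest networks consistent with the observed phenomenology
(a product that can appear faster than the 665 nm feature decays) and with
the convention that "intermediate decay" is labelled k3 in the linear and
k4 in the branched pathway.  Product release regenerates free enzyme, so a
1:1 enzyme:substrate mixture still consumes all substrate through multiple
turnovers.  The networks are deliberately restricted to mass action: no
Michaelis–Menten shortcut steps, no cooperativity, no detailed-balance
constraints (the hydrolysis is treated as irreversible).

Internal units are µM, seconds and cm, matching the assay concentrations
and keeping second-order constants near unity.  Integration uses the
implicit BDF method with an analytic Jacobian, rtol 1e-8 and atol 1e-10 µM
by default, because fitted rate sets routinely span three or more orders of
magnitude and the system is stiff.  Two invariants are enforced by
construction and checked in tests: the enzyme-containing and
substrate-derived totals are conserved exactly by every reaction's
stoichiometry, and concentrations never drop below −1e-9 µM (solver
round-off only).

The **rate-limiting step** is reported as the smallest first-order rate
constant among productive path steps (reverse binding excluded) that carry
at least 1% of the substrate flux, with flux split at branch points in
proportion to the competing rate constants.  The flux filter matters when
a fitted branched model drives its direct channel to a negligible rate: a
channel that is never traversed cannot limit turnover, and without the
filter the nested branched fit of effectively linear data would name its
dormant branch instead of the intermediate decay.

## Synthetic data: what is emulated, and what is not

The generators reproduce the statistical structure of three assay formats:

* **Stopped-flow**: 1:1 rapid mixing (pre-mix concentrations halved,
  default 50 µM enzyme + 50 µM nitrocefin post-mix, 5 °C tag), photodiode
  array on a 300–750 nm grid, 100 s acquisitions, additive Gaussian noise
  with σ = 0.002 AU.  Mixing dead time is taken as zero — acquisition
  starts at the post-mix state with no truncated early points.
* **Initial-rate titrations**: 10 substrate concentrations in a two-fold
  serial dilution from 400 µM (reaching 0.78 µM, spanning the stated
  0.4–400 µM working range to within one dilution step), expected rate
  v = k_cat·[E]·S/(K_m+S), multiplicative Gaussian noise of 2%.
* **Dose-response**: 8 log-spaced inhibitor concentrations spanning two
  decades around the true IC₅₀ plus an uninhibited control, expected
  activity from the three-parameter logistic with Hill slope 1, additive
  Gaussian noise of 0.02 on the activity fraction.  The 5 min
  pre-incubation is treated as establishing binding equilibrium; no
  slow-binding kinetics are modelled.

Chromophores are Gaussian bands (σ 40 nm) at the assigned λ_max values —
substrate 390 nm (ε_max 0.0115 µM⁻¹cm⁻¹), ring-opened product 485 nm
(0.0175), anionic intermediate 665 nm (0.030) — with ES and EI carrying the
substrate and intermediate spectra respectively, and a 1 cm path.  Only the
λ_max assignments are anchored in observation; the ε magnitudes and band
shapes are order-of-magnitude-plausible defaults, chosen so that a
mostly-direct branched run shows a 665 nm excursion of ≈0.25 AU.  Every
rate-recovery result is amplitude-agnostic, so these defaults affect
realism of the pictures, not the conclusions.

Not emulated: instrument dead time, baseline drift and lamp flicker
(noise is i.i.d.), wavelength-dependent noise, photobleaching, enzyme
inactivation during the run, temperature or pH as mechanistic variables
(they are metadata tags; pH-dependence enters only through the rate
constants chosen for a given simulation), and substrate depletion effects
in the plate-reader model (rates are drawn from the hyperbola directly).
Passing tests therefore demonstrate correct recovery under clean,
well-specified noise — they do not certify behaviour against correlated
instrument artefacts.

## Fitting stages

**Exponential trace fits** use nonlinear least squares (Levenberg–
Marquardt via lmfit).  The single-exponential form a·e^(−k·t)+c covers
decays (a>0) and rises (a<0); the rate guess comes from the slope of
log|A−A_end| over the first half of the trace, amplitude and offset from
the endpoints — deterministic, no random restarts.  The 665 nm feature
uses the rise-then-fall difference form A₁(1−e^(−k_rise t)) −
A₂(1−e^(−k_fall t)) + c rather than a sum of two decays, because the
feature accumulates before decaying; rates are relabelled post-fit so
k_rise ≥ k_fall.  Non-convergence is data, not an exception: flat traces,
failed optimisations and traces whose fitted signal is below 5× the
estimated noise floor (from the lag-1 difference of the residual series)
come back with `converged=False`, mirroring how unfittable shallow traces
are reported as "not fitted" in practice.  Near-equal rise and fall rates
converge but with standard errors exceeding the estimates
(`well_determined` is False).

**Initial rates** are the OLS slope over the leading window in which the
absorbance excursion stays within 10% of the curve's full observed span
(minimum 3 points), converted to µM/s through ε and path length, and
reported positive for both rising and falling signals.

**Michaelis–Menten regression** fits V_max and K_m directly; k_cat is
V_max/[E] with [E] known from the assay, which mirrors how plate-reader
constants are tabulated.  Fits with K_m outside the substrate grid or with
SE(K_m) > K_m are flagged `poorly_identified`.

**Dose-response** fits parameterise (top, bottom, log₁₀ IC₅₀) with Hill
slope fixed at 1 — the standard three-parameter form.  The IC₅₀ error uses
the delta method, σ_IC50 = ln(10)·IC₅₀·σ_log10IC50.  Curves whose fitted
span (top−bottom) is under 5% of the top plateau are flagged
`no_inhibition`.

**Global mechanism fitting** minimises the joint residual over the 390,
485 and 665 nm traces simultaneously.  Rate constants are log₁₀-
parameterised inside a common box (default 1e-3 to 1e4 in natural units)
and optimised by bounded trust-region least squares from multistart
points drawn log-uniformly with a caller-supplied seed (reproducibility is
a hard contract: same dataset + seed ⇒ identical result).  A trial point
whose integration fails is penalised, not fatal.  During fitting the ODE
tolerances are relaxed to rtol 1e-6 / atol 1e-9 and each start is capped
at 300 residual evaluations; both are configurable.  Standard errors come
from the linearised covariance on the log scale, mapped back by the delta
method.  Chromophore amplitudes are held fixed by default — amplitudes and
ε are confounded, and anchoring the spectra removes the degeneracy; the
recovery targets are rates.

**Model discrimination** compares fits by small-sample AICc,
n·ln(RSS/n) + 2p + 2p(p+1)/(n−p−1), with verdict *indistinguishable* iff
|ΔAICc| < 2.  The linear scheme is the branched scheme's boundary at zero
direct-channel rate, so `discriminate()` fits the linear scheme first and
warm-starts the branched fit from the nested point (direct rate at the
lower bound) alongside its random starts — this guarantees branched RSS ≤
linear RSS up to optimiser tolerance, which is precisely why the verdict
needs an information criterion rather than a raw RSS comparison.
Predicted intermediate **visibility** re-simulates the fitted model and
asks whether the EI contribution at 665 nm exceeds 5× the dataset's noise
σ — an operational version of "an intermediate was (not) observed".

## Choices of study conditions in the test suite

* The AICc indistinguishability bar (|Δ|<2) is demanding at stopped-flow
  data sizes: with ~600 residuals at σ = 0.002 AU, a branched truth with
  even a few percent of direct-channel flux leaves a detectable signature
  and is correctly called distinguishable.  The discrimination demonstration
  therefore uses two regimes: a branched truth whose direct channel carries
  ~0.2% of flux (statistically unresolvable → indistinguishable, with
  intermediate decay rate-limiting under both fitted pathways) and a
  strongly branched truth (~75% direct flux → decisively branched).
* Replicated parameter-recovery studies for the global fit use rate sets
  whose relaxation times are all resolvable on the 0.2 s sampling grid
  (k1 = 0.02 µM⁻¹s⁻¹ … k4 = 0.05 s⁻¹); sub-millisecond binding transients
  are invisible at photodiode-array sampling and would make k1/k-1
  unidentifiable regardless of optimiser quality.  The study runs 25
  seeded replicates at 500 time points over 100 s.
* Grid-search, matrix-exponential, profile-likelihood and
  finite-difference oracles back the regression and integration code at
  small problem sizes; the pseudo-first-order oracle comparisons use
  enzyme excesses of 10⁶–10⁷ because enzyme depletion perturbs the
  closed-form exponent by ~k1·S0·t.

## Known limitations

* Schemes are fixed-topology (linear/branched/custom five-species); the
  package is not a general network builder.
* Chromophore amplitude fitting is not exposed in the global fit; datasets
  whose true ε values differ from the configured map will show amplitude
  misfit that is absorbed nowhere.
* AICc assumes i.i.d. Gaussian residuals; correlated residuals (e.g.
  systematic baseline error) would bias the verdict toward
  "distinguishable".
* The dose-response model fixes the Hill slope at 1; cooperative
  inhibition requires the four-parameter extension.
* Identifiability is data-limited, not flagged automatically: a fit can
  converge with large standard errors on rates whose timescales the
  sampling grid cannot resolve.
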