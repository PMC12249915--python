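# Methods

## Fast-exchange binding model

A guest G and host H forming a 1:1 inclusion complex in fast exchange show
one set of NMR signals with population-averaged parameters.  The averaged
diffusion coefficient of the guest is

    D_obs = (1 − f)·D_free + f·D_complex

with f the bound molar fraction.  Two approximations close the model:

* **D_complex ≈ D_host.**  The host macrocycle dominates the hydrodynamic
  size of the complex, so the complex is assumed to diffuse like the free
  host.  This is the standard working approximation for cyclodextrin
  complexes and makes D_host measurable in the same spectrum.
* **Weighting convention.**  Solving the average for f gives
  `f = (D_free − D_obs)/(D_free − D_host)`, i.e. the bound fraction weights
  the *host/complex* coefficient.  Some write-ups of this method print the
  weights the other way around; only this orientation is consistent with
  f → 1 as D_obs → D_host, and it is the form implemented here.

With the analytical concentrations c_G, c_H the 1:1 equilibrium
K = [GH]/([G][H]) becomes

    K = f / ((c_H − f·c_G)(1 − f))

Given K, the mass balance is a quadratic in f,
`K·c_G·f² − (K(c_G+c_H)+1)·f + K·c_H = 0`; the smaller root is the
physical branch (the larger exceeds min(1, c_H/c_G)).  It is evaluated in
the Citardauq form `2c/(−b+√(b²−4ac))`, which is cancellation-free for
small K·c; the result is verified against the mass-balance residual
(< 1e−10 relative) and, in the tests, against an independent bisection
oracle to 1e−8.

Estimated constants from a single composition are semi-quantitative: the
dominant uncertainty is reading D values off DOSY spectra, which the
Monte-Carlo harness (below) propagates empirically rather than analytically.

### Guard rails

* D_obs must lie in [D_host, D_free].  Fractional overshoot up to 1% of
  the bracket (default, configurable) is clamped to the boundary with a
  warning — DOSY read-off noise regularly produces such excursions; larger
  violations raise, since they indicate mismatched samples.
* If D_free and D_host coincide within tolerance the system is declared
  non-identifiable rather than returning a wild ratio.
* Viscosity comparability across the with-CD and without-CD samples is
  checked on non-binding species (HDO preferred; the free acid with the
  caveat that it may weakly bind the CD).  Default acceptance: 2% relative
  difference, chosen to sit above the sub-1% agreement seen in matched
  samples while still catching genuinely different solvent batches.

### Defaults

* Temperature 298.15 K; D₂O viscosity 1.09e−3 Pa·s (used only by the
  Stokes–Einstein radius helper; the binding analysis itself is
  viscosity-free by construction).
* SI units internally (m²/s, mol/L).  All I/O requires explicit unit
  strings (`"1e-10 m2/s"`, `"1.917mM"`) because this domain habitually
  mixes mM with M and scaled diffusion values; silent magnitude errors are
  the canonical failure mode.

## Acid–base model

Protonation is ideal-solution Henderson–Hasselbalch throughout: activity
coefficients are unity and pKa values are temperature-independent.  A
polyprotic acid with pKa₁ < … < pKaₙ has n+1 microstates; the fraction
with j protons removed is computed from cumulative Ka products in log10
space (normalised with a max-shift, so pKa spans of 10+ units are safe).

pH solves the charge balance
`[H⁺] + c_Na − Kw/[H⁺] − Σᵢ Cᵢ·q̄ᵢ(pH) = 0` by Brent's method on
pH ∈ [0, 14] (Kw = 1e−14).  Strong acids are ordinary registry entries
with a single very negative pKa (HCl −7, tosylic −2.8): at any attainable
pH they are fully dissociated, and one code path handles every acid.

Bicarbonate neutralisation treats CO₂ as escaping completely (open
system), so a dose b of NaHCO₃ is exactly b of inert Na⁺ in the charge
balance; the dose reaching a target pH is found by bracketing + Brent on
the monotone dose–pH map.  The diprotic maleate system shows the expected
buffering plateau near its second pKa (6.1), which is what makes dosing it
to pH 4.5–6 robust to small volume errors.

Computed pH values for concentrated reconstituted samples (ionic strength
well above 0.1 M) should be read as qualitative: measured values in such
matrices reflect activity corrections this model deliberately omits.

Registry pKa values that the underlying study does not state (formic 3.75,
citric 4.8/6.4 upper pair, tosylic −2.8, the drug's basic-group default
7.0) are standard literature values shipped as editable YAML and flagged
as such in the file.

## Formulation arithmetic

* As-is molar mass of a randomly substituted CD lot:
  `(parent + DS·net_substituent)/(1 − water_fraction)`.  For the SBE-β-CD
  lot modelled here (β-CD 1134.98 g/mol, sodium sulfobutyl ether
  +158.15 g/mol per substitution, DS 6.5, 5.7% water) this yields
  2293.7 g/mol, within 0.02% of the lot's declared 2294.1 g/mol — the
  residual is rounding of DS/water in the declaration, which is why
  comparisons against declared values use a 1e−3 relative tolerance.
* Batch masses scale all components to the mole amount of one reference
  component; the arithmetic is homogeneous of degree 1 in the reference
  mass (property-tested).
* Stability series are summarised as consecutive-interval and
  first-to-last percent changes plus the change in summed degradation
  products; interval changes compose multiplicatively to the total.
* t90 = ln(10/9)/k converts first-order rate constants to shelf-life
  figures and back.

Drug and acid molar masses (ceftobiprole 534.6 g/mol from C₂₀H₂₂N₈O₆S₂,
maleic acid 116.07 g/mol) are registry standards; they are validated
indirectly by the batch figures they reproduce (53.5 mg per 0.1 mmol,
23.6 mg of 1:25:4 system per 1 mg of drug).

## Synthetic NMR data

The generator emulates the observables of a 600 MHz solution study
(599.8 MHz ¹H, D₂O, HDO reference at 4.64 ppm):

* **Spectra** are sums of area-normalised Lorentzians (the natural
  solution-state lineshape) on a descending ppm axis.  A carbon-bound
  proton singlet optionally carries a ¹³C satellite doublet at ± J/2 with
  the natural-abundance area (1.1% total, split equally) — formate's
  210 Hz one-bond coupling is the motivating case.  Noise is additive
  Gaussian per point, seeded.
* **Region integration** is trapezoidal with the baseline taken as the
  median intensity of flanking segments (default 0.2 ppm each side), which
  is robust to broad neighbouring tails.
* **DOSY decays** follow plain Stejskal–Tanner attenuation
  I(g) = I₀·exp(−D·γ²g²δ²(Δ−δ/3)).  The default acquisition mirrors the
  study settings: 16 gradients linearly spaced 3–25 G/cm (0.03–0.25 T/m),
  Δ = 200 ms, δ = 2 ms, γ = 2.6752e8 rad s⁻¹ T⁻¹ (maximum b ≈ 3.57e9
  s/m², so a 3e−10 m²/s species decays to ~35% — a well-conditioned
  ladder).  Convection compensation and the spatial non-uniformity of real
  gradient coils are outside the simulation contract: the generator tests
  the analysis chain, not the spectrometer.
* **Fitting** is unweighted nonlinear least squares of (I₀, D) with
  log-linear initialisation; negative noisy intensities are retained (they
  carry information and truncating them biases D).  Standard errors come
  from the fit covariance.
* **End-to-end recovery** composes everything: from a true K the bound
  fraction and hence the true averaged D follow; per replicate, decays for
  free guest, observed guest and host are simulated at a given
  signal-to-noise ratio (σ = I₀/SNR), fitted, and pushed through the
  binding estimators.  Replicate streams derive from one base seed via
  spawned child seeds, so runs are reproducible and replicates
  independent.  At SNR 100 and the dilute-sample conditions, the median
  recovered K over 200 replicates sits within a few percent of truth with
  a ~±30% 95% band — consistent with calling single-composition constants
  semi-quantitative.

What passing these tests shows is that the *analysis chain* is unbiased
and correctly propagates noise of the assumed kind.  Real spectra add
baseline roll, phase error, peak overlap (severe for randomly substituted
CDs, whose multiplets are broadened by the substitution-pattern
distribution), radiation damping of the water line, and gradient
non-uniformity — none of which the generator produces, so real-data
uncertainties will be larger than the synthetic bands.

## Scenario fixtures

`cdformulate.fixtures.make_fixtures` writes the study-condition scenarios
as deterministic plain-text files: the dilute DOSY diffusion table (with
viscosity references), analytical concentrations, the molar-ratio recipes
of every prepared system, reconstitution solubility/pH bookkeeping, and
the solid-state stability series.  Measured solubility and pH entries are
reference data for qualitative comparison, not modelled outputs.  Absolute
degradation-product levels are not available for the maleate series, so
its `sum_dp_percent` column is relative to the initial time point.

## Problem sizes

The test suite's stochastic experiments use 200 replicates for the
Monte-Carlo recovery checks and 1000 randomised compositions for the
solver-vs-bisection comparison; both complete in seconds and give medians
stable to well inside the asserted tolerances.

## Known limitations

* 1:1 stoichiometry only; no multi-site or n:1 models, no slow-exchange
  lineshape analysis.
* Ideal-solution pH; no Debye–Hückel correction, no CO₂ solubility
  equilibrium, no pKa temperature dependence.
* Possible weak binding of the acid itself to the CD is surfaced by the
  viscosity check but not modelled in the equilibrium.
* Degradation kinetics beyond the first-order t90 bookkeeping (pathway
  modelling, humidity uptake) are out of scope.
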