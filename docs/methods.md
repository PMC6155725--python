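# Methods

This note documents the scientific and numerical choices behind
`saxskit`: the models, the estimator, the synthetic-data world the test
suite runs in, and what a passing test does and does not establish.

## Scattering models

**Generalized Guinier–Porod (GGP).** Each compact scatterer follows the
empirical two-branch form

* Guinier-like branch, q ≤ q₁: I(q) = I(0) q⁻ˢ exp(−q²Rg²/(3−s))
* Porod branch, q ≥ q₁: I(q) = D q⁻ᵈ

with crossover q₁ = (1/Rg)√((d−s)(3−s)/2). Both exponents enter with a
negative sign; under this convention s = 0 reduces the low-q branch to
the classical Guinier law, and q₁ is exactly the point where the
Guinier branch's logarithmic slope reaches −d, so requiring value
continuity there also yields slope continuity. The prefactor D is never
a free parameter: it is computed from continuity,
D = I(0) q₁^(d−s) exp(−q₁²Rg²/(3−s)). Validity requires d > s and
s < 3; both are structural constraints, not fitting conveniences.

Useful closed forms used throughout:

* Kratky maximum of the Guinier branch: q* = √((2−s)(3−s)/2)/Rg,
  valid (q* ≤ q₁) whenever d ≥ 2; for spheres q* = √3/Rg.
* Equivalent-sphere diameter: 2R with R² = (5/3)Rg², the uniform-sphere
  relation between geometric radius and radius of gyration.

**Porod shoulder.** Scatterers larger than the observable window
(2π/q_min ≈ 44 nm here) contribute only their power-law tail; they are
modelled as a pure D_s q^(−d_s) term with d_s bounded to (3, 4] by
default (sharp-interface range). Fixing d_s at 4.0 is supported as an
option since a shoulder exponent pinned at its bound carries little
information.

**Correlation-length models.** Debye–Bueche, I = A/(1+ξ²q²)², describes
scattering from long-range density inhomogeneities in gels;
Ornstein–Zernike, I = A/(1+ξ²q²), thermal concentration fluctuations of
chains. Their sum is provided for profiles that need both, with a
comparison rule (below) for deciding whether the extra term is earned.

## Estimator

Fits minimize Σᵢ wᵢ (I_obs,i − I_model,i)² in raw intensity space with
wᵢ = 1/σᵢ² (unit weights when no uncertainty column is present).
Intensity space, not Kratky space, is the objective: the q² weighting of
a Kratky-space fit would distort the error model of counting-type noise.

* Optimizer: `scipy.optimize.least_squares`, trust-region reflective,
  box bounds, 2-point numerical Jacobian, xtol = ftol = 1e-15,
  max 1000 function evaluations. The very tight tolerance is deliberate:
  with the strongly correlated shoulder/dimensionality directions a
  1e-10 tolerance leaves noise-free recoveries one digit short of six
  significant figures.
* Internal parameterization: each GGP component is fitted as
  (I(0), Rg, s, δ) with δ = d − s and δ > 0 as a box bound, so the
  structural constraint d > s holds at every optimizer step — a dynamic
  inequality between two free parameters cannot be expressed as a box
  bound. Reported estimates and errors are in natural (d, s)
  coordinates; the variance of d = s + δ is obtained by full covariance
  propagation including the s–δ covariance. Consequence: the literal
  cap d ≤ 4.5 becomes δ ≤ 4.5; for the near-zero s values of this
  system the difference is immaterial. Fixing d holds δ fixed.
* Default bounds: Rg ∈ [0.1, 50] nm (the upper end is the detectable
  limit of the emulated camera), s ∈ [0, 2.99] (3−s must stay positive —
  enforced by bound, not epsilon fudging), δ ∈ [0.01, 4.5], amplitudes
  positive.
* Uncertainties: standard deviations from the covariance of the
  linearized problem at the optimum, scaled by the reduced chi-square —
  the conventional "nonlinear regression" error bar. Singular
  directions (detected via SVD) report NaN rather than a fabricated
  number. Fixed parameters have no stderr entry.
* Multistart: 5 seeded starts by default; the first is always the
  unperturbed initialization (so a fit started at the truth of a
  noise-free curve is a fixed point), the rest perturb log-scale
  parameters by ~25 %. Lowest cost wins.
* Non-convergence is reported in `FitResult.converged`, never raised.

**Kratky-peak initialization.** Up to two GGP components are seeded
from the smoothed (Savitzky–Golay) Kratky curve by iterative peak
stripping: the most prominent maximum at q_p seeds Rg = √3/q_p and
I(0) = k_p Rg² e/3 (the s = 0 inversion of the peak relations, with
d = 4, s = 0 as neutral starting values); its Kratky contribution is
subtracted and the residual searched for the next maximum, rejecting
candidates within a factor 1.8 in q of an already-seeded peak (flank
artifacts). Stripping matters: when the two forward intensities are
dissimilar the weaker scatterer is a shoulder, not a separate maximum,
and plain peak detection finds only one component. A Porod shoulder
seed takes half of the lowest-q Kratky value; a profile with no peaks
and no shoulder falls back to a flat-background model.

**Model comparison.** Fits of the same data are ranked by reduced
chi-square, ties broken toward fewer free parameters. A more complex
model is "selected" only when it improves reduced chi-square by more
than 5 % (configurable) — the formalization of the judgement that good
Debye–Bueche data do not require an Ornstein–Zernike term.

## Pre-processing conventions

* Canonical q unit is nm⁻¹; an explicit ×10 converter from Å⁻¹ exists
  because silent unit mix-ups are the classic SAXS bug.
* Background grids must match exactly (1e-9 relative) by default;
  linear interpolation is opt-in. Negative post-subtraction intensities
  are retained — the fit is weighted, and clipping would bias it.
  Uncertainties combine in quadrature.
* Replicate averaging: mean intensity; uncertainty of the mean from the
  sample standard deviation / √n when the inputs carry no sigmas, else
  propagated from them. Identical replicates (zero spread) yield no
  sigma column rather than a zero one.
* Pipeline order is subtract-then-average; the two operations commute
  for a shared background, and subtracting first keeps per-replicate
  residual inspection meaningful. Exposed in the CLI manifest.

## Synthetic-data world

The generator emulates a Cu Kα pinhole camera: λ = 0.154 nm,
q = 0.142–2.844 nm⁻¹, 256 linearly spaced points. Composite curves are
built from the published per-concentration parameter table of the
cellulose/ionic-liquid series; one aggregate below 50 mol %, two
aggregates plus a bundle shoulder at 50–80 mol %. Replicates follow the
measurement protocol (3 above 40 mol %, 1 otherwise). Since forward
intensities were not published, the stated amplitude convention is
I(0)_large = 1.0, I(0)_small = 0.5, and a shoulder prefactor chosen so
the shoulder carries 20 % of total intensity at q_min. Default noise is
2 % multiplicative Gaussian — a typical laboratory-source figure;
Poisson counting noise is available. The sigma column always carries
the true per-point standard deviation. The Kapton-like background is a
constant plus a weak low-q power law at ~1 % of the sample's forward
intensity; simulated "measurements" can include it additively so that
downstream subtraction is exercised against a separately measured noisy
background, as in the real workflow.

What the generator does **not** emulate: instrumental smearing,
polydispersity, detector geometry, dark current, or the actual
(unknown) noise statistics of the instrument. A green recovery test
therefore establishes that the estimator inverts its own forward model
under realistic noise — not that it would reproduce the published
numbers from the original raw detector images, which were never
deposited.

## Identifiability and known limitations

* With s free and the shoulder present, the 60 mol % model is weakly
  identified at 2 % noise near the low-q edge: occasionally the global
  minimum of a particular noise realization trades shoulder amplitude
  against a distorted large component (s₁ up to ~0.7, Rg₁ low). Over 20
  seeds the mean recovered Rg₁ is ≈ 5.7 vs the generating 5.9 nm — a
  3–4 % downward bias that is a property of the estimator-plus-noise
  world, well within the published ±0.5 uncertainty, and honestly
  reflected by the large per-fit standard errors on Rg₁. Fixing s or
  d_s removes most of it.
* The small aggregate (Rg ≈ 1.6 nm) is tightly identified throughout.
* The normalization of the small/large intensity ratio is a package
  convention (divide by the series maximum, recorded in the report);
  the published figure's normalization is undefined, so those values
  are not directly comparable.
* Sub-seeds for replicate simulation derive from `SeedSequence`; all
  outputs are bit-for-bit reproducible for a given seed.
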