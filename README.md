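# saxskit

Decomposition of 1-D small-angle X-ray scattering (SAXS) profiles into
generalized Guinier–Porod components, with Kratky analysis,
equivalent-sphere sizing, and Debye–Bueche / Ornstein–Zernike
correlation-length fitting.

## The problem

Laboratory SAXS probes structures of roughly 1–100 nm through the
azimuthally averaged intensity I(q) at low momentum transfer
(here q = 0.142–2.844 nm⁻¹). For semi-dilute and concentrated biopolymer
solutions — the motivating system is cellulose dissolved in an
imidazolium-acetate ionic liquid over a wide concentration series — a
single measured curve superimposes several scatterers: nanoscale
aggregates that show up as peaks in the Kratky plot (q²I vs q), and
much larger fibril bundles whose Guinier rollover lies below the
instrument window and which contribute only a power-law shoulder.
`saxskit` separates these contributions by weighted nonlinear least
squares and turns the fitted radii of gyration into physically
interpretable sizes.

## The model

Each compact scatterer is described by the empirical generalized
Guinier–Porod form

```
I(q) = I(0) · q⁻ˢ · exp(−q²Rg²/(3−s))      for q ≤ q₁
I(q) = D · q⁻ᵈ                              for q ≥ q₁
q₁   = (1/Rg) · √((d−s)(3−s)/2)
```

where Rg is the radius of gyration, d the Porod exponent (≈4 for sharp
interfaces), and s the dimensionality parameter (0 globular, 1 rod,
2 lamella). The crossover q₁ is the unique point where the two branches
match in value and logarithmic slope, which fixes the Porod prefactor
D = I(0)·q₁^(d−s)·exp(−q₁²Rg²/(3−s)). A full profile is modelled as a
sum of up to two such components, an optional pure power law Dₛq^(−dₛ)
for the out-of-window bundle shoulder, and an optional flat background.

Derived quantities:

* equivalent-sphere diameter 2R with R² = (5/3)Rg²,
* Kratky peak position q* = √((2−s)(3−s)/2)/Rg (√3/Rg for spheres),
* forward-intensity ratio I₂(0)/I₁(0) of the small vs large aggregate.

For gel-like profiles without a Kratky peak the package fits
Debye–Bueche I = A/(1+ξ²q²)² (long-range inhomogeneity) and
Ornstein–Zernike I = A/(1+ξ²q²) (chain fluctuations), alone or summed,
with a parsimony-based comparison that flags when the extra term is not
required by the data.

## Worked example

Simulate one noisy measurement of the published 60 mol % two-aggregate
model and refit it blind:

```python
from saxskit import (InstrumentConfig, NoiseModel, simulate_profile,
                     initialize_from_kratky, fit_composite, sphere_diameter)
from saxskit.synthetic import build_concentration_model

model = build_concentration_model(60)                       # Rg 5.9 / 1.6 nm + shoulder
profile = simulate_profile(model, InstrumentConfig(),       # q = 0.142-2.844 1/nm
                           NoiseModel(level=0.02, seed=1))  # 2 % multiplicative noise
init = initialize_from_kratky(profile, n_components=2, include_shoulder=True)
fit = fit_composite(profile, init, seed=1)

for j in (1, 2):
    rg = fit.estimates[f"rg_{j}"]
    print(f"aggregate {j}: Rg = {rg:.2f} +/- {fit.stderr[f'rg_{j}']:.2f} nm, "
          f"d = {fit.estimates[f'd_{j}']:.2f}, "
          f"sphere diameter = {sphere_diameter(rg):.1f} nm")
print(f"reduced chi-square = {fit.chi2_reduced:.2f}")
```

prints

```
aggregate 1: Rg = 5.80 +/- 3.13 nm, d = 3.46, sphere diameter = 15.0 nm
aggregate 2: Rg = 1.63 +/- 0.07 nm, d = 4.02, sphere diameter = 4.2 nm
reduced chi-square = 0.86
```

Aggregate 1 is the large, concentration-dependent entanglement structure
(generating value Rg = 5.9 nm, diameter 15.2 nm); aggregate 2 is the
microfibril-like scatterer (generating Rg = 1.6 nm, diameter 4.1 nm).
The large component carries the broad uncertainty typical for a feature
sitting close to the low-q edge of the window; the small one is tightly
determined. A reduced chi-square near 1 says the fit is consistent with
the injected 2 % noise.

The same workflow is scriptable from the shell:

```sh
saxskit simulate --out-dir sim --seed 1          # synthetic series + manifest
saxskit fit --manifest sim/manifest.yaml --out-dir results
saxskit kratky sim/conc060_rep0.dat kratky60.dat
```

`saxskit fit` writes a per-concentration parameter table (CSV and JSON)
with standard errors, equivalent-sphere diameters, and normalized
intensity ratios.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline numbers from
scratch: the equivalent-sphere diameters implied by the fitted radii of
gyration (closed form), the mean recovered radii from 20 seeded
simulate-and-refit replicates of the 60 mol % composite model, and the
mean recovered Debye–Bueche correlation length from 20 seeded replicates
of a ξ = 4.8 nm curve — all under the stated instrument grid and 2 %
noise. Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
| --- | --- |
| `saxskit.models` | closed-form model functions and analytic helpers |
| `saxskit.profiles` | profile container, .dat I/O, subtraction, averaging, Kratky |
| `saxskit.fitting` | weighted least squares, Kratky initialization, model comparison |
| `saxskit.pipeline` | concentration-series orchestration and report export |
| `saxskit.synthetic` | seeded instrument-realistic profile generator |
| `saxskit.cli` | `saxskit` command with simulate / fit / kratky / report |

See `docs/methods.md` for the modelling assumptions, numerical choices,
and known limitations.
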