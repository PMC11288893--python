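# maturation

Analysis toolkit for studying how liquid protein condensates age into
solid-like states — the "maturation" of droplets formed by liquid–liquid
phase separation (LLPS) of proteins such as FUS.

The package is aimed at biophysicists who combine thermodynamic modelling
with NMR and Raman spectroscopy of droplet samples. It provides:

- **`maturation.thermo`** — a ternary Flory–Huggins model of monomers (1),
  aggregates (2) and solvent (s). The free-energy density

  ```
  f/kBT = (φ₁/v₁) ln φ₁ + (φ₂/v₂) ln φ₂ + (φ_s/v_s) ln φ_s
          + χ₁₂ φ₁φ₂ + (χ₁s φ₁ + χ₂s φ₂) φ_s
  ```

  is minimized subject to the coexistence conditions μ₁ᴵ = μ₁ᴵᴵ,
  μ₂ᴵ = μ₂ᴵᴵ, Πᴵ = Πᴵᴵ (with μᵢ = v_s ∂f/∂φᵢ and
  Π = −f + φ₁ ∂f/∂φ₁ + φ₂ ∂f/∂φ₂ after eliminating φ_s = 1 − φ₁ − φ₂).
  Monomers interconvert with aggregates by first-order kinetics
  dφ̄₁/dt = −k₁φ̄₁ + k₂φ̄₂, solved in closed form, with phase equilibrium
  re-established at every time point (phase separation is fast compared
  with aggregation). An exhaustive grid-search oracle
  (`brute_force_equilibrium`) validates the tie-line solver.
- **`maturation.dosy`** — condensed/dilute protein fractions from
  pulsed-field-gradient (DOSY) decays: the endpoint ratio
  I(g_max)/I(g_min) and a constrained two-component Stejskal–Tanner fit
  (I = Σ Aᵢ exp(−Dᵢ γ²g²δ²(Δ−δ/3)), D_fast/D_slow ≥ 100).
- **`maturation.ssnmr`** — kinetics from time series of 1D CP/INEPT
  spectra: region integration, signal-to-noise, 48-h normalization,
  linear rates in 1/day, and slope-ratio comparison between samples.
- **`maturation.shifts`** — secondary-structure classification of Cα/Cβ
  chemical shifts against per-class Gaussian statistics, and
  back-prediction of DARR/NCA/NCO peak lists from assignment tables.
- **`maturation.raman`** — broadband CARS processing: Kramers–Kronig
  phase retrieval against a nonresonant reference, Savitzky–Golay
  error-phase removal, amide-I mapping, concentric-ring droplet
  segmentation and core-versus-shell spectral comparison.
- **`maturation.synth`** — seeded generators for every input class, each
  returning ground truth for parameter-recovery tests.

## Worked example

Simulate maturation in the two solvent-flux regimes
(`examples/01_maturation_model.py`):

```
$ python examples/01_maturation_model.py
regimeA: chi1s=3.0, chi2s=2.1
  dense-phase solvent fraction: 0.0707 (day 0) -> 0.1619 (day 20)
  dense-phase volume fraction nu: 0.558 -> 0.563
regimeB: chi1s=2.1, chi2s=3.0
  dense-phase solvent fraction: 0.3146 (day 0) -> 0.1076 (day 20)
  dense-phase volume fraction nu: 0.635 -> 0.557
```

In regime A (monomer–solvent contacts more unfavorable than
aggregate–solvent contacts, χ₁s > χ₂s) solvent flows into the droplet as
aggregates accumulate — the droplet interior dilutes, consistent with the
increasing diffusivity of droplet protein seen by DOSY. In regime B the
preference is reversed and the droplet densifies.

The spectroscopy pipelines run the same way
(`examples/02_dosy_fractions.py` … `examples/05_cars_core_shell.py`):

```
$ python examples/05_cars_core_shell.py
droplet: 812 px in 5 rings; shell pixels in border ring: 100%
border - internal difference peaks at 1665 cm^-1 (height 0.0045, FWHM 9 cm^-1)
tyrosine 1618 cm^-1 difference height: 0.0007
strongest core band: 1656 cm^-1 (broad amide I)
```

The border-minus-internal difference spectrum localizes the narrow
1665 cm⁻¹ feature injected into the synthetic shell — the spectral
signature of β-sheet material forming at the droplet surface.

A thin command-line layer mirrors the library:
`maturation simulate|binodal|dosy-fractions|kinetics|classify-shifts|backpredict|raman|generate`
(see `maturation --help`).

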