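# Methods

This note records the models implemented in `maturation`, the choices made
where the underlying methods leave latitude, and what the synthetic-data
tests do and do not demonstrate about real data.

## Ternary phase-separation + aggregation model

The mixture is incompressible with three components — protein monomers
(volume fraction φ₁), protein aggregates (φ₂) and solvent (φ_s = 1−φ₁−φ₂) —
described by the Flory–Huggins free-energy density (kB·T = 1, molecular
volumes vᵢ in units of a reference volume):

f = (φ₁/v₁)ln φ₁ + (φ₂/v₂)ln φ₂ + (φ_s/v_s)ln φ_s + χ₁₂φ₁φ₂ + (χ₁sφ₁ + χ₂sφ₂)φ_s

**Incompressibility.** f is reduced to a function of (φ₁, φ₂) before
differentiation; chemical potentials μᵢ = v_s ∂f/∂φᵢ and the osmotic
pressure Π = −f + φ₁∂f/∂φ₁ + φ₂∂f/∂φ₂ use these reduced partials. Π is
implemented exactly in this form, without sign or constant adjustments,
even though its relation to a conventional osmotic-pressure definition is
a matter of convention.

**Coexistence solving.** The two-phase state has five unknowns
(φ₁ᴵ, φ₂ᴵ, φ₁ᴵᴵ, φ₂ᴵᴵ, ν) closed by five equations: the three equal-potential
conditions plus the two lever-rule constraints placing the average
composition on the tie-line (the binodal alone is a one-parameter tie-line
family; the average selects the member). The system is solved with a
hybrid Powell root finder (step tolerance 1e-13) followed, if the residual
norm exceeds 1e-10, by a Levenberg–Marquardt polish; up to five randomized
restarts are attempted. Accepted solutions must (i) have residual norm
≤ 1e-10, (ii) be distinct phases (‖dense − dilute‖ ≥ 1e-4 — the
identical-phases root always satisfies the equations), and (iii) lower the
total free energy relative to the homogeneous state. If no such solution
exists and the homogeneous Hessian is positive definite, the state is
single-phase. Volume fractions are clamped to [1e-12, 1−1e-12] inside
logarithms during iteration.

**Initialization and continuation.** The first guess lumps both protein
species into an effective binary mixture with composition-weighted χ and
solves the symmetric binary binodal ln(φ/(1−φ)) = χ(2φ−1) by bisection
(exact when χ₁s = χ₂s; a warm start otherwise). Along a maturation
trajectory each time point warm-starts from the previous tie-line. A
coarse grid search (the brute-force oracle at n = 80) is the fallback
start. Edges of the simplex (φ₂ ≈ 0 or φ₁ ≈ 0) are solved by the dedicated
binary routine, dropping the chemical potential of the absent component.

**Brute-force oracle.** `brute_force_equilibrium` grids the dense-phase
composition (n per axis) and the dense volume fraction ν, derives the
dilute composition from mass balance, and minimizes total free energy
exhaustively. It exists to validate the solver (free-energy agreement to
1e-3 kB·T and tie-lines to grid resolution at n = 200), not for production.

**Kinetics.** Monomer↔aggregate interconversion is first-order and
phase-independent, dφ̄₁/dt = −k₁φ̄₁ + k₂φ̄₂, with closed-form solution from
a monomeric initial state; φ̄₁ + φ̄₂ = φ_tot exactly. Phase separation is
treated as instantaneous relative to aggregation, so equilibrium is
re-solved at each time point for the current averages. Time is in days to
match rate constants quoted in d⁻¹. Bundled presets: regime A
(χ₁s = 3 > χ₂s = 2.1, k₁ = 0.2/d, k₂ = 0.1/d, φ_tot = 0.55 — solvent
influx) and regime B (χ₁s = 2.1 < χ₂s = 3, k₁ = 0.1/d, k₂ = 0.05/d —
solvent efflux), plus a φ_tot = 0.8 concentration variant. Trajectories use
41 points over 20 days by default; the sign of dφ_sᴵ/dt tracks the sign of
χ₁s − χ₂s over the full runs.

Out of scope by design: spatial (Cahn–Hilliard) dynamics, droplet-size
distributions, surface tension, nucleation/elongation/fragmentation
extensions, and fitting χ or k to experimental data.

## DOSY phase fractions

Attenuation follows Stejskal–Tanner, I(g) = A exp(−D γ²g²δ²(Δ − δ/3)),
with defaults Δ = 0.05 s (0.1 s selectable), δ = 10 ms, ¹H γ = 2.675×10⁸
rad s⁻¹ T⁻¹. Gradients are stored in absolute T/m; converters accept
percent-of-maximum (the usual acquisition convention, 2–95%) with g_max
supplied in configuration, defaulting to 0.5 T/m. "Zero gradient" is
operationalized as the weakest measured gradient.

The endpoint estimator (condensed = I(g_max)/I(g_min)) is unbiased only
when the fast pool is fully attenuated *and* the slow pool is essentially
intact at g_max; with a diffusivity ratio of exactly 200 these cannot both
hold to better than a few percent, so the estimators agree within 0.02
only at larger contrast (the tests use ratio 2000 for that comparison).
The fit estimator — two-term Stejskal–Tanner least squares with analytic
Jacobian, amplitudes ≥ 0 and D_fast/D_slow ≥ 100 (the physical floor for
condensed-phase protein), initialized from log-linear fits of the decay
head and tail — has no such bias and is preferred. On 200 seeded
replicates at signal-to-noise 100 with 16 gradient points it recovers a
0.60 condensed fraction with |bias| < 0.005 and RMSE < 0.02.

## CP/INEPT kinetics

Spectra are ingested as (ppm, intensity) tables; axes are stored
descending. Region integrals are trapezoidal and sign-preserving. Default
¹³C windows (C′ 165–182, aromatic 105–140, Cα 50–65, Gly Cα 42–48, Cβ
15–40 ppm, plus a ¹H imino window 10–15 ppm) are conventional ranges and
fully configurable — real studies should set windows from their own
spectra. Series are normalized to the measurement nearest a reference time
(48 h, ±1 h tolerance) and fitted by ordinary least squares against time
in days. Slope ratios between samples propagate standard errors to first
order; zero-denominator slopes are flagged rather than divided.

Signal-to-noise has two modes: `standard` (peak height / 2·rms noise) and
`as_printed` (peak height / rms²), the latter provided because some
processing software reports this scale-dependent variant. The default is
`standard`; note that rescaling a spectrum leaves `standard` unchanged and
halves `as_printed` per factor of two.

## Chemical-shift secondary structure

Classification is Bayesian with independent Gaussians per dimension:
posterior ∝ prior × N(Cα; μ, σ) × N(Cβ; μ, σ), omitting unobserved
dimensions; priors default to uniform. The per-(residue, class) means and
standard deviations live in an editable CSV
(`maturation/data/shift_stats.csv`) with values representative of the
published secondary-structure shift surveys for Thr, Ser, Ala, Gly, Tyr
and Gln; users should substitute their preferred statistics table. Under
the bundled values a threonine at Cα 61.2 / Cβ 72.3 ppm is classified
β-sheet (posterior 0.83). The Cβ-band classifier minimizes |Cβ − μ|/σ and
reports all z-scores; ties break helix < sheet < coil with a flag. Note
that with unequal class σ the nearest-z call can differ from the density
argmax near crossovers — the density comparison is exactly equivalent only
for a common σ.

Back-prediction: NCA pairs N(i)–Cα(i); NCO pairs N(i)–C′(i−1); DARR at
short mixing (≈20 ms) predicts intra-residue carbon–carbon pairs at both
symmetric positions, and an option adds sequential Cα–Cα/C′–Cα pairs above
50 ms. Rows with missing atoms are skipped and counted; output order is
deterministic (sorted), so row order does not matter.

## BCARS processing

Raw CARS intensity is |χ_NR + χ_R|². Dividing by the nonresonant reference
and writing √(I/I_NR)·e^{iφ} = 1 + χ_R/χ_NR, the phase is the Hilbert
transform of ½ln(I/I_NR). The transform is applied with mirror-image edge
padding; the sign convention is fixed so that an isolated resonance
appears as a positive peak at its true position with height ≈ Im χ_R/χ_NR
(verified against synthetic Lorentzians). The slowly varying error phase
is estimated with a Savitzky–Golay smoother (second order, 400 cm⁻¹
window converted to the nearest odd sample count) and subtracted; a
second-order filter passes quadratic phase backgrounds exactly. Because
the smoother treats any feature broad relative to its window as
background, linewidth fidelity is assessed on the raw retrieval (centers
within one bin, widths within 10% for lines of half-width 6–25 cm⁻¹ on a
3 cm⁻¹ grid, amplitudes ≲ 0.1·χ_NR); very broad or very strong lines incur
interference distortion from the real part of χ.

Droplets are segmented by Otsu threshold on the amide-I (1600–1700 cm⁻¹)
integral map, keeping the largest connected component; a manual mask
override is supported. Rings are equal-width annuli of the pixel radius
from the centroid (equal-area rings were the plausible alternative;
equal-width was chosen for geometric transparency), default n = 5, the
outermost ring being the "border". Ring comparison normalizes spectra by
fingerprint-band (900–1800 cm⁻¹) area by default (max-normalization
selectable; the choice scales heights but cannot move peak centers) and
reports the border-minus-internal difference with marker-band metrics at
1618 cm⁻¹ (tyrosine hydrogen-bonding) and 1665 cm⁻¹ (narrow β-sheet
feature).

## Synthetic data: what it emulates, what it does not

All generators draw from a single seeded NumPy generator per dataset and
echo their parameters as ground truth sufficient to predict estimator
outputs.

- **CP/INEPT series**: Lorentzian multiplets in the default regions; CP
  amplitudes grow linearly at 0.25/day from an intercept of half the 48-h
  level (solid material is present within hours of droplet formation);
  INEPT decays at −0.06/day. Noise is additive Gaussian plus 10%
  multiplicative slot-to-slot scatter, mirroring the intensity
  uncertainty between interleaved measurement slots. Not emulated:
  lineshape changes, chemical-shift drift, baseline artefacts.
- **DOSY**: two Stejskal–Tanner components, condensed fraction 0.6,
  D_fast = 1e-10 m²/s, ratio 200 (floor 100), 16 gradients spanning
  2–95% of g_max, Gaussian noise at SNR 100. Not emulated: convection,
  peak overlap in the spectral dimension.
- **CARS cubes**: a disk droplet (radius 16 px) on a nonresonant
  agarose-like background; core spectra carry a broad 1655 cm⁻¹ amide-I
  band and a 1618 cm⁻¹ tyrosine line; the shell (outer 15% of the
  radius) adds a narrow 1665 cm⁻¹ line and extra 1618 intensity.
  Optional Poisson + Gaussian noise. Not emulated: non-circular droplets,
  focus drift, multi-droplet fields.
- **Shift observations**: Gaussian Cα/Cβ samples per class from the
  statistics table.

Passing recovery tests on these generators demonstrates estimator
correctness and calibration under the stated noise models — not
robustness to the artefacts listed as non-emulated, which real data will
contain.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in minutes on a single CPU: oracle comparisons use 10 random parameter
draws against a 200-per-axis grid; recovery ensembles use 200 (DOSY) and
100 (CP slope) seeded replicates; CARS cubes are 48×48×301. These sizes
give Monte-Carlo standard errors comfortably below the tolerances they are
tested against.
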