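# Methods

## Scope and model

The package analyses reduced, absolute-scale 1-D SANS spectra I(q) of
lyotropic lamellar phases. The lineshape model is the sum of a diffuse
and a structured contribution,

    I(q) = A_z / (1 + q² ξ_p²) + A_B / (1 + (q − q₀)² ξ_l²) + b,

two Lorentzians carrying exactly five physical parameters: diffuse
amplitude A_z (cm⁻¹) and in-plane concentration-fluctuation correlation
length ξ_p (Å); Bragg amplitude A_B (cm⁻¹), interlamellar correlation
length ξ_l (Å) and first-order peak position q₀ (Å⁻¹). The additive
constant b (default 0, freed on request) represents incoherent
background present in real reduced data; with b = 0 the bare
five-parameter model is recovered. The model is intended for dilute and
moderately concentrated stacks where a single first-order reflection
dominates; a second-order reflection (charged or polymer-bridged stacks)
is handled in the generator as an optional extra Lorentzian at 2q₀, and
in analysis by restricting the fit window if desired.

Elasticity is treated at the level of the standard smectic relations:

- Helfrich undulation repulsion per unit area
  V(d̄) = 3π²(k_BT)²/(128 κ d̄²), with d̄ = d − δ the water gap;
- Caillé parameter η = q₀² k_BT / (8π √(B̄ K)) with K = κ/d;
- undulation compression modulus B̄ = d·∂²V/∂d̄² = 9π²(k_BT)² d/(64 κ d̄⁴);
- salt-free electrostatic compression modulus B̄ = π k_BT d/(l_B d̄³),
  l_B the Bjerrum length (7 Å in water).

These forms close algebraically: inserting the undulation B̄ into the
moduli form of η returns the pure-geometry Helfrich limit
η = (4/3)(d̄/d)² = m π² (d̄/d)², m = 4/(3π²), exactly. Under the ideal
swelling law d = δ/ϕ this is (4/3)(1 − ϕ)², which reproduces the
published Caillé values of the neutral TX100/TX35 series (1.20, 1.08,
0.85, 0.65 at ϕ = 5–30%) at printed precision. The electrostatic
modulus is exposed for trend analysis only; its absolute scale depends
on the Gouy–Chapman prefactor convention, so tests assert scaling and
monotonicity, not published numbers.

The dilute-membrane form factor uses the Kratky–Porod representation

    I(q) = 2π ϕ Δρ² δ / q² · exp(−q²δ²/12),

which is exactly log-linear in q² with slope −δ²/12 — the property the
thickness estimator relies on. The exponential form is quantitatively
valid for qδ ≲ 2; the exact flat-sheet factor sinc²(qδ/2) is available
(`form="sheet"`) for work outside that window. Defaults Δρ = 6×10¹⁰
cm⁻², V_A = 3×10⁻⁷ cm³ are the constants of the TX100/TX35/water
system; V_A is carried as metadata and does not enter the thin-sheet
expression.

Units: q in Å⁻¹, lengths in Å, intensities in cm⁻¹, energies in J,
moduli in Pa; k_B = 1.380649×10⁻²³ J/K, default T = 293.15 K (samples
equilibrated at 20 °C). All elastic functions convert to SI internally,
so outputs are invariant under a consistent change of input length
units.

## Estimation

**Lineshape fit.** Bounded nonlinear least squares
(scipy `least_squares`, TRF) on the five parameters (plus optional
background), weights 1/σ² when uncertainties are present, unweighted
otherwise. Multi-start: the starting point is jittered multiplicatively
(±20% by default) over 5 restarts with a seeded generator; the lowest
cost wins. When no starting point is given, a heuristic builds one: q₀
from the most prominent peak of q²I (Bragg term frozen at zero if none),
ξ_l from 2/FWHM of that peak, A_z and ξ_p from a linearised Lorentzian
fit to the lowest decade of q, background from the median of the top 10%
of q. Parameter uncertainties come from the SVD-based covariance of the
weighted Jacobian scaled by reduced χ²; directions in the numerical null
space of the Jacobian are reported as not-determined (`N.D.` in
reports) — the situation of very dilute stacks whose Bragg term
degenerates to a constant (ξ_l → 0), where ξ_l and q₀ carry no
information.

**Peak detection.** Candidate maxima of the Porod representation q²I
are accepted when their prominence exceeds 3× the robust local
fluctuation scale (MAD of q²I about its 15-point running median); the
reported position is refined to the local intensity maximum near the
accepted candidate, because the q² weighting skews the apex of a
resolution-broadened peak upward on a log grid. Monotone curves yield
no peak; absence is a result, not an error.

**Thickness.** Ordinary least squares of ln(q²I/ϕ) on q² inside a
user-chosen window; δ = √(−12·slope), with the error propagated from
the slope standard error (dδ = 6·d(slope)/δ). A non-negative slope
raises a dedicated error (wrong window or non-lamellar signal). The
published windows for the dilute neutral samples (0.063–0.138 Å⁻¹ at
ϕ = 5%, 0.055–0.141 Å⁻¹ at ϕ = 10%) are shipped as constants.

**Swelling law.** Through-origin least squares of d on 1/ϕ — the law
d = δ/ϕ has no intercept; a free-intercept variant exists for
diagnostics. A single point is accepted (exact one-point slope, zero
error); the standard error uses n − 1 degrees of freedom. On the
published charged-series Bragg positions the through-origin fit gives
δ = 30.6 ± 0.7 Å, consistent with the published 30 ± 1 Å.

**High-q overlap.** Curves in the q²I/ϕ representation are compared
above a q threshold by the median of |a − b|/min(a, b) on the merged
grid of their common support — symmetric, zero for identical curves,
c − 1 for a constant ratio c.

## Synthetic data

The generator emulates a three-configuration pinhole SANS measurement:
200 log-spaced points on q ∈ [0.002, 0.4] Å⁻¹ and Gaussian q-resolution
with widths 1×10⁻³, 2.8×10⁻³ and 5×10⁻³ Å⁻¹ assigned to the low/mid/high
thirds of the grid. The width is interpolated in log q between the
region centres rather than stepped: a discontinuous σ(q) across a Bragg
peak spreads its intensity asymmetrically and violates intensity
conservation (the smeared ∫q²I dq is conserved within 0.5% for in-range
peaks with the smooth map). Smearing is evaluated by 21-node
Gauss–Hermite quadrature of the model under the Gaussian kernel, with
the kernel reflected about q = 0; zero width returns the model exactly.
A metadata flag warns when the resolution width at the peak exceeds one
fifth of the peak width 1/ξ_l.

Noise is multiplicative Gaussian (default 2%, a typical reduced-data
level) plus an optional additive floor, with σ reported per point;
reduced absolute-scale curves no longer carry raw counts, so Poisson
statistics are not simulated. All generators are pure functions of
(parameters, seed).

Dilution series place each Bragg peak at q₀ = 2πϕ/δ. Defaults emulate
the studied system: Ω = 1.26, T = 293.15 K, ϕ ∈ {5, 10, 20, 30}%, and
the published per-ϕ lineshape rows (neutral, charged Γ = 1%, polymer
Ψ = 10%) shipped in `lamsans.reference` as generator inputs and
round-trip ground truth.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: 2-D detector effects (beamstop,
transmission, anisotropy), q-dependent backgrounds, multiple scattering,
concentration-dependent deviations from ideal swelling, and the true
(unpublished) per-q resolution function. Round-trip recovery on
synthetic curves demonstrates estimator correctness, not instrument
modelling fidelity.

## Numerical choices and edge cases

- Optimiser tolerances 1e-14 (xtol/ftol/gtol) with per-parameter
  `x_scale` from the starting point; bounds are non-negativity for all
  parameters and q₀ ≤ 2·q_max.
- A flat curve fits to A_z = A_B = 0 with the background carrying the
  level (the heuristic initialises A_z at the background-subtracted low-q
  level, which is zero there, and the optimiser has no incentive to
  move it).
- Fits are equivariant under intensity rescaling: scaling I and σ by c
  scales amplitudes and background by c and leaves lengths and q₀
  unchanged.
- The thickness estimator requires ≥ 3 points and strictly positive
  intensity in the window; the lineshape fit requires ≥ 10 points; peak
  detection requires ≥ 20.
- Curve readers sort unsorted q (logged), clip negative intensities to
  zero (logged), reject duplicate q, and convert nm⁻¹ input.
- Reports are deterministic given (inputs, seed); per-sample failures in
  the pipeline are isolated into failed rows.

## Design decisions

- The two-Lorentzian lineshape is the implemented reading of the
  structured-plus-diffuse decomposition: it carries exactly the five
  described parameters and reproduces all published parameter rows in
  round-trip. More elaborate smectic structure factors (Caillé power-law
  tails, finite stack size) are out of scope.
- The Caillé/Helfrich/compression relations were chosen so the three
  forms are mutually consistent (the closure above), rather than mixing
  prefactor conventions from different sources; property tests assert
  only relations that survive any consistent prefactor choice.
- ϕ is the membrane volume fraction throughout: the swelling law
  d = δ/ϕ and the ideal-dilution Caillé values require it.
- The published neutral-series q₀ at ϕ = 10% (0.1187 Å⁻¹) is
  inconsistent with the swelling law and with the absence of a peak at
  that dilution; it is kept verbatim in the reference table (it is a
  perfectly identifiable fit problem) but not used for any structural
  inference.
- Round-trip validation uses unsmeared synthetic curves: fitting the
  unsmeared lineshape to smeared data biases ξ_l low by construction
  (that bias is itself asserted as a smearing property), so resolution
  effects are tested separately from estimator correctness.
- Problem sizes follow the study conditions: 200-point curves,
  four-sample dilution series, 20-seed Monte-Carlo repeats for coverage
  checks and 50 seeds for the thickness-bias check.

## Known limitations

- The fitted model is unsmeared; analysing strongly smeared data
  without accounting for resolution underestimates ξ_l (by ~15% for the
  narrowest published peaks on this instrument emulation). Desmearing
  or fitting the smeared model is future work.
- The electrostatic compression modulus is prefactor-convention
  dependent and untested against absolute published values.
- The compression-modulus column of the published elasticity table
  cannot be reproduced: the bending modulus used there is not stated.
  The neutral-series swelling thickness (≈35 Å) is likewise not
  independently reproducible, because the dilute-sample repeat
  distances entering it are themselves constructed from the swelling
  law. Both are covered by property tests (finite-difference oracle for
  B̄, monotone η/B̄ trends, scaling laws) instead of value checks.
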