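# lamsans

Analysis of small-angle neutron scattering (SANS) from lyotropic lamellar
phases — stacks of surfactant bilayers separated by solvent layers, the
simplest smectic and a standard model for biological membranes and
drug-delivery vehicles. The package targets systems such as the
TX100/TX35/water lamellar phase, neat or doped with a charged surfactant
or a telechelic (end-anchored) polymer, and answers the questions a
scattering experiment on such a system poses: is the stack ordered, how
far apart are the membranes, how thick is the bilayer, and how stiff is
the stack?

## The model

A reduced, absolute-scale spectrum I(q) (cm⁻¹, q in Å⁻¹) is described as
the sum of two contributions,

    I(q) = A_z / (1 + q² ξ_p²)  +  A_B / (1 + (q − q₀)² ξ_l²)  [+ b],

a diffuse Lorentzian from in-plane surfactant concentration fluctuations
(amplitude A_z, correlation length ξ_p) and a Bragg term from the
periodic stacking (amplitude A_B, interlamellar correlation length ξ_l,
peak position q₀), plus an optional constant incoherent background b.
Around the fit, the package derives the standard structural and elastic
quantities:

- repeat distance `d = 2π/q₀` (Bragg condition) and the ideal swelling
  law `d = δ/ϕ`, whose slope over a dilution series is the dry bilayer
  thickness δ;
- bilayer thickness from the Kratky–Porod regression: the slope of
  ln(q²I/ϕ) vs q² is −δ²/12 for a thin sheet;
- Helfrich undulation repulsion `V(d̄) = 3π²(k_BT)²/(128 κ d̄²)` between
  bilayers confined to a water gap d̄ = d − δ, with κ the bending
  modulus;
- Caillé parameter `η = q₀² k_BT / (8π √(B̄ κ/d))`, which in the
  Helfrich-dominated limit reduces to the pure-geometry form
  `η = (4/3)(1 − δ/d)² = (4/3)(1 − ϕ)²` under ideal swelling;
- layer compression moduli B̄ for undulation-stabilised
  (∝ d/d̄⁴) and salt-free electrostatically stabilised (∝ d/d̄³) stacks.

A synthetic-data module generates resolution-smeared, noisy curves and
ideal dilution series with the statistical structure the analysis
assumes (three-configuration pinhole instrument, q ∈ [0.002, 0.4] Å⁻¹,
Gaussian resolution widths 1×10⁻³/2.8×10⁻³/5×10⁻³ Å⁻¹, multiplicative
counting noise), so every estimator can be validated end to end.

## Worked example

Fit a synthetic charged-series sample at membrane volume fraction
ϕ = 20% (2% noise, seeded):

```python
import lamsans as ls
from lamsans.reference import CHARGED_SERIES

curve = ls.generate_nallet_curve(
    CHARGED_SERIES[0.20], noise=ls.NoiseModel(relative_level=0.02, seed=1),
    label="charged phi=20%")

result = ls.fit_nallet(curve, random_state=1)
p, u = result.parameters, result.uncertainties
for name, v, e in zip(("A_z", "xi_p", "A_B", "xi_l", "q0"),
                      (p.A_z, p.xi_p, p.A_B, p.xi_l, p.q0), u):
    print(f"{name:>5s} = {v:10.4g} +/- {e:.2g}")
d = ls.bragg_spacing(p.q0)
print(f"repeat distance d = {d:.1f} A")
geom = ls.MembraneGeometry(delta=30.0, d=d)
print(f"Caille parameter eta = {ls.caille_helfrich(geom):.3f}")
```

prints

```
  A_z =      21.06 +/- 0.1
 xi_p =      30.49 +/- 0.12
  A_B =        110 +/- 1.2
 xi_l =      141.9 +/- 1.3
   q0 =    0.04129 +/- 5.1e-05
repeat distance d = 152.2 A
Caille parameter eta = 0.859
```

The Bragg position lands on the generating value (q₀ = 0.0413 Å⁻¹, so
d ≈ 152 Å, an ordered stack), while the fitted ξ_l (141.9 Å) sits below
the generating 162.5 Å: instrument resolution broadens the peak, and the
fitted correlation length absorbs that broadening. η ≈ 0.86 says thermal
undulations are moderate — a well-ordered lamellar phase. A curve with no
detectable peak instead collapses onto the diffuse term, and parameters
the data cannot constrain are reported as `N.D.`.

The same pipeline is available from the shell:

```sh
lamsans simulate --delta 30 --phis 0.05,0.1,0.2,0.3 --out series/
lamsans fit series/phi0200.dat
lamsans swelling 0.05:598.4 0.1:332.4 0.2:152.1 0.3:102.7
```

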