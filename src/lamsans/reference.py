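"""Published Nallet-model parameter sets for the TX100/TX35/water system.

Fitted five-parameter rows for three dilution series of the lamellar
phase at co-surfactant ratio Ω = 1.26: the neutral series, the charged
series (Γ = 1% cetylpyridinium chloride) and the telechelic-polymer
series (Ψ = 10% PEO-2m).  Keys are membrane volume fractions ϕ.  These
rows serve as generator inputs for synthetic curves and as ground truth
for round-trip identifiability checks.

Two rows (neutral ϕ = 0.05 and polymer ϕ = 0.05) carry an interlamellar
correlation length of essentially zero (1e-7 Å scale): their Bragg term
is a constant over any finite q range, so ``xi_l`` and ``q0`` are not
identifiable from a curve — the fitter reports their uncertainty as
not-determined.  ``IDENTIFIABLE`` lists the (series, ϕ) pairs whose five
parameters are all recoverable from data.
"""

from __future__ import annotations

from .datatypes import NalletParameters

__all__ = [
    "NEUTRAL_SERIES",
    "CHARGED_SERIES",
    "POLYMER_SERIES",
    "SERIES",
    "IDENTIFIABLE",
    "CHARGED_DRY_THICKNESS",
    "CAILLE_HELFRICH_TABLE",
    "KRATKY_WINDOWS",
]

NEUTRAL_SERIES = {
    0.05: NalletParameters(A_z=14531.6, xi_p=1033.03, A_B=11.31, xi_l=2.43e-7, q0=0.0091),
    0.10: NalletParameters(A_z=2114.0, xi_p=337.43, A_B=72.32, xi_l=79.48, q0=0.1187),
    0.20: NalletParameters(A_z=760.77, xi_p=245.61, A_B=50.51, xi_l=98.01, q0=0.04087),
    0.30: NalletParameters(A_z=493.14, xi_p=181.59, A_B=62.55, xi_l=109.53, q0=0.06207),
}

CHARGED_SERIES = {
    0.05: NalletParameters(A_z=102.15, xi_p=55.37, A_B=546.33, xi_l=628.84, q0=0.0105),
    0.10: NalletParameters(A_z=44.05, xi_p=23.50, A_B=326.93, xi_l=381.38, q0=0.0189),
    0.20: NalletParameters(A_z=21.76, xi_p=29.99, A_B=122.82, xi_l=162.48, q0=0.0413),
    0.30: NalletParameters(A_z=22.58, xi_p=35.27, A_B=72.31, xi_l=133.66, q0=0.0612),
}

POLYMER_SERIES = {
    0.05: NalletParameters(A_z=722.82, xi_p=161.06, A_B=3.44, xi_l=3.92e-9, q0=0.01378),
    0.10: NalletParameters(A_z=1123.0, xi_p=305.50, A_B=172.63, xi_l=201.04, q0=0.02165),
    0.20: NalletParameters(A_z=21.76, xi_p=29.99, A_B=144.75, xi_l=226.81, q0=0.04132),
}

SERIES = {
    "neutral": NEUTRAL_SERIES,
    "charged": CHARGED_SERIES,
    "polymer": POLYMER_SERIES,
}

#: (series, phi) rows whose Bragg lineshape is resolvable, i.e. all five
#: model parameters are identifiable from a curve on q ∈ [0.002, 0.4] Å⁻¹.
IDENTIFIABLE = [
    ("neutral", 0.10), ("neutral", 0.20), ("neutral", 0.30),
    ("charged", 0.05), ("charged", 0.10), ("charged", 0.20), ("charged", 0.30),
    ("polymer", 0.10), ("polymer", 0.20),
]

#: Dry bilayer thickness (Å) of the charged series from the swelling-law
#: fit of the Bragg-derived repeat distances (reported as 30 ± 1 Å).
CHARGED_DRY_THICKNESS = 30.0

#: Helfrich-limit Caillé parameter vs membrane volume fraction for the
#: neutral series under ideal swelling (printed to two decimals).
CAILLE_HELFRICH_TABLE = {0.05: 1.20, 0.10: 1.08, 0.20: 0.85, 0.30: 0.65}

#: q windows (Å⁻¹) used for the ln(q²I) vs q² thickness regression of the
#: dilute neutral samples.
KRATKY_WINDOWS = {0.05: (0.063, 0.138), 0.10: (0.055, 0.141)}
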