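"""Closed-form physics of dilute lamellar stacks.

Intensity models (Nallet two-Lorentzian lineshape, dilute thin-sheet form
factor), smectic elasticity (Helfrich undulation repulsion, Caillé
parameter, compression moduli) and lamellar geometry (Bragg condition,
ideal swelling law) as pure, unit-checked functions.

Unit conventions: q in Å⁻¹, lengths in Å, intensities in cm⁻¹, energies in
J, moduli in Pa, temperatures in K.  Functions convert to SI internally so
every elastic output is invariant under a consistent change of input
length units.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy import constants

from .datatypes import (
    DEFAULT_BJERRUM,
    ElasticState,
    MembraneGeometry,
    NalletParameters,
    SlabModel,
    _require,
)

__all__ = [
    "K_B",
    "DEFAULT_TEMPERATURE",
    "CAILLE_HELFRICH_M",
    "nallet_intensity",
    "slab_intensity",
    "helfrich_potential",
    "caille_helfrich",
    "caille_from_moduli",
    "electrostatic_compression_modulus",
    "helfrich_compression_modulus",
    "swelling_d",
    "bragg_spacing",
]

#: Boltzmann constant (J/K).
K_B = constants.Boltzmann

#: Default sample temperature (K): samples equilibrated at 20 °C.
DEFAULT_TEMPERATURE = 293.15

#: Prefactor m = 4/(3π²) of the Helfrich-limit Caillé parameter,
#: η = m π² (d̄/d)².
CAILLE_HELFRICH_M = 4.0 / (3.0 * np.pi**2)

_M_PER_A = 1.0e-10  # metres per Å

ArrayLike = Union[float, np.ndarray]


# ---------------------------------------------------------------------------
# intensity models
# ---------------------------------------------------------------------------

def nallet_intensity(q: ArrayLike, params: NalletParameters) -> ArrayLike:
    """Lamellar-phase scattered intensity I(q) (cm⁻¹).

    Sum of two contributions: diffuse small-angle scattering from in-plane
    surfactant concentration fluctuations, a zero-centred Lorentzian of
    amplitude ``A_z`` and correlation length ``xi_p``; and structured Bragg
    scattering from the periodic stacking, a Lorentzian of amplitude
    ``A_B`` and interlamellar correlation length ``xi_l`` centred on the
    Bragg position ``q0``; plus a constant incoherent ``background``.

    Parameters
    ----------
    q : float or ndarray
        Scattering vector (Å⁻¹), ≥ 0.
    params : NalletParameters

    Returns
    -------
    float or ndarray
        Intensity in cm⁻¹, everywhere ≥ ``params.background``.
    """
    q = np.asarray(q, dtype=float)
    _require(np.all(np.isfinite(q)) and np.all(q >= 0.0), "q must be finite and non-negative")
    if not isinstance(params, NalletParameters):
        raise TypeError("params must be a NalletParameters instance")
    diffuse = params.A_z / (1.0 + (q * params.xi_p) ** 2)
    bragg = params.A_B / (1.0 + ((q - params.q0) * params.xi_l) ** 2)
    out = diffuse + bragg + params.background
    return out if out.ndim else float(out)


def slab_intensity(q: ArrayLike, model: SlabModel, form: str = "guinier") -> ArrayLike:
    """Dilute thin-sheet (homogeneous membrane) intensity I(q) (cm⁻¹).

    For randomly oriented, weakly interacting bilayers of thickness δ at
    membrane volume fraction ϕ and contrast Δρ,

        I(q) = 2π ϕ Δρ² δ / q² · S(qδ),

    with the thickness factor ``S`` either the Kratky–Porod/Guinier form
    ``exp(−q²δ²/12)`` (default, log-linear in q² with slope exactly
    −δ²/12) or the exact flat-sheet form ``sinc²(qδ/2)``
    (``form="sheet"``).  The Guinier representation is quantitatively
    valid for qδ ≲ 2; beyond that it remains the conventional linearising
    representation used for thickness regression.  Intensity is linear in
    ϕ and in Δρ².

    Parameters
    ----------
    q : float or ndarray
        Scattering vector (Å⁻¹), > 0.
    model : SlabModel
    form : {"guinier", "sheet"}
    """
    q = np.asarray(q, dtype=float)
    _require(np.all(np.isfinite(q)) and np.all(q > 0.0), "q must be finite and positive")
    if not isinstance(model, SlabModel):
        raise TypeError("model must be a SlabModel instance")
    q_cm = q * 1.0e8            # Å⁻¹ → cm⁻¹
    delta_cm = model.delta * 1.0e-8
    prefactor = 2.0 * np.pi * model.phi * model.drho**2 * delta_cm / q_cm**2
    x = q * model.delta         # dimensionless qδ
    if form == "guinier":
        shape = np.exp(-(x**2) / 12.0)
    elif form == "sheet":
        half = x / 2.0
        shape = np.where(half == 0.0, 1.0, (np.sin(half) / np.where(half == 0.0, 1.0, half)) ** 2)
    else:
        raise ValueError(f"unknown form {form!r}; use 'guinier' or 'sheet'")
    out = prefactor * shape
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# elasticity
# ---------------------------------------------------------------------------

def helfrich_potential(geometry: MembraneGeometry, kappa: float,
                       temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Helfrich undulation repulsion per unit area (J·m⁻²).

    Entropic repulsion between adjacent fluctuating bilayers confined to a
    water gap d̄ = d − δ:

        V(d̄) = 3π² (k_B T)² / (128 κ d̄²).

    Inversely proportional to the bending modulus κ — stiff membranes
    undulate less — and decaying as d̄⁻².
    """
    _require(kappa > 0.0, "kappa must be positive")
    _require(temperature > 0.0, "temperature must be positive")
    dbar_m = geometry.dbar * _M_PER_A
    _require(dbar_m > 0.0, "dbar must be positive (potential diverges at contact)")
    kT = K_B * temperature
    return 3.0 * np.pi**2 * kT**2 / (128.0 * kappa * dbar_m**2)


def caille_helfrich(geometry: MembraneGeometry) -> float:
    """Caillé parameter of an undulation-stabilised (Helfrich) stack.

    When the interlamellar interaction is dominated by the Helfrich
    repulsion, the Caillé parameter depends only on geometry:

        η = m π² (d̄/d)² = (4/3) (1 − δ/d)²,   m = 4/(3π²).

    Under the ideal swelling law d = δ/ϕ this is (4/3)(1 − ϕ)².  Bounded
    by 4/3 (pure solvent, δ → 0) and 0 (zero water gap, δ = d), strictly
    decreasing in δ/d.
    """
    ratio = geometry.dbar / geometry.d
    return CAILLE_HELFRICH_M * np.pi**2 * ratio**2


def caille_from_moduli(q0: float, elastic: ElasticState, d: float,
                       temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Caillé parameter from the smectic elastic moduli.

        η = q0² k_B T / (8π √(B̄ K)),   K = κ/d,

    with ``q0`` the first-order Bragg wavevector (Å⁻¹), ``B̄`` the layer
    compression modulus (Pa) and ``κ`` the bending modulus (J); ``K``
    (N) is the bulk smectic curvature modulus.  Dimensionless; decreasing
    in both moduli, growing as q0².
    """
    _require(q0 > 0.0, "q0 must be positive")
    _require(d > 0.0, "d must be positive")
    _require(elastic.kappa is not None and elastic.kappa > 0.0,
             "elastic.kappa must be set and positive")
    _require(elastic.Bbar is not None and elastic.Bbar > 0.0,
             "elastic.Bbar must be set and positive (eta diverges for a soft stack)")
    _require(temperature > 0.0, "temperature must be positive")
    q0_m = q0 / _M_PER_A
    K = elastic.kappa / (d * _M_PER_A)
    return q0_m**2 * K_B * temperature / (8.0 * np.pi * np.sqrt(elastic.Bbar * K))


def electrostatic_compression_modulus(
    geometry: MembraneGeometry,
    temperature: float = DEFAULT_TEMPERATURE,
    bjerrum: float = DEFAULT_BJERRUM,
) -> float:
    """Layer compression modulus B̄ (Pa) of a weakly screened charged stack.

    For unscreened (salt-free) electrostatic repulsion between adjacent
    bilayers in the Gouy–Chapman regime, the interaction per unit area is
    ∝ k_B T / (l_B d̄), giving

        B̄ = d ∂²V/∂d̄² = π k_B T d / (l_B d̄³),

    with l_B the Bjerrum length of the solvent (7 Å for water).  Positive,
    strictly decreasing in d̄, vanishing at infinite dilution.
    """
    _require(bjerrum > 0.0, "bjerrum must be positive")
    _require(temperature > 0.0, "temperature must be positive")
    dbar_m = geometry.dbar * _M_PER_A
    _require(dbar_m > 0.0, "dbar must be positive (modulus diverges at contact)")
    d_m = geometry.d * _M_PER_A
    lb_m = bjerrum * _M_PER_A
    return np.pi * K_B * temperature * d_m / (lb_m * dbar_m**3)


def helfrich_compression_modulus(geometry: MembraneGeometry, kappa: float,
                                 temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Layer compression modulus B̄ (Pa) of an undulation-stabilised stack.

    Second derivative of the Helfrich potential, B̄ = d ∂²V/∂d̄²:

        B̄ = 9π² (k_B T)² d / (64 κ d̄⁴).

    Scales as d/d̄⁴ and vanishes for rigid membranes (κ → ∞).  Used for
    trend and consistency checks; inserting it into the modulus form of
    the Caillé parameter recovers the pure-geometry Helfrich limit
    exactly.
    """
    _require(kappa > 0.0, "kappa must be positive")
    _require(temperature > 0.0, "temperature must be positive")
    dbar_m = geometry.dbar * _M_PER_A
    _require(dbar_m > 0.0, "dbar must be positive (modulus diverges at contact)")
    d_m = geometry.d * _M_PER_A
    kT = K_B * temperature
    return 9.0 * np.pi**2 * kT**2 * d_m / (64.0 * kappa * dbar_m**4)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def swelling_d(delta: float, phi: float) -> float:
    """Ideal lamellar swelling law: repeat distance d = δ/ϕ (Å)."""
    _require(np.isfinite(delta) and delta > 0.0, "delta must be positive")
    _require(np.isfinite(phi) and 0.0 < phi <= 1.0,
             "phi must lie in (0, 1] (d diverges as phi -> 0)")
    return delta / phi


def bragg_spacing(q0: ArrayLike) -> ArrayLike:
    """Repeat distance from the first-order Bragg position, d = 2π/q0 (Å).

    Self-inverse: applying it to a distance returns the wavevector.
    """
    q0 = np.asarray(q0, dtype=float)
    _require(np.all(np.isfinite(q0)) and np.all(q0 > 0.0), "q0 must be finite and positive")
    out = 2.0 * np.pi / q0
    return out if out.ndim else float(out)
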