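"""Domain containers for lamellar-phase SANS analysis.

Unit conventions used throughout the package: scattering vectors *q* in
Å⁻¹, lengths in Å, absolute intensities in cm⁻¹, energies in J, moduli in
Pa, temperatures in K.  All containers validate their invariants on
construction and raise :class:`ValueError` naming the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ScatteringCurve",
    "SampleComposition",
    "NalletParameters",
    "MembraneGeometry",
    "ElasticState",
    "SlabModel",
]

#: Default Bjerrum length of water (Å); distance at which two unit charges
#: interact with thermal energy k_B T.
DEFAULT_BJERRUM = 7.0


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass
class ScatteringCurve:
    """One reduced 1-D SANS spectrum on absolute scale.

    Parameters
    ----------
    q : array_like
        Scattering vector per point (Å⁻¹), strictly increasing, positive.
    intensity : array_like
        Absolute scattered intensity per point (cm⁻¹), finite, ≥ 0.
    sigma : array_like, optional
        One-standard-deviation uncertainty per point (cm⁻¹), ≥ 0.
    label : str
        Free-text sample identifier.
    meta : dict, optional
        Generator/reader provenance (resolution warnings, seeds, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _require(self.q.ndim == 1 and self.q.size > 0, "q must be a non-empty 1-D array")
        _require(self.intensity.shape == self.q.shape,
                 "intensity must have the same length as q")
        _require(np.all(np.isfinite(self.q)) and np.all(self.q > 0),
                 "q must be finite and strictly positive")
        _require(np.all(np.diff(self.q) > 0), "q must be strictly increasing")
        _require(np.all(np.isfinite(self.intensity)) and np.all(self.intensity >= 0),
                 "intensity must be finite and non-negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            _require(self.sigma.shape == self.q.shape,
                     "sigma must have the same length as q")
            _require(np.all(np.isfinite(self.sigma)) and np.all(self.sigma >= 0),
                     "sigma must be finite and non-negative")

    def __len__(self) -> int:
        return self.q.size

    def window_mask(self, q_window: Optional[tuple] = None) -> np.ndarray:
        """Boolean mask selecting points inside ``q_window`` (inclusive)."""
        if q_window is None:
            return np.ones_like(self.q, dtype=bool)
        lo, hi = float(q_window[0]), float(q_window[1])
        _require(lo < hi, "q_window must satisfy lo < hi")
        return (self.q >= lo) & (self.q <= hi)

    def crop(self, q_window: tuple) -> "ScatteringCurve":
        m = self.window_mask(q_window)
        return ScatteringCurve(
            self.q[m], self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            label=self.label, meta=dict(self.meta),
        )


@dataclass(frozen=True)
class SampleComposition:
    """Composition of one lamellar sample.

    ``phi`` is the membrane volume fraction, ``omega`` the
    co-surfactant/surfactant mass ratio, ``gamma`` the charged-surfactant
    fraction, ``psi`` the telechelic-polymer fraction; ``temperature`` in K.
    """

    phi: float
    omega: float = 1.26
    gamma: float = 0.0
    psi: float = 0.0
    temperature: float = 293.15

    def __post_init__(self) -> None:
        for name in ("phi", "gamma", "psi"):
            v = getattr(self, name)
            _require(np.isfinite(v) and 0.0 <= v < 1.0, f"{name} must lie in [0, 1)")
        _require(self.phi > 0.0, "phi must be positive")
        _require(self.omega >= 0.0, "omega must be non-negative")
        _require(self.temperature > 0.0, "temperature must be positive")


@dataclass
class NalletParameters:
    """Five-parameter lamellar intensity model (plus constant background).

    ``A_z`` (cm⁻¹) and ``A_B`` (cm⁻¹) are the diffuse and Bragg amplitudes,
    ``xi_p`` (Å) the in-plane concentration-fluctuation correlation length,
    ``xi_l`` (Å) the interlamellar correlation length, ``q0`` (Å⁻¹) the
    first-order Bragg position.  ``background`` (cm⁻¹) is an additive
    incoherent level, zero by default so the bare model is recovered.
    """

    A_z: float
    xi_p: float
    A_B: float
    xi_l: float
    q0: float
    background: float = 0.0

    _FIELDS = ("A_z", "xi_p", "A_B", "xi_l", "q0", "background")

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            v = float(getattr(self, name))
            _require(np.isfinite(v) and v >= 0.0, f"{name} must be finite and non-negative")
            setattr(self, name, v)

    def as_array(self, include_background: bool = False) -> np.ndarray:
        vals = [self.A_z, self.xi_p, self.A_B, self.xi_l, self.q0]
        if include_background:
            vals.append(self.background)
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, theta, background: float = 0.0) -> "NalletParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.size == 6:
            return cls(*theta)
        return cls(*theta, background=background)


@dataclass(frozen=True)
class MembraneGeometry:
    """Lamellar stack geometry: bilayer thickness ``delta``, repeat
    distance ``d`` and derived water gap ``dbar = d − delta`` (all Å)."""

    delta: float
    d: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.delta) and self.delta >= 0.0, "delta must be non-negative")
        _require(np.isfinite(self.d) and self.d > 0.0, "d must be positive")
        _require(self.d >= self.delta, "d must be >= delta")

    @property
    def dbar(self) -> float:
        return self.d - self.delta

    @classmethod
    def from_swelling(cls, delta: float, phi: float) -> "MembraneGeometry":
        """Geometry of an ideally swelling stack, ``d = delta / phi``."""
        _require(np.isfinite(phi) and 0.0 < phi <= 1.0, "phi must lie in (0, 1]")
        _require(np.isfinite(delta) and delta > 0.0, "delta must be positive")
        return cls(delta=float(delta), d=float(delta) / float(phi))


@dataclass(frozen=True)
class ElasticState:
    """Elastic description of the stack: bending modulus ``kappa`` (J),
    layer compression modulus ``Bbar`` (Pa), Caillé parameter ``eta``
    (dimensionless) and solvent Bjerrum length (Å, 7 Å for water)."""

    kappa: Optional[float] = None
    Bbar: Optional[float] = None
    eta: Optional[float] = None
    bjerrum: float = DEFAULT_BJERRUM

    def __post_init__(self) -> None:
        if self.kappa is not None:
            _require(self.kappa > 0.0, "kappa must be positive")
        if self.Bbar is not None:
            _require(self.Bbar > 0.0, "Bbar must be positive")
        if self.eta is not None:
            _require(self.eta >= 0.0, "eta must be non-negative")
        _require(self.bjerrum > 0.0, "bjerrum must be positive")


@dataclass(frozen=True)
class SlabModel:
    """Dilute homogeneous-membrane (thin sheet) scattering model.

    ``drho`` is the scattering-length-density contrast between membrane and
    solvent (cm⁻²) and ``V_A`` the membrane volume (cm³); defaults are the
    values appropriate to the TX100/TX35/water system.
    """

    phi: float
    delta: float
    drho: float = 6.0e10
    V_A: float = 3.0e-7

    def __post_init__(self) -> None:
        _require(np.isfinite(self.phi) and self.phi > 0.0, "phi must be positive")
        _require(np.isfinite(self.delta) and self.delta > 0.0, "delta must be positive")
        _require(self.drho > 0.0, "drho must be positive")
        _require(self.V_A > 0.0, "V_A must be positive")
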