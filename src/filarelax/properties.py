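"""Material, geometry and dissipation parameters of a filament.

All quantities are SI internally: Pa for moduli, m for lengths,
kg m^-1 s^-1 for the drag and internal-friction coefficients.
Micrometre conveniences live at the I/O boundary (:mod:`filarelax.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


def section_properties(r: float) -> tuple[float, float]:
    """Area and second moment of area of a solid circular cross section.

    Parameters
    ----------
    r : float
        Filament radius in metres; must be positive.

    Returns
    -------
    (A, I) : tuple of float
        Cross-sectional area ``A = pi r**2`` (m^2) and area moment of
        inertia ``I = pi r**4 / 4`` (m^4).
    """
    if not r > 0:
        raise InvalidParameterError(f"radius must be positive, got {r!r}")
    return math.pi * r**2, math.pi * r**4 / 4.0


@dataclass(frozen=True)
class FilamentProperties:
    """Parameters of a thermally fluctuating filament.

    Attributes
    ----------
    E : float
        Young's modulus (Pa).
    G : float
        Shear modulus (Pa).
    r : float
        Radius of the (solid circular) cross section (m).
    kappa : float
        Timoshenko shear correction factor; 0.75 for a circular section.
    eta : float
        External hydrodynamic drag coefficient per unit length
        (kg m^-1 s^-1), Stokes regime.
    eta_b : float
        Internal dissipation coefficient for bending rate (kg m^-1 s^-1).
    eta_s : float
        Internal dissipation coefficient for shear rate (kg m^-1 s^-1).

    The section properties ``A``, ``I`` and stiffnesses ``B = E I``
    (bending) and ``S = G A`` (shear) are always derived from the
    primitive fields, never stored.
    """

    E: float
    G: float
    r: float
    kappa: float = 0.75
    eta: float = 0.0
    eta_b: float = 0.0
    eta_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise InvalidParameterError(f"E must be positive, got {self.E}")
        if not self.G > 0:
            raise InvalidParameterError(f"G must be positive, got {self.G}")
        if not self.r > 0:
            raise InvalidParameterError(f"r must be positive, got {self.r}")
        if not 0 < self.kappa <= 1:
            raise InvalidParameterError(
                f"kappa must lie in (0, 1], got {self.kappa}"
            )
        for name in ("eta", "eta_b", "eta_s"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")

    @property
    def A(self) -> float:
        """Cross-sectional area pi r^2 (m^2)."""
        return section_properties(self.r)[0]

    @property
    def I(self) -> float:
        """Second moment of area pi r^4 / 4 (m^4)."""
        return section_properties(self.r)[1]

    @property
    def B(self) -> float:
        """Bending stiffness E*I (N m^2)."""
        return self.E * self.I

    @property
    def S(self) -> float:
        """Shear stiffness G*A (N)."""
        return self.G * self.A

    def with_internal_friction(
        self, eta_b: float, eta_s: float
    ) -> "FilamentProperties":
        """Copy of these properties with new internal-friction coefficients."""
        return replace(self, eta_b=eta_b, eta_s=eta_s)

    @classmethod
    def from_poisson(
        cls,
        E: float,
        poisson_ratio: float,
        r: float,
        kappa: float = 0.75,
        eta: float = 0.0,
        eta_b: float = 0.0,
        eta_s: float = 0.0,
    ) -> "FilamentProperties":
        """Construct with G derived from the Poisson ratio, G = E/(2(1+nu))."""
        if not -1 < poisson_ratio < 0.5:
            raise InvalidParameterError(
                f"poisson_ratio must lie in (-1, 0.5), got {poisson_ratio}"
            )
        G = E / (2.0 * (1.0 + poisson_ratio))
        return cls(E=E, G=G, r=r, kappa=kappa, eta=eta, eta_b=eta_b, eta_s=eta_s)
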