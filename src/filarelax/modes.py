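"""Which fluctuation modes of a cantilevered filament are shear-dominated.

A mode whose wavelength is short relative to the filament radius
(lambda/r < 10 by the standard slenderness criterion) deforms mainly in
shear rather than bending.  For a clamped-free filament of length L the
mode-n wavelength is approximated by lambda_n = 2 L / ((2n - 1) pi),
the reciprocal of the cantilever wavenumber q_n = (2n - 1) pi / (2 L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .properties import InvalidParameterError

DEFAULT_THRESHOLD = 10.0
MICROTUBULE_RADIUS = 12.5e-9  # standard outer radius, m


@dataclass(frozen=True)
class ModeCriterionResult:
    """Partition of the mode ladder into bending- and shear-dominated.

    ``last_bending_mode`` is the largest mode number n for which the
    wavelength-to-radius criterion is NOT met (0 when even the
    fundamental is shear-dominated); ``first_shear_mode`` is the next
    integer.
    """

    L: float
    r: float
    threshold_ratio: float
    last_bending_mode: int
    first_shear_mode: int

    def __post_init__(self) -> None:
        if self.first_shear_mode != self.last_bending_mode + 1:
            raise InvalidParameterError("mode partition inconsistent")


def mode_wavelength(L: float, n: int) -> float:
    """Wavelength of cantilever mode n: lambda_n = 2L / ((2n - 1) pi)."""
    if not L > 0:
        raise InvalidParameterError(f"length must be positive, got {L}")
    if int(n) != n or n < 1:
        raise InvalidParameterError(f"mode number must be an integer >= 1, got {n}")
    return 2.0 * L / ((2 * n - 1) * math.pi)


def shear_dominated_modes(
    L: float, r: float, threshold: float = DEFAULT_THRESHOLD
) -> ModeCriterionResult:
    """First mode at which shear dominates bending for a given filament.

    The first shear-dominated mode is the smallest integer n with
    lambda_n / r < threshold, i.e. with 2n - 1 > 2L / (threshold r pi).
    """
    if not L > 0 or not r > 0:
        raise InvalidParameterError("L and r must be positive")
    if not threshold > 0:
        raise InvalidParameterError("threshold must be positive")
    x = 2.0 * L / (threshold * r * math.pi)
    # smallest n with 2n - 1 > x
    n_first = max(math.floor((x + 1.0) / 2.0) + 1, 1)
    while 2 * n_first - 1 <= x:  # guard against float edge cases
        n_first += 1
    while n_first > 1 and 2 * (n_first - 1) - 1 > x:
        n_first -= 1
    return ModeCriterionResult(
        L=L, r=r, threshold_ratio=threshold,
        last_bending_mode=n_first - 1, first_shear_mode=n_first,
    )
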