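"""Density-to-modulus conversion laws for femoral bone.

Apparent bone mineral density (g/cm^3) maps to an elastic modulus (MPa)
through two empirical laws: an affine law for cortical bone,

    E_c = -13450 + 14261 * rho_c,

calibrated near the cortical density of ~1.86 g/cm^3, and a power law for
trabecular bone,

    E_t = 6950 * rho_t ** 1.49.

These laws document the material model underlying the strain surrogate; the
probability-of-failure pipeline itself works directly on the surrogate and
does not call them.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LawKind",
    "DensityModulusLaw",
    "CORTICAL_LAW",
    "TRABECULAR_LAW",
    "cortical_modulus",
    "trabecular_modulus",
]


class LawKind(str, enum.Enum):
    CORTICAL_LINEAR = "cortical_linear"
    TRABECULAR_POWER = "trabecular_power"


@dataclass(frozen=True)
class DensityModulusLaw:
    """One density-to-modulus law with its calibrated constants.

    For ``cortical_linear``: ``modulus = intercept + slope * density``.
    For ``trabecular_power``: ``modulus = coefficient * density ** exponent``.
    Units: modulus MPa, density g/cm^3.
    """

    kind: LawKind
    intercept: float = 0.0  # MPa, cortical only
    slope: float = 0.0  # MPa per (g/cm^3), cortical only
    coefficient: float = 0.0  # MPa, trabecular only
    exponent: float = 1.0  # dimensionless, trabecular only

    def __post_init__(self) -> None:
        if self.kind is LawKind.TRABECULAR_POWER:
            if self.coefficient <= 0:
                raise ValueError("trabecular coefficient must be positive")
            if self.exponent <= 0:
                raise ValueError("trabecular exponent must be positive")


CORTICAL_LAW = DensityModulusLaw(LawKind.CORTICAL_LINEAR, intercept=-13450.0, slope=14261.0)
TRABECULAR_LAW = DensityModulusLaw(LawKind.TRABECULAR_POWER, coefficient=6950.0, exponent=1.49)


def cortical_modulus(density: float, law: DensityModulusLaw = CORTICAL_LAW) -> float:
    """Cortical elastic modulus (MPa) from apparent density (g/cm^3).

    The affine law is calibrated for cortical densities near 1.86 g/cm^3 and
    turns negative below its root (~0.943 g/cm^3 for the default constants);
    a warning is emitted in that regime because the law has no physical
    meaning there.

    Raises
    ------
    ValueError
        If ``density`` is not strictly positive.
    """
    if density <= 0:
        raise ValueError(f"cortical density must be positive, got {density}")
    modulus = law.intercept + law.slope * density
    if modulus < 0:
        warnings.warn(
            f"cortical law yields negative modulus ({modulus:.1f} MPa) at "
            f"density {density} g/cm^3; the law is only valid near cortical "
            "densities (~1.86 g/cm^3)",
            stacklevel=2,
        )
    return modulus


def trabecular_modulus(density: float, law: DensityModulusLaw = TRABECULAR_LAW) -> float:
    """Trabecular elastic modulus (MPa) from apparent density (g/cm^3).

    Strictly increasing power law; zero at zero density.

    Raises
    ------
    ValueError
        If ``density`` is negative.
    """
    if density < 0:
        raise ValueError(f"trabecular density must be nonnegative, got {density}")
    return law.coefficient * float(np.power(density, law.exponent))
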