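"""Uncertain scalars and moment algebra for products and squares.

The FOSM pipeline propagates only the first two moments of each input. For
the quadratic surrogate this requires the mean and variance of products and
squares of the underlying normal variables:

    product (independent X1, X2):
        mu_p  = mu1 * mu2
        var_p = (sigma1^2 + mu1^2)(sigma2^2 + mu2^2) - mu1^2 mu2^2

    square (general, with skewness gamma and kurtosis kappa):
        mu_q  = mu^2 + sigma^2
        var_q = 4 mu^2 sigma^2 + 4 mu gamma sigma^3 + (kappa - 1) sigma^4

    square (normal, gamma = 0, kappa = 3):
        var_q = 4 mu^2 sigma^2 + 2 sigma^4
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "RandomVariable",
    "TermMoments",
    "from_mean_cov",
    "product_moments",
    "square_moments",
]


@dataclass(frozen=True)
class RandomVariable:
    """A scalar uncertain quantity characterized by its first four moments.

    Parameters
    ----------
    mean, sd
        First two moments, in the units of the quantity. ``sd >= 0``.
    skewness, kurtosis
        Standardized third and fourth moments; default to the normal values
        (0 and 3). Must satisfy the Pearson inequality
        ``kurtosis >= 1 + skewness**2``.
    label
        Human-readable name used in sample-matrix headers and reports.
    """

    mean: float
    sd: float
    skewness: float = 0.0
    kurtosis: float = 3.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")
        if self.kurtosis < 1.0 + self.skewness**2 - 1e-12:
            raise ValueError(
                f"kurtosis {self.kurtosis} violates the Pearson bound "
                f"1 + skewness^2 = {1.0 + self.skewness ** 2}"
            )

    @property
    def variance(self) -> float:
        return self.sd**2

    @property
    def cov(self) -> float:
        """Coefficient of variation sd/mean; undefined for zero mean."""
        if self.mean == 0:
            raise ZeroDivisionError("COV undefined for zero mean")
        return self.sd / self.mean

    @property
    def is_normal(self) -> bool:
        return self.skewness == 0.0 and self.kurtosis == 3.0


@dataclass(frozen=True)
class TermMoments:
    """Mean and standard deviation of one derived term (product or square)."""

    mean: float
    sd: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")

    @property
    def variance(self) -> float:
        return self.sd**2


def from_mean_cov(
    mean: float,
    cov: float,
    label: str = "",
    skewness: float = 0.0,
    kurtosis: float = 3.0,
) -> RandomVariable:
    """Build a RandomVariable from a mean and coefficient of variation.

    ``sd = |mean| * cov``; the distribution defaults to normal shape.
    """
    if cov < 0:
        raise ValueError(f"cov must be nonnegative, got {cov}")
    if mean == 0 and cov > 0:
        raise ValueError("COV is undefined for a zero mean")
    return RandomVariable(
        mean=mean, sd=abs(mean) * cov, skewness=skewness, kurtosis=kurtosis, label=label
    )


def product_moments(x: RandomVariable, y: RandomVariable) -> TermMoments:
    """Exact mean and sd of ``X * Y`` for independent X and Y.

    Uses only the first two moments of each factor, so it is exact for any
    independent pair regardless of distribution shape.
    """
    mean = x.mean * y.mean
    variance = (x.sd**2 + x.mean**2) * (y.sd**2 + y.mean**2) - x.mean**2 * y.mean**2
    return TermMoments(mean=mean, sd=math.sqrt(max(variance, 0.0)))


def square_moments(x: RandomVariable) -> TermMoments:
    """Mean and sd of ``X**2``.

    The variance uses the general fourth-moment expression
    ``4 mu^2 sigma^2 + 4 mu gamma sigma^3 + (kappa - 1) sigma^4``, which for
    normal shape (gamma = 0, kappa = 3) reduces to
    ``4 mu^2 sigma^2 + 2 sigma^4``.

    Raises
    ------
    ValueError
        If the supplied skewness/kurtosis make the variance negative.
    """
    mean = x.mean**2 + x.sd**2
    variance = (
        4.0 * x.mean**2 * x.sd**2
        + 4.0 * x.mean * x.skewness * x.sd**3
        + (x.kurtosis - 1.0) * x.sd**4
    )
    if variance < 0:
        raise ValueError(
            f"variance of X^2 is negative ({variance}) for skewness "
            f"{x.skewness}, kurtosis {x.kurtosis}"
        )
    return TermMoments(mean=mean, sd=math.sqrt(variance))
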