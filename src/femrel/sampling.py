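"""Seeded Latin hypercube and Monte Carlo sampling of independent normals.

Latin hypercube sampling (LHS) partitions each variable's distribution into
``n`` equiprobable strata and draws exactly one sample per stratum, with the
stratum order permuted independently per column. For smooth statistics this
converges faster than plain Monte Carlo at equal ``n``, which is why it was
the design of the virtual experiment behind the published surrogate.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

from femrel.random_model import RandomVariable

__all__ = ["SampleMethod", "SampleMatrix", "latin_hypercube", "monte_carlo"]

logger = logging.getLogger(__name__)


class SampleMethod(str, enum.Enum):
    LHS = "lhs"
    MC = "mc"


@dataclass(frozen=True)
class SampleMatrix:
    """An ``n_samples x n_variables`` array of draws with provenance.

    ``values[:, j]`` holds the draws for ``variable_labels[j]``.
    """

    values: np.ndarray
    variable_labels: tuple[str, ...]
    seed: int
    method: SampleMethod

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_samples, n_variables)")
        if self.values.shape[1] != len(self.variable_labels):
            raise ValueError("one label per column required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.variable_labels.index(label)]

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV with a header row of variable labels."""
        np.savetxt(
            path,
            self.values,
            delimiter=",",
            header=",".join(self.variable_labels),
            comments="",
        )


def _labels(variables: Sequence[RandomVariable]) -> tuple[str, ...]:
    return tuple(v.label or f"x{i}" for i, v in enumerate(variables))


def latin_hypercube(
    variables: Sequence[RandomVariable],
    n: int,
    seed: int,
    midpoint: bool = False,
) -> SampleMatrix:
    """Latin hypercube draws from independent normal variables.

    Each variable's normal distribution is split into ``n`` equiprobable
    strata; each stratum receives exactly one draw, placed uniformly at
    random within the stratum (or at the stratum probability midpoint when
    ``midpoint=True``). Column permutations and within-stratum positions are
    all derived from ``seed``, so results are bit-reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not variables:
        raise ValueError("at least one variable required")
    sampler = qmc.LatinHypercube(d=len(variables), scramble=not midpoint, seed=seed)
    u = sampler.random(n)  # uniform (0,1)^d, one point per stratum per column
    values = np.empty_like(u)
    for j, v in enumerate(variables):
        if v.sd == 0:
            values[:, j] = v.mean
        else:
            values[:, j] = stats.norm.ppf(u[:, j], loc=v.mean, scale=v.sd)
    return SampleMatrix(values, _labels(variables), seed, SampleMethod.LHS)


def monte_carlo(
    variables: Sequence[RandomVariable],
    n: int,
    seed: int,
    truncate_at: float | None = None,
) -> SampleMatrix:
    """Plain i.i.d. normal draws, optionally truncated from below.

    With ``truncate_at`` set, draws below the threshold are resampled until
    all columns clear it (used for physically nonnegative densities at high
    COV). Truncation is off by default so the Monte Carlo oracle matches the
    untruncated-normal assumptions of the FOSM math; a warning is logged
    when raw draws fall below zero and no truncation is requested.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    means = np.array([v.mean for v in variables])
    sds = np.array([v.sd for v in variables])
    values = rng.normal(means, sds, size=(n, len(variables)))
    if truncate_at is not None:
        for _ in range(1000):
            bad = values < truncate_at
            if not bad.any():
                break
            values[bad] = rng.normal(
                np.broadcast_to(means, values.shape)[bad],
                np.broadcast_to(sds, values.shape)[bad],
            )
        else:
            raise RuntimeError("truncated resampling did not converge")
    elif (values < 0).any():
        logger.warning(
            "%d raw normal draws are negative; pass truncate_at=0 if the "
            "variable is physically nonnegative",
            int((values < 0).sum()),
        )
    return SampleMatrix(values, _labels(variables), seed, SampleMethod.MC)
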