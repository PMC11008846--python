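"""FOSM reliability analysis of the strain performance function.

The performance function is Z = Y - S: capacity (compressive yield strain
Y, default N(0.0085, 0.0010)) minus demand (load-induced strain S). With

    mu_Z    = mu_Y - mu_S
    sigma_Z = sqrt(sigma_S^2 + sigma_Y^2)
    beta    = mu_Z / sigma_Z            (reliability index)
    PoF     = 1 - Phi(beta)

the probability of failure follows once (mu_S, sigma_S) are known. Four
routes to those strain moments are provided:

``paper_termwise``
    Each regressor term of the quadratic surrogate (BMD, BW, BMD*BW,
    BMD^2, BW^2) is reduced to its own mean and sd via the product/square
    moment formulas, and the terms are then combined *as if independent*:
    sigma_S^2 = sum(ai^2 * sd_i^2). The derived terms are of course
    correlated (BMD and BMD^2 share the same underlying draw), so this
    overstates sigma_S; it is retained as its own mode because it is the
    linearized-combination recipe the published failure probabilities
    follow, and it is the default for reproduction.
``taylor_first_order``
    Classic FOSM linearization: mu_S = S at the input means, sigma_S^2 =
    (dS/dBMD)^2 sigma_BMD^2 + (dS/dBW)^2 sigma_BW^2 with gradients at the
    means.
``exact_moments``
    Exact mean and variance of the quadratic form in two independent
    normals, using closed-form normal raw moments up to order four and
    including all covariances among the five terms. Recommended for new
    analyses.
``monte_carlo``
    Sampling oracle: i.i.d. normal draws of (BMD, BW, Y), PoF = fraction
    of draws with S > Y.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from femrel.random_model import RandomVariable, product_moments, square_moments
from femrel.response_surface import QuadraticResponseModel

__all__ = [
    "Mode",
    "YieldCriterion",
    "PerformanceSummary",
    "strain_moments_termwise",
    "strain_moments_taylor",
    "strain_moments_exact",
    "strain_moments",
    "pof_analytic",
    "pof_monte_carlo",
]


class Mode(str, enum.Enum):
    PAPER_TERMWISE = "paper_termwise"
    TAYLOR_FIRST_ORDER = "taylor_first_order"
    EXACT_MOMENTS = "exact_moments"
    MONTE_CARLO = "monte_carlo"


DEFAULT_YIELD_MEAN = 0.0085  # strain fraction (0.85%)
DEFAULT_YIELD_SD = 0.0010  # strain fraction (0.10%)


@dataclass(frozen=True)
class YieldCriterion:
    """Compressive yield strain of trabecular bone as a random capacity."""

    yield_strain: RandomVariable = RandomVariable(
        mean=DEFAULT_YIELD_MEAN, sd=DEFAULT_YIELD_SD, label="yield_strain"
    )


@dataclass(frozen=True)
class PerformanceSummary:
    """All intermediate moments and the failure probability for one run."""

    mode: Mode
    mu_S: float
    sigma_S: float
    mu_Z: float
    sigma_Z: float
    beta: float
    pof: float
    n_mc: int | None = None
    seed: int | None = None
    mc_standard_error: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["mode"] = self.mode.value
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def strain_moments_termwise(
    model: QuadraticResponseModel, bmd: RandomVariable, bw: RandomVariable
) -> tuple[float, float]:
    """Term-wise strain moments (the reproduction mode).

    Each derived regressor term gets exact product/square moments, but the
    five terms are then combined as if mutually independent. Deliberately
    ignores covariances among the terms; see the module docstring.
    """
    p = product_moments(bmd, bw)
    q_bmd = square_moments(bmd)
    q_bw = square_moments(bw)
    term_means = np.array([bmd.mean, bw.mean, p.mean, q_bmd.mean, q_bw.mean])
    term_sds = np.array([bmd.sd, bw.sd, p.sd, q_bmd.sd, q_bw.sd])
    coeffs = np.array([model.a1, model.a2, model.a3, model.a4, model.a5])
    mu = model.scale * (model.a0 + float(coeffs @ term_means))
    sigma = model.scale * math.sqrt(float((coeffs**2) @ (term_sds**2)))
    return mu, sigma


def strain_moments_taylor(
    model: QuadraticResponseModel, bmd: RandomVariable, bw: RandomVariable
) -> tuple[float, float]:
    """First-order Taylor strain moments (gradients at the input means)."""
    mu = model.evaluate(bmd.mean, bw.mean)
    d_bmd = model.scale * (model.a1 + model.a3 * bw.mean + 2.0 * model.a4 * bmd.mean)
    d_bw = model.scale * (model.a2 + model.a3 * bmd.mean + 2.0 * model.a5 * bw.mean)
    sigma = math.hypot(d_bmd * bmd.sd, d_bw * bw.sd)
    return float(mu), sigma


def strain_moments_exact(
    model: QuadraticResponseModel, bmd: RandomVariable, bw: RandomVariable
) -> tuple[float, float]:
    """Exact strain moments for independent normal inputs.

    Substituting BMD = mu_b + sigma_b*U and BW = mu_w + sigma_w*V with U, V
    independent standard normals rewrites the surrogate as a quadratic in
    (U, V) whose five non-constant terms {U, V, UV, U^2, V^2} are mutually
    uncorrelated (all odd standard-normal moments vanish). The variance is
    then an exact sum of squares — every covariance among the original
    correlated terms (e.g. Cov(X, X^2) = 2 mu sigma^2) is absorbed by the
    centering, with no cancellation error.
    """
    if not (bmd.is_normal and bw.is_normal):
        raise ValueError("exact_moments requires normal BMD and BW inputs")
    mb, sb = bmd.mean, bmd.sd
    mw, sw = bw.mean, bw.sd
    # centered-representation coefficients c_pq of U^p V^q
    c10 = sb * (model.a1 + model.a3 * mw + 2.0 * model.a4 * mb)
    c01 = sw * (model.a2 + model.a3 * mb + 2.0 * model.a5 * mw)
    c11 = model.a3 * sb * sw
    c20 = model.a4 * sb * sb
    c02 = model.a5 * sw * sw
    mean = model.evaluate(mb, mw) / model.scale + c20 + c02
    # Var(U) = Var(V) = Var(UV) = 1, Var(U^2) = Var(V^2) = 2
    var = c10**2 + c01**2 + c11**2 + 2.0 * c20**2 + 2.0 * c02**2
    return model.scale * float(mean), model.scale * math.sqrt(float(var))


_MOMENT_ROUTES = {
    Mode.PAPER_TERMWISE: strain_moments_termwise,
    Mode.TAYLOR_FIRST_ORDER: strain_moments_taylor,
    Mode.EXACT_MOMENTS: strain_moments_exact,
}


def strain_moments(
    model: QuadraticResponseModel,
    bmd: RandomVariable,
    bw: RandomVariable,
    mode: Mode | str = Mode.PAPER_TERMWISE,
) -> tuple[float, float]:
    """Dispatch to one of the analytic strain-moment routes by mode."""
    return _MOMENT_ROUTES[Mode(mode)](model, bmd, bw)


def pof_analytic(
    moments: tuple[float, float],
    criterion: YieldCriterion = YieldCriterion(),
    mode: Mode | str = Mode.PAPER_TERMWISE,
) -> PerformanceSummary:
    """Failure probability from strain moments via the reliability index.

    Degenerate case sigma_S = sigma_Y = 0 collapses to a step function
    (PoF 1 if mu_S >= mu_Y else 0) with a warning instead of an exception.
    """
    mu_S, sigma_S = moments
    y = criterion.yield_strain
    mu_Z = y.mean - mu_S
    sigma_Z = math.hypot(sigma_S, y.sd)
    if sigma_Z == 0.0:
        warnings.warn(
            "sigma_Z = 0 (deterministic demand and capacity); "
            "PoF degenerates to a step function",
            stacklevel=2,
        )
        pof = 1.0 if mu_S >= y.mean else 0.0
        beta = -math.inf if pof == 1.0 else math.inf
    else:
        beta = mu_Z / sigma_Z
        pof = float(norm.sf(beta))
    return PerformanceSummary(
        mode=Mode(mode),
        mu_S=mu_S,
        sigma_S=sigma_S,
        mu_Z=mu_Z,
        sigma_Z=sigma_Z,
        beta=beta,
        pof=pof,
    )


def pof_monte_carlo(
    model: QuadraticResponseModel,
    bmd: RandomVariable,
    bw: RandomVariable,
    criterion: YieldCriterion = YieldCriterion(),
    n: int = 1_000_000,
    seed: int = 0,
    truncate_bmd_at: float | None = None,
) -> PerformanceSummary:
    """Monte Carlo failure probability (verification oracle).

    Draws (BMD, BW, Y) as independent normals — untruncated by default to
    match the FOSM assumptions — and counts S > Y. Reports the binomial
    standard error alongside the estimate.
    """
    if n < 10_000:
        raise ValueError(f"n must be >= 10^4 for a stable estimate, got {n}")
    rng = np.random.default_rng(seed)
    b = rng.normal(bmd.mean, bmd.sd, n)
    if truncate_bmd_at is not None:
        for _ in range(1000):
            bad = b < truncate_bmd_at
            if not bad.any():
                break
            b[bad] = rng.normal(bmd.mean, bmd.sd, int(bad.sum()))
    w = rng.normal(bw.mean, bw.sd, n)
    y = rng.normal(criterion.yield_strain.mean, criterion.yield_strain.sd, n)
    # surrogate polynomial evaluated directly: MC draws may be negative by
    # design (untruncated normals), which evaluate() would reject
    s = model.scale * (
        model.a0 + model.a1 * b + model.a2 * w + model.a3 * b * w
        + model.a4 * b**2 + model.a5 * w**2
    )
    failures = s > y
    pof = float(failures.mean())
    se = math.sqrt(max(pof * (1.0 - pof), 1e-300) / n)
    mu_S = float(s.mean())
    sigma_S = float(s.std(ddof=1))
    z = y - s
    return PerformanceSummary(
        mode=Mode.MONTE_CARLO,
        mu_S=mu_S,
        sigma_S=sigma_S,
        mu_Z=float(z.mean()),
        sigma_Z=float(z.std(ddof=1)),
        beta=float(z.mean() / z.std(ddof=1)),
        pof=pof,
        n_mc=n,
        seed=seed,
        mc_standard_error=se,
    )
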