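"""Quadratic response-surface surrogate for trabecular compressive strain.

The surrogate expresses the peak compressive strain S (dimensionless
fraction) in the proximal trabecular bone as a bivariate quadratic in
apparent bone mineral density (BMD, g/cm^3) and hip-contact loading
(BW, multiples of body weight):

    S = scale * (a0 + a1*BMD + a2*BW + a3*BMD*BW + a4*BMD^2 + a5*BW^2)

The published coefficients (fit to 100 finite-element simulations sampled
by Latin hypercube) are a0=4.09, a1=-17.66, a2=2.80, a3=-2.35, a4=15.67,
a5=-0.05 at scale 1e-3. Coefficients are stored exactly as printed plus the
global scale, so the published model is bit-faithful.

Strain is a dimensionless fraction everywhere internally; "%" appears only
in formatting. The 0.85% yield criterion is the fraction 0.0085.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "QuadraticResponseModel",
    "PUBLISHED_MODEL",
    "FitStats",
    "fit",
    "failure_boundary_bmd",
    "classify_region",
    "region_to_dataframe",
]

# training envelope of the published fit: sampling means +/- 3 sd
_BMD_ENVELOPE = (0.5 - 3 * 0.175, 0.5 + 3 * 0.175)
_BW_ENVELOPE = (2.0 - 3 * 0.4, 2.0 + 3 * 0.4)

_REGRESSOR_NAMES = ("1", "bmd", "bw", "bmd*bw", "bmd^2", "bw^2")


@dataclass(frozen=True)
class QuadraticResponseModel:
    """Coefficients of the strain surrogate on the printed scale."""

    a0: float
    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    scale: float = 1e-3

    @property
    def coefficients(self) -> np.ndarray:
        """The six printed-scale coefficients in regressor order."""
        return np.array([self.a0, self.a1, self.a2, self.a3, self.a4, self.a5])

    def evaluate(
        self,
        bmd: float | np.ndarray,
        bw: float | np.ndarray,
        warn_extrapolation: bool = False,
    ) -> float | np.ndarray:
        """Strain fraction at the given BMD (g/cm^3) and loading (BW).

        With ``warn_extrapolation=True`` a warning is emitted when the query
        leaves the training envelope of the published fit (sampling mean
        +/- 3 sd: BMD in [-0.025, 1.025], BW in [0.8, 3.2]).
        """
        bmd = np.asarray(bmd, dtype=float)
        bw = np.asarray(bw, dtype=float)
        if (bmd < 0).any() or (bw < 0).any():
            raise ValueError("bmd and bw must be nonnegative")
        if warn_extrapolation:
            out = (
                (bmd < _BMD_ENVELOPE[0]).any()
                or (bmd > _BMD_ENVELOPE[1]).any()
                or (bw < _BW_ENVELOPE[0]).any()
                or (bw > _BW_ENVELOPE[1]).any()
            )
            if out:
                warnings.warn(
                    "query outside the training envelope "
                    f"BMD {_BMD_ENVELOPE}, BW {_BW_ENVELOPE}; the surrogate "
                    "extrapolates there",
                    stacklevel=2,
                )
        s = self.scale * (
            self.a0
            + self.a1 * bmd
            + self.a2 * bw
            + self.a3 * bmd * bw
            + self.a4 * bmd**2
            + self.a5 * bw**2
        )
        return float(s) if s.ndim == 0 else s

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "a0": float(self.a0), "a1": float(self.a1), "a2": float(self.a2),
            "a3": float(self.a3), "a4": float(self.a4), "a5": float(self.a5),
            "scale": float(self.scale),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuadraticResponseModel":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**{k: float(payload[k]) for k in ("a0", "a1", "a2", "a3", "a4", "a5", "scale")})


#: The published surrogate, bit-faithful to the printed coefficients.
PUBLISHED_MODEL = QuadraticResponseModel(
    a0=4.09, a1=-17.66, a2=2.80, a3=-2.35, a4=15.67, a5=-0.05, scale=1e-3
)


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit summary for a least-squares surrogate fit.

    ``sse`` is the sum of squared residuals on the strain-fraction scale;
    ``rmse = sqrt(sse / (n - p))`` with ``p = 6`` coefficients.
    """

    sse: float
    r_squared: float
    adjusted_r_squared: float
    rmse: float
    n: int
    p: int = 6


def _design_matrix(bmd: np.ndarray, bw: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(bmd), bmd, bw, bmd * bw, bmd**2, bw**2])


def fit(samples, scale: float = 1e-3) -> tuple[QuadraticResponseModel, FitStats]:
    """Ordinary least squares fit of the quadratic surrogate.

    Parameters
    ----------
    samples
        Sequence of ``(bmd, bw, strain)`` triples; strain as a fraction.
    scale
        Printed scale of the returned coefficients (default 1e-3, matching
        the published model). The fit itself is scale-invariant.

    Raises
    ------
    ValueError
        Fewer than 6 samples, or a rank-deficient design (the error names
        the collinear regressors).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("samples must be an iterable of (bmd, bw, strain) triples")
    n = arr.shape[0]
    if n < 6:
        raise ValueError(f"need at least 6 samples to fit 6 coefficients, got {n}")
    bmd, bw, strain = arr.T
    X = _design_matrix(bmd, bw)
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        # name the regressors involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        dep = [
            _REGRESSOR_NAMES[j]
            for j in range(6)
            if abs(r[j, j]) < 1e-10 * max(abs(np.diag(r)).max(), 1.0)
        ]
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < 6); "
            f"collinear regressors: {dep or _REGRESSOR_NAMES}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, strain, rcond=None)
    resid = strain - X @ beta
    sse = float(resid @ resid)
    sst = float(((strain - strain.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("constant response (SST = 0); defining R^2 = 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - sse / sst
    p = 6
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    rmse = float(np.sqrt(sse / (n - p))) if n > p else 0.0
    model = QuadraticResponseModel(*(float(b) for b in beta / scale), scale=scale)
    return model, FitStats(sse=sse, r_squared=r2, adjusted_r_squared=adj, rmse=rmse, n=n)


def failure_boundary_bmd(
    model: QuadraticResponseModel, yield_strain: float, bw: float
) -> list[float]:
    """BMD values where S(BMD, bw) crosses the yield strain, at fixed bw.

    Solves the quadratic ``a4*b^2 + (a1 + a3*bw)*b + (a0 + a2*bw + a5*bw^2
    - yield/scale) = 0`` in closed form and returns the real nonnegative
    roots sorted ascending. An empty list means the whole BMD axis is on
    one side of the criterion (all safe or all failing; disambiguate by
    evaluating at bmd = 0).
    """
    if yield_strain <= 0:
        raise ValueError(f"yield_strain must be positive, got {yield_strain}")
    a = model.a4
    b = model.a1 + model.a3 * bw
    c = model.a0 + model.a2 * bw + model.a5 * bw**2 - yield_strain / model.scale
    if a == 0.0:
        if b == 0.0:
            return []
        roots = np.array([-c / b])
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            return []
        sq = np.sqrt(disc)
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    return sorted(float(r) for r in roots if r >= 0)


def classify_region(
    model: QuadraticResponseModel,
    yield_strain: float,
    bmd_grid: np.ndarray,
    bw_grid: np.ndarray,
) -> np.ndarray:
    """Boolean failure mask over a (BMD, BW) grid; True where S >= yield.

    ``mask[i, j]`` corresponds to ``bmd_grid[i], bw_grid[j]``. Both grids
    must be sorted ascending.
    """
    bmd_grid = np.asarray(bmd_grid, dtype=float)
    bw_grid = np.asarray(bw_grid, dtype=float)
    for name, g in (("bmd_grid", bmd_grid), ("bw_grid", bw_grid)):
        if (np.diff(g) < 0).any():
            raise ValueError(f"{name} must be sorted ascending")
    B, W = np.meshgrid(bmd_grid, bw_grid, indexing="ij")
    return np.asarray(model.evaluate(B, W)) >= yield_strain


def region_to_dataframe(model, yield_strain, bmd_grid, bw_grid):
    """Long-format table (bmd, bw, strain, failure_flag) for export."""
    import pandas as pd

    bmd_grid = np.asarray(bmd_grid, dtype=float)
    bw_grid = np.asarray(bw_grid, dtype=float)
    B, W = np.meshgrid(bmd_grid, bw_grid, indexing="ij")
    S = np.asarray(model.evaluate(B, W))
    return pd.DataFrame(
        {
            "bmd": B.ravel(),
            "bw": W.ravel(),
            "strain": S.ravel(),
            "failure_flag": (S >= yield_strain).ravel(),
        }
    )
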