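"""Virtual-experiment generator for surrogate training data.

The published surrogate was trained on 100 finite-element simulations whose
(BMD, BW) inputs were drawn by Latin hypercube from N(0.5, 0.175) g/cm^3
and N(2.0, 0.4) BW. This module replays that design with the published
surrogate itself as the ground truth plus homoscedastic Gaussian strain
noise, so fitting and the downstream reliability pipeline are testable
end to end without any finite-element solver.

The default noise sd, 6.57e-4 strain fraction, is sqrt(SSE / n) for the
published fit residual (SSE 4.316e-5 over n = 100). The published RMSE
figure is not consistent with that SSE under any standard definition; the
noise default follows the SSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from femrel.random_model import RandomVariable
from femrel.reliability import Mode, YieldCriterion, pof_analytic, strain_moments
from femrel.response_surface import PUBLISHED_MODEL, QuadraticResponseModel, fit
from femrel.sampling import latin_hypercube
from femrel.scenarios import Scenario

__all__ = [
    "DEFAULT_NOISE_SD",
    "VirtualExperimentConfig",
    "generate",
    "dataset_to_csv",
    "dataset_from_csv",
    "parameter_recovery_experiment",
]

logger = logging.getLogger(__name__)

DEFAULT_NOISE_SD = 6.57e-4  # strain fraction; sqrt(4.316e-5 / 100)

#: FE inputs must be physical: sampled BMD below this floor is clipped.
_BMD_FLOOR = 0.01

_COLUMNS = ("bmd_g_cm3", "bw_multiples", "strain_fraction")


@dataclass(frozen=True)
class VirtualExperimentConfig:
    """Design of one virtual experiment (defaults match the published one)."""

    n: int = 100
    bmd: RandomVariable = RandomVariable(mean=0.5, sd=0.175, label="bmd")
    bw: RandomVariable = RandomVariable(mean=2.0, sd=0.4, label="bw")
    noise_sd: float = DEFAULT_NOISE_SD
    truth_model: QuadraticResponseModel = PUBLISHED_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")


def generate(config: VirtualExperimentConfig) -> np.ndarray:
    """Generate an (n, 3) array of (bmd, bw, strain) training triples.

    (BMD, BW) come from a seeded Latin hypercube of the configured normal
    distributions; strain is the truth model plus i.i.d. Gaussian noise.
    Sampled BMD below 0.01 g/cm^3 is clipped there (a finite-element input
    must be physical) with a logged count; the clipping applies only here,
    never in the reliability oracles.
    """
    samples = latin_hypercube([config.bmd, config.bw], config.n, seed=config.seed)
    bmd = samples.column("bmd").copy()
    bw = samples.column("bw")
    n_clipped = int((bmd < _BMD_FLOOR).sum())
    if n_clipped:
        logger.info("clipped %d sampled BMD values to %.2f g/cm^3", n_clipped, _BMD_FLOOR)
        bmd = np.clip(bmd, _BMD_FLOOR, None)
    # noise stream is seeded independently of the LHS stream
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = config.truth_model.scale * (
        config.truth_model.a0
        + config.truth_model.a1 * bmd
        + config.truth_model.a2 * bw
        + config.truth_model.a3 * bmd * bw
        + config.truth_model.a4 * bmd**2
        + config.truth_model.a5 * bw**2
    )
    strain = truth + rng.normal(0.0, config.noise_sd, config.n)
    return np.column_stack([bmd, bw, strain])


def dataset_to_csv(dataset: np.ndarray, path: str | Path) -> None:
    # %.17g round-trips doubles exactly
    pd.DataFrame(dataset, columns=list(_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def dataset_from_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    return df[list(_COLUMNS)].to_numpy(dtype=float)


def parameter_recovery_experiment(
    reps: int,
    config: VirtualExperimentConfig = VirtualExperimentConfig(),
    reference_scenario: Scenario | None = None,
) -> pd.DataFrame:
    """Repeated generate -> fit cycles: coefficient bias, RMSE, downstream PoF.

    Each replicate regenerates the virtual experiment with a distinct seed
    derived from ``config.seed``, refits the surrogate, and (optionally)
    recomputes the term-wise failure probability of a reference scenario
    from the fitted model. Returns one row per replicate with fitted
    coefficients, fit R^2, and the downstream PoF.
    """
    if reps < 10:
        raise ValueError(f"reps must be >= 10 for a meaningful summary, got {reps}")
    rows = []
    for r in range(reps):
        rep_seed = int(
            np.random.SeedSequence([config.seed, 2, r]).generate_state(1)[0] % (2**31)
        )
        cfg = VirtualExperimentConfig(
            n=config.n,
            bmd=config.bmd,
            bw=config.bw,
            noise_sd=config.noise_sd,
            truth_model=config.truth_model,
            seed=rep_seed,
        )
        model, stats = fit(generate(cfg))
        row = {
            "rep": r,
            "seed": rep_seed,
            "a0": model.a0, "a1": model.a1, "a2": model.a2,
            "a3": model.a3, "a4": model.a4, "a5": model.a5,
            "r_squared": stats.r_squared,
        }
        if reference_scenario is not None:
            sc = reference_scenario
            ps = pof_analytic(
                strain_moments(model, sc.bmd, sc.bw, mode=Mode.PAPER_TERMWISE),
                sc.criterion,
                mode=Mode.PAPER_TERMWISE,
            )
            row["pof_termwise"] = ps.pof
        rows.append(row)
    return pd.DataFrame(rows)
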