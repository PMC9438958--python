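"""Synthetic proportional-hazards cohorts with known ground truth.

The generator draws covariates X ~ N(0, I), forms the linear predictor
eta = X beta, and samples event times from a Weibull proportional-hazards
model with baseline survival S0(t) = exp(-(t/scale)^shape), i.e.

    S_i(t) = S0(t)^{exp(eta_i)},   Y_i = scale * (-log U_i / exp(eta_i))^{1/shape}

by inversion sampling.  Censoring times are independent exponentials with a
chosen rate (rate 0 means no censoring).  Because the model is strictly
proportional hazards, the true survival curves of distinct subjects never
cross, and every order-preserving reduction of the true curves recovers the
eta ranking exactly — the property the test suites lean on.

Truncating the true curves at an early time produces *improper* predictions
(rows plateauing above 0), emulating product-limit predictions confined to
an observation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalCurveMatrix, SurvivalOutcomes, TimeGrid, validate_curves
from .exceptions import DataValidationError

__all__ = [
    "PHSimConfig",
    "SimulatedCohort",
    "simulate_ph_cohort",
    "true_curve_matrix",
    "default_grid",
    "truncate_curves",
]


@dataclass(frozen=True)
class PHSimConfig:
    """Parameters of the Weibull proportional-hazards simulation.

    ``censor_rate`` is the rate of the independent exponential censoring
    distribution (0 = no censoring); ``weibull_shape``/``weibull_scale``
    parameterise the baseline hazard; ``beta`` has one coefficient per
    covariate.
    """

    n_subjects: int = 300
    beta: tuple = (1.0,)
    weibull_shape: float = 1.5
    weibull_scale: float = 10.0
    censor_rate: float = 0.0
    grid_size: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise DataValidationError("need at least 2 subjects")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise DataValidationError("Weibull shape and scale must be positive")
        if self.censor_rate < 0:
            raise DataValidationError("censor_rate must be non-negative")
        if self.grid_size < 1:
            raise DataValidationError("grid_size must be at least 1")
        object.__setattr__(self, "beta", tuple(float(b) for b in np.atleast_1d(self.beta)))

    @property
    def n_covariates(self) -> int:
        return len(self.beta)


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort with its latent ground truth.

    ``eta`` is the true linear predictor X beta; ``latent_event_time`` and
    ``latent_censor_time`` are the (normally unobservable) Y_i and C_i with
    T_i = min(Y_i, C_i) and delta_i = 1(T_i = Y_i).
    """

    config: PHSimConfig
    covariates: np.ndarray
    eta: np.ndarray
    latent_event_time: np.ndarray
    latent_censor_time: np.ndarray
    outcomes: SurvivalOutcomes


def simulate_ph_cohort(config: PHSimConfig) -> SimulatedCohort:
    """Draw a cohort from the Weibull PH model; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_covariates
    X = rng.standard_normal((n, p))
    beta = np.asarray(config.beta)
    eta = X @ beta

    u = rng.uniform(size=n)
    y = config.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.weibull_shape)
    if config.censor_rate > 0:
        c = rng.exponential(scale=1.0 / config.censor_rate, size=n)
    else:
        c = np.full(n, np.inf)
    t = np.minimum(y, c)
    status = (t == y).astype(int)
    outcomes = SurvivalOutcomes(np.arange(1, n + 1), t, status)
    return SimulatedCohort(
        config=config,
        covariates=X,
        eta=eta,
        latent_event_time=y,
        latent_censor_time=c,
        outcomes=outcomes,
    )


def default_grid(config: PHSimConfig) -> TimeGrid:
    """Equally spaced grid from the 1st to the 99th percentile of the baseline distribution."""
    q = np.array([0.01, 0.99])
    lo, hi = config.weibull_scale * (-np.log(1 - q)) ** (1.0 / config.weibull_shape)
    return TimeGrid(np.linspace(lo, hi, config.grid_size))


def true_curve_matrix(cohort: SimulatedCohort, grid: TimeGrid | None = None) -> SurvivalCurveMatrix:
    """Exact model survival curves S_i(t) = exp(-(t/scale)^shape * exp(eta_i))."""
    if grid is None:
        grid = default_grid(cohort.config)
    cfg = cohort.config
    base_cumhaz = (grid.times / cfg.weibull_scale) ** cfg.weibull_shape
    probs = np.exp(-np.outer(np.exp(cohort.eta), base_cumhaz))
    return validate_curves(
        SurvivalCurveMatrix(grid, probs, cohort.outcomes.subject_id)
    )


def truncate_curves(curves: SurvivalCurveMatrix, t_max: float) -> SurvivalCurveMatrix:
    """Restrict a curve matrix to grid times <= t_max, typically leaving rows improper."""
    times = curves.grid.times
    if t_max >= times[-1]:
        raise DataValidationError(
            f"t_max={t_max} is not below the grid end {times[-1]}; nothing to truncate"
        )
    keep = times <= t_max
    if not keep.any():
        raise DataValidationError(f"t_max={t_max} precedes the first grid time {times[0]}")
    return SurvivalCurveMatrix(
        TimeGrid(times[keep]), curves.probabilities[:, keep], curves.subject_ids
    )
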