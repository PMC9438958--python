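"""Distribution-to-risk reductions and extrapolation policies for improper curves.

A reduction maps a predicted survival curve (a row of probabilities over a
time grid) to a single relative risk, so that time-independent concordance
measures become applicable to distribution-predicting models.  Three
reductions are provided:

* :func:`prob_at_time` — minus the predicted survival probability at a
  chosen time t' (lower survival at t' = higher risk);
* :func:`curve_summary` — minus the mean or median of the discrete
  time-to-event distribution implied by the curve;
* :func:`expected_mortality` — the sum of the predicted cumulative hazard
  over the grid, an assumption-free relative risk (higher = riskier).

Product-limit-style predictions are usually *improper*: the curve plateaus
above 0 inside the observation window, so the implied distribution has
missing probability mass and summary statistics misbehave.  Two
extrapolation policies "fix" a curve before summarising:

* ``drop``   — force survival to 0 one step past the last grid time,
  i.e. assume everyone still alive dies at once just after the study end;
* ``linear`` — extend the straight line through (0, 1) and the last
  observed point down to its zero crossing, which can land at unrealistic
  times when the curve is shallow.

``naive`` applies no fix at all, and the mean is then the *unnormalised*
truncated mass sum — the pathological quantity that makes naive-summary
concordances collapse (and even invert) on improper predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import (
    RiskVector,
    SurvivalCurveMatrix,
    TimeGrid,
    step_survival_all,
    validate_curves,
)
from .exceptions import DataValidationError, ImproperCurveError

__all__ = [
    "ImproperPolicy",
    "SummaryStatistic",
    "prob_at_time",
    "expected_mortality",
    "drop_to_zero",
    "linear_extrapolate",
    "curve_summary",
]

_POLICY_MODES = ("naive", "drop", "linear")
_SUMMARY_KINDS = ("mean", "median")


@dataclass(frozen=True)
class ImproperPolicy:
    """How to treat curves that do not reach 0 before summarising.

    ``drop_offset`` is the time increment past the last grid point at which
    the ``drop`` policy places the remaining mass; ``None`` defaults to the
    smallest positive spacing of the grid at application time.
    """

    mode: str = "naive"
    drop_offset: float | None = None

    def __post_init__(self):
        if self.mode not in _POLICY_MODES:
            raise DataValidationError(f"policy mode must be one of {_POLICY_MODES}, got {self.mode!r}")
        if self.drop_offset is not None and self.drop_offset <= 0:
            raise DataValidationError("drop_offset must be positive")


@dataclass(frozen=True)
class SummaryStatistic:
    """Which location summary of the implied distribution to use as (minus) the risk."""

    kind: str = "mean"

    def __post_init__(self):
        if self.kind not in _SUMMARY_KINDS:
            raise DataValidationError(f"summary kind must be one of {_SUMMARY_KINDS}, got {self.kind!r}")


def prob_at_time(curves: SurvivalCurveMatrix, t_prime: float) -> RiskVector:
    """Reduce curves to risks by (negated) survival probability at time ``t_prime``.

    risk_i = -S_i(t'), evaluated by step interpolation, so a lower predicted
    survival probability at t' means a higher risk.  At any t' before the
    first grid point every curve evaluates to 1 and all risks are tied.
    """
    validate_curves(curves)
    if t_prime < 0:
        raise DataValidationError(f"evaluation time must be non-negative, got {t_prime}")
    surv = step_survival_all(curves, t_prime)
    return RiskVector(curves.subject_ids, -surv, label=f"Prob@{t_prime:g}")


def expected_mortality(curves: SurvivalCurveMatrix) -> RiskVector:
    """Sum of the predicted cumulative hazard over the grid, as a relative risk.

    phi_i = sum_{t in grid} -log S_i(t) = sum_t H_i(t).  Grid points where
    S_i(t) = 0 contribute +inf, which is propagated (not clamped); when two
    or more subjects are both +inf their ranking is a tie and a warning is
    emitted.  Requires no assumptions about the curve beyond validity, which
    is why it is the most robust reduction for improper predictions.
    """
    validate_curves(curves)
    with np.errstate(divide="ignore"):
        cumhaz = -np.log(curves.probabilities)
    phi = cumhaz.sum(axis=1)
    if np.isposinf(phi).sum() >= 2:
        warnings.warn(
            "two or more subjects have infinite expected mortality; "
            "their relative ranking is a tie",
            stacklevel=2,
        )
    return RiskVector(curves.subject_ids, phi, label="ExpMort")


def _resolved_offset(grid: TimeGrid, policy: ImproperPolicy) -> float:
    if policy.drop_offset is not None:
        return float(policy.drop_offset)
    if len(grid) > 1:
        return float(np.diff(grid.times).min())
    return float(grid.times[0])


def drop_to_zero(curves: SurvivalCurveMatrix, policy: ImproperPolicy = ImproperPolicy("drop")) -> SurvivalCurveMatrix:
    """Append one grid point just past the study end with survival 0 for every row.

    All remaining probability mass of an improper row is placed at
    ``last grid time + drop_offset``; rows already at 0 gain the same grid
    point but their implied distribution is unchanged.
    """
    validate_curves(curves)
    if policy.mode != "drop":
        raise DataValidationError(f"drop_to_zero requires a 'drop' policy, got {policy.mode!r}")
    t_end = curves.grid.times[-1] + _resolved_offset(curves.grid, policy)
    grid = TimeGrid(np.append(curves.grid.times, t_end))
    probs = np.hstack([curves.probabilities, np.zeros((curves.n_subjects, 1))])
    return SurvivalCurveMatrix(grid, probs, curves.subject_ids)


def linear_extrapolate(curves: SurvivalCurveMatrix) -> SurvivalCurveMatrix:
    """Extend each improper row linearly from (0, 1) through its last point to 0.

    The line through (0, 1) and (t_K, S(t_K)) crosses zero at
    t_zero = t_K / (1 - S(t_K)).  Grid points are appended beyond t_K at the
    grid's median spacing up to the largest zero crossing, with every row's
    own zero crossing included, and each row follows its clipped line on the
    appended points.  Rows already at 0 are unchanged in distribution;
    pre-existing grid points are never modified.  A shallow curve produces a
    very distant zero crossing — the reason this policy can yield
    unrealistically large survival-time summaries.
    """
    validate_curves(curves)
    t_k = curves.grid.times[-1]
    s_k = curves.probabilities[:, -1]
    flat = s_k >= 1.0
    if flat.any():
        raise ImproperCurveError(
            f"cannot extrapolate a flat curve (rows {np.flatnonzero(flat)[:5].tolist()} "
            "end at survival 1)"
        )
    improper = s_k > 0
    if not improper.any():
        return curves

    # each improper row's line has slope -(1 - s_k)/t_k from (0, 1)
    with np.errstate(divide="ignore"):
        t_zero = np.where(improper, t_k / (1.0 - s_k), t_k)
    spacing = float(np.median(np.diff(curves.grid.times))) if len(curves.grid) > 1 else t_k
    new_times = np.arange(t_k + spacing, t_zero.max(), spacing)
    new_times = np.unique(np.concatenate([new_times, t_zero[improper]]))
    new_times = new_times[new_times > t_k]

    slope = (1.0 - s_k) / t_k  # decay rate of each row's line
    appended = np.clip(1.0 - np.outer(slope, new_times), 0.0, None)
    appended[~improper] = 0.0
    grid = TimeGrid(np.concatenate([curves.grid.times, new_times]))
    probs = np.hstack([curves.probabilities, appended])
    return validate_curves(SurvivalCurveMatrix(grid, probs, curves.subject_ids))


def _apply_policy(curves: SurvivalCurveMatrix, policy: ImproperPolicy) -> SurvivalCurveMatrix:
    if policy.mode == "naive":
        return curves
    if policy.mode == "drop":
        return drop_to_zero(curves, policy)
    return linear_extrapolate(curves)


def curve_summary(
    curves: SurvivalCurveMatrix,
    stat: SummaryStatistic = SummaryStatistic("mean"),
    policy: ImproperPolicy = ImproperPolicy("naive"),
) -> RiskVector:
    """Reduce curves to risks via a location summary of the implied distribution.

    The discrete mass at grid point t_k is S(t_{k-1}) - S(t_k) with S = 1
    before the grid.  The mean is the unnormalised sum over the grid,
    sum_k t_k * mass_k: for a proper row the masses sum to 1 and this is the
    distribution mean; for an improper row under ``naive`` part of the mass
    is simply missing, which is exactly the pathology that corrupts naive
    summary concordances.  The median is the smallest grid time with
    S <= 0.5; under ``naive`` it is undefined when the curve never reaches
    0.5, and that is an error rather than a silent imputation.

    risk_i = -statistic (longer predicted survival = lower risk).
    """
    validate_curves(curves)
    fixed = _apply_policy(curves, policy)
    times = fixed.grid.times
    probs = fixed.probabilities

    if stat.kind == "mean":
        mass = np.hstack([1.0 - probs[:, :1], -np.diff(probs, axis=1)])
        value = mass @ times
    else:
        reaches = probs <= 0.5
        undefined = ~reaches.any(axis=1)
        if undefined.any():
            rows = np.flatnonzero(undefined)[:5].tolist()
            raise ImproperCurveError(
                f"median undefined for improper row(s) {rows}: survival never "
                "reaches 0.5 within the window under the naive policy"
            )
        value = times[reaches.argmax(axis=1)]

    return RiskVector(
        fixed.subject_ids, -value, label=f"Summary({stat.kind},{policy.mode})"
    )
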