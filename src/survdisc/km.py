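"""Kaplan–Meier product-limit estimation.

Implements the discrete product-limit estimator

    S(t) = 1                                   for t < t(1)
    S(t) = prod_{i: t(i) <= t} (1 - d_i / n_i) for t >= t(1)

over the ordered distinct event times t(i), with d_i events and n_i subjects
at risk at t(i).  At a tied event/censoring time, events are processed
before censorings (the standard convention): a subject censored at t(i)
still counts as at risk for the event at t(i).

The same estimator applied with the status flipped yields the censoring
survival function G(t), the IPCW denominator used by Uno's concordance.
"""

from __future__ import annotations

import numpy as np

from .data import SurvivalCurveMatrix, SurvivalOutcomes, TimeGrid
from .exceptions import DataValidationError

__all__ = ["kaplan_meier", "censoring_km"]


def kaplan_meier(outcomes: SurvivalOutcomes, label: str = "KM") -> SurvivalCurveMatrix:
    """Kaplan–Meier estimate of the survival function as a single-row curve.

    The grid is the distinct observed event times; when no events exist the
    grid collapses to the largest observed time with S identically 1.  If
    any subject remains at risk after the last event (in particular when the
    largest observed time is censored), the estimate plateaus above 0 — an
    "improper" survival distribution.
    """
    times = outcomes.time
    status = outcomes.status

    event_times = np.unique(times[status == 1])
    if event_times.size == 0:
        # no events: the estimator never steps down
        grid = TimeGrid(np.array([times.max()]))
        return SurvivalCurveMatrix(grid, np.ones((1, 1)), np.array([label]))

    # at risk at t: everyone with observed time >= t (ties: events first)
    n_at_risk = np.array([(times >= t).sum() for t in event_times])
    d = np.array([((times == t) & (status == 1)).sum() for t in event_times])
    surv = np.cumprod(1.0 - d / n_at_risk)

    grid = TimeGrid(event_times)
    return SurvivalCurveMatrix(grid, surv[np.newaxis, :], np.array([label]))


def censoring_km(outcomes: SurvivalOutcomes) -> SurvivalCurveMatrix:
    """Kaplan–Meier estimate G(t) of the censoring survival function.

    Exactly :func:`kaplan_meier` with the status flipped, so censorings play
    the role of events.  G never reaching 0 is the usual (proper) situation.
    """
    if len(outcomes) == 0:
        raise DataValidationError("outcomes must contain at least one subject")
    return kaplan_meier(outcomes.flip_status(), label="G")
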