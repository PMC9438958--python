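"""Core domain types for right-censored outcomes and survival-curve predictions.

The central objects are:

* :class:`SurvivalOutcomes` — observed (time, status) pairs per subject,
  where status 1 means the event was observed and 0 means the subject was
  censored at that time.
* :class:`TimeGrid` — the shared, strictly increasing sequence of times at
  which survival probabilities are predicted.
* :class:`SurvivalCurveMatrix` — an M x K matrix of predicted survival
  probabilities, one row per subject over a shared grid.  Rows are treated
  as right-continuous step functions: S = 1 strictly before the first grid
  point, the value at the largest grid time <= t inside the grid, and the
  last value carried forward beyond it.
* :class:`RiskVector` — one relative risk per subject with an orientation
  contract: a strictly larger risk means a strictly higher predicted hazard
  of the event.  Every risk vector carries a label naming how it was
  produced, so no downstream number can lose its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, IdAlignmentError

__all__ = [
    "SurvivalOutcomes",
    "TimeGrid",
    "SurvivalCurveMatrix",
    "RiskVector",
    "validate_curves",
    "step_survival",
    "step_survival_all",
]


def _as_id_array(ids) -> np.ndarray:
    arr = np.asarray(ids)
    if arr.ndim != 1:
        raise DataValidationError("subject ids must be one-dimensional")
    if len(np.unique(arr)) != arr.size:
        raise DataValidationError("subject ids must be unique")
    return arr


@dataclass(frozen=True)
class SurvivalOutcomes:
    """Observed right-censored outcomes (T_i, delta_i) for M subjects."""

    subject_id: np.ndarray
    time: np.ndarray
    status: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subject_id", _as_id_array(self.subject_id))
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        if time.shape != self.subject_id.shape or status.shape != time.shape:
            raise DataValidationError("id, time and status must have equal length")
        if time.size == 0:
            raise DataValidationError("outcomes must contain at least one subject")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise DataValidationError("all outcome times must be strictly positive and finite")
        if not np.isin(status, (0, 1)).all():
            raise DataValidationError("status must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(int))

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def flip_status(self) -> "SurvivalOutcomes":
        """Swap the roles of events and censorings (used for censoring-distribution estimation)."""
        return SurvivalOutcomes(self.subject_id, self.time, 1 - self.status)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.subject_id, "time": self.time, "status": self.status}
        )


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sequence of K positive prediction times."""

    times: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise DataValidationError("time grid must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(times)) or times[0] <= 0:
            raise DataValidationError("grid times must be positive and finite")
        if np.any(np.diff(times) <= 0):
            raise DataValidationError("grid times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SurvivalCurveMatrix:
    """Predicted survival probabilities, one row per subject over a shared grid.

    Construction checks only shape consistency; numeric invariants (range,
    row monotonicity, NaN) are checked by :func:`validate_curves`, which
    every consuming operation calls on entry.
    """

    grid: TimeGrid
    probabilities: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        probs = np.atleast_2d(np.asarray(self.probabilities, dtype=float))
        ids = _as_id_array(self.subject_ids)
        if probs.shape[1] != len(self.grid):
            raise DataValidationError(
                f"matrix has {probs.shape[1]} columns but grid has {len(self.grid)} times"
            )
        if probs.shape[0] != ids.size:
            raise DataValidationError(
                f"matrix has {probs.shape[0]} rows but {ids.size} subject ids"
            )
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n_subjects(self) -> int:
        return self.probabilities.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=self.grid.times)
        df.insert(0, "id", self.subject_ids)
        return df


@dataclass(frozen=True)
class RiskVector:
    """One relative risk per subject; higher risk = higher predicted hazard.

    +inf entries are legal (a curve that hits zero survival accrues infinite
    cumulative hazard); -inf and NaN are not.  The label must name the
    measure/transformation that produced the risks.
    """

    subject_ids: np.ndarray
    risk: np.ndarray
    label: str

    def __post_init__(self):
        ids = _as_id_array(self.subject_ids)
        risk = np.asarray(self.risk, dtype=float)
        if risk.shape != ids.shape:
            raise DataValidationError("risk vector and ids must have equal length")
        if np.any(np.isnan(risk)) or np.any(np.isneginf(risk)):
            raise DataValidationError("risks must be finite or +inf (NaN and -inf forbidden)")
        if not self.label:
            raise DataValidationError("risk vector label must be non-empty")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "risk", risk)

    def __len__(self) -> int:
        return self.risk.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.subject_ids, "risk": self.risk})


def validate_curves(curves: SurvivalCurveMatrix) -> SurvivalCurveMatrix:
    """Check the numeric invariants of a curve matrix and return it unchanged.

    Raises :class:`DataValidationError` naming the offending row/column for
    NaN entries, probabilities outside [0, 1], or a row that increases
    anywhere (an increasing survival function is impossible).
    """
    probs = curves.probabilities
    nan = np.argwhere(np.isnan(probs))
    if nan.size:
        r, c = nan[0]
        raise DataValidationError(f"NaN survival probability at row {r}, column {c}")
    bad = np.argwhere((probs < 0) | (probs > 1))
    if bad.size:
        r, c = bad[0]
        raise DataValidationError(
            f"out of range survival probability {probs[r, c]} at row {r}, column {c}"
        )
    inc = np.argwhere(np.diff(probs, axis=1) > 0)
    if inc.size:
        r, c = inc[0]
        raise DataValidationError(
            f"non-monotone survival curve: row {r} increases between columns {c} and {c + 1}"
        )
    return curves


def _step_eval(grid_times: np.ndarray, values: np.ndarray, t: float, left: bool = False) -> np.ndarray:
    """Evaluate right-continuous step rows at scalar time ``t``.

    ``values`` may be 1-d (single curve) or 2-d (matrix; evaluated per row).
    With ``left=True`` the left limit is returned: the value just before
    ``t``, i.e. at the largest grid time strictly below ``t``.
    """
    side = "left" if left else "right"
    k = np.searchsorted(grid_times, t, side=side) - 1
    if k < 0:
        shape = values.shape[:-1]
        return np.ones(shape) if shape else np.float64(1.0)
    return values[..., k]


def step_survival(curves: SurvivalCurveMatrix, subject_index: int, t: float) -> float:
    """Predicted survival probability for one subject at an arbitrary time.

    Right-continuous step interpolation of the discrete matrix: 1 before the
    first grid time, last column carried forward past the grid.
    """
    if t < 0:
        raise DataValidationError(f"evaluation time must be non-negative, got {t}")
    if not 0 <= subject_index < curves.n_subjects:
        raise IndexError(f"subject index {subject_index} out of range")
    return float(_step_eval(curves.grid.times, curves.probabilities[subject_index], t))


def step_survival_all(curves: SurvivalCurveMatrix, t: float) -> np.ndarray:
    """Vector of predicted survival probabilities for every subject at time ``t``."""
    if t < 0:
        raise DataValidationError(f"evaluation time must be non-negative, got {t}")
    return np.asarray(_step_eval(curves.grid.times, curves.probabilities, t), dtype=float)


def align_by_id(outcomes: SurvivalOutcomes, other_ids: np.ndarray, what: str) -> np.ndarray:
    """Indices into ``other_ids`` matching the order of ``outcomes.subject_id``.

    Alignment is by id join, never by row order; any id present on one side
    only is an error, not a silent reindex.
    """
    other_ids = np.asarray(other_ids)
    pos = {v: i for i, v in enumerate(other_ids)}
    missing = [v for v in outcomes.subject_id if v not in pos]
    if missing or other_ids.size != len(outcomes):
        extra = sorted(set(map(str, other_ids)) - set(map(str, outcomes.subject_id)))
        raise IdAlignmentError(
            f"subject ids do not match between outcomes and {what}: "
            f"missing {missing[:5]}, unexpected {extra[:5]}"
        )
    return np.array([pos[v] for v in outcomes.subject_id])
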