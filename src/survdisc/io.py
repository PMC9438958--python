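"""CSV input/output for outcomes, curve matrices and risk vectors.

File layouts:

* outcomes:  columns ``id,time,status`` with status in {0, 1}
* curves:    first column ``id``; remaining column headers are the grid
             times in increasing order; cells are survival probabilities
* risks:     columns ``id,risk``

Times are unitless reals; no date parsing is attempted.  All readers
validate the parsed object before returning it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    RiskVector,
    SurvivalCurveMatrix,
    SurvivalOutcomes,
    TimeGrid,
    validate_curves,
)
from .exceptions import DataValidationError

__all__ = [
    "read_outcomes",
    "read_curves",
    "read_risks",
    "write_outcomes",
    "write_curves",
    "write_risks",
]


def _read_csv(path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataValidationError(f"{path}: missing column(s) {missing}")
    return df


def read_outcomes(path) -> SurvivalOutcomes:
    df = _read_csv(path, required=["id", "time", "status"])
    try:
        time = pd.to_numeric(df["time"]).to_numpy(dtype=float)
        status = pd.to_numeric(df["status"]).to_numpy()
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"{path}: non-numeric time/status: {exc}") from exc
    return SurvivalOutcomes(df["id"].to_numpy(), time, status)


def read_curves(path) -> SurvivalCurveMatrix:
    df = _read_csv(path)
    if df.columns[0] != "id":
        raise DataValidationError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    try:
        grid_times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DataValidationError(f"{path}: non-numeric grid time in header: {exc}") from exc
    if grid_times.size == 0:
        raise DataValidationError(f"{path}: no grid columns")
    if np.any(np.diff(grid_times) <= 0):
        raise DataValidationError(f"{path}: grid times in header are not strictly increasing")
    try:
        probs = df.iloc[:, 1:].apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"{path}: non-numeric survival probability: {exc}") from exc
    curves = SurvivalCurveMatrix(TimeGrid(grid_times), probs, df["id"].to_numpy())
    return validate_curves(curves)


def read_risks(path, label: str | None = None) -> RiskVector:
    df = _read_csv(path, required=["id", "risk"])
    try:
        risk = pd.to_numeric(df["risk"]).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"{path}: non-numeric risk: {exc}") from exc
    return RiskVector(df["id"].to_numpy(), risk, label or f"risk:{Path(path).name}")


def write_outcomes(outcomes: SurvivalOutcomes, path) -> None:
    outcomes.to_frame().to_csv(path, index=False)


def write_curves(curves: SurvivalCurveMatrix, path) -> None:
    df = curves.to_frame()
    df.columns = ["id"] + [repr(float(t)) for t in curves.grid.times]
    df.to_csv(path, index=False)


def write_risks(risks: RiskVector, path) -> None:
    risks.to_frame().to_csv(path, index=False)
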