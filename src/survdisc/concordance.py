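"""Time-independent concordance: comparable pairs, Harrell's C, Uno's IPCW C.

An ordered pair of subjects (i, j) is *comparable* when T_i < T_j and
subject i's event was observed (delta_i = 1): we then know i failed before
j.  A risk vector is *concordant* on the pair when phi_i > phi_j.  Harrell's
C is the proportion of concordant pairs among comparable pairs, with risk
ties credited 1/2.  Uno's C reweights each comparable pair by
G(T_i-)^{-2}, the inverse squared Kaplan–Meier estimate of the censoring
survival just before T_i, which removes the censoring-distribution bias of
Harrell's C; with no censoring the two coincide exactly.

Pairs with tied outcome times are never comparable (strict inequality),
including event–event ties; some other implementations credit such pairs —
a documented divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import RiskVector, SurvivalOutcomes, align_by_id, _step_eval
from .exceptions import DataValidationError, UndefinedMeasureError
from .km import censoring_km

__all__ = ["PairSet", "ConcordanceResult", "comparable_pairs", "harrell_c", "uno_c"]


@dataclass(frozen=True)
class PairSet:
    """Ordered comparable pairs (i, j): T_i < T_j and delta_i = 1."""

    pairs: np.ndarray  # (n, 2) int indices
    count: int


@dataclass(frozen=True)
class ConcordanceResult:
    """A concordance value that cannot be separated from what produced it.

    ``measure_label`` names the index (e.g. "Harrell's C"); ``transform_label``
    names the reduction applied to obtain the risks ("native" when none).
    """

    value: float
    n_comparable: int
    n_concordant: float  # ties counted 1/2
    measure_label: str
    transform_label: str

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise DataValidationError(f"concordance {self.value} outside [0, 1]")
        if not self.measure_label or not self.transform_label:
            raise DataValidationError("measure and transform labels must be non-empty")

    def __str__(self) -> str:
        return (
            f"{self.measure_label} [{self.transform_label}] = {self.value:.3f} "
            f"({self.n_concordant:g}/{self.n_comparable} pairs)"
        )


def comparable_pairs(outcomes: SurvivalOutcomes, tau: float | None = None) -> PairSet:
    """All ordered pairs (i, j) with T_i < T_j and delta_i = 1.

    With ``tau`` given, pairs are additionally restricted to T_i < tau (the
    truncation used by Uno's C).
    """
    n = len(outcomes)
    if n < 2:
        raise DataValidationError("need at least 2 subjects to form pairs")
    t, d = outcomes.time, outcomes.status
    ii, jj = np.nonzero((t[:, None] < t[None, :]) & (d[:, None] == 1))
    if tau is not None:
        keep = t[ii] < tau
        ii, jj = ii[keep], jj[keep]
    pairs = np.column_stack([ii, jj])
    return PairSet(pairs=pairs, count=pairs.shape[0])


def _pair_concordance(phi_i: np.ndarray, phi_j: np.ndarray) -> np.ndarray:
    """Per-pair concordance credit: 1 if phi_i > phi_j, 1/2 on ties (incl. +inf vs +inf)."""
    credit = np.where(phi_i > phi_j, 1.0, 0.0)
    tied = (phi_i == phi_j) | (np.isposinf(phi_i) & np.isposinf(phi_j))
    return np.where(tied, 0.5, credit)


def harrell_c(outcomes: SurvivalOutcomes, risk: RiskVector) -> ConcordanceResult:
    """Harrell's concordance index on comparable pairs, ties at 1/2."""
    idx = align_by_id(outcomes, risk.subject_ids, "risks")
    phi = risk.risk[idx]
    ps = comparable_pairs(outcomes)
    if ps.count == 0:
        raise UndefinedMeasureError("concordance undefined: no comparable pairs")
    credit = _pair_concordance(phi[ps.pairs[:, 0]], phi[ps.pairs[:, 1]])
    n_conc = float(credit.sum())
    return ConcordanceResult(
        value=n_conc / ps.count,
        n_comparable=ps.count,
        n_concordant=n_conc,
        measure_label="Harrell's C",
        transform_label=risk.label,
    )


def uno_c(
    outcomes: SurvivalOutcomes, risk: RiskVector, tau: float | None = None
) -> ConcordanceResult:
    """Uno's IPCW concordance index.

    Each comparable pair with T_i < tau is weighted by G(T_i-)^{-2} where G
    is the Kaplan–Meier censoring survival estimate (left limit, so a
    subject is not weighted by its own censoring step).  ``tau`` defaults to
    the largest observed event time.  Reduces exactly to Harrell's C
    restricted to T_i < tau when no subject is censored.
    """
    idx = align_by_id(outcomes, risk.subject_ids, "risks")
    phi = risk.risk[idx]
    if tau is None:
        if outcomes.n_events == 0:
            raise UndefinedMeasureError("concordance undefined: no observed events")
        tau = float(outcomes.time[outcomes.status == 1].max())
    ps = comparable_pairs(outcomes, tau=tau)
    if ps.count == 0:
        raise UndefinedMeasureError("concordance undefined: no comparable pairs below tau")

    G = censoring_km(outcomes)
    g_times, g_vals = G.grid.times, G.probabilities[0]
    ti = outcomes.time[ps.pairs[:, 0]]
    g_left = np.array([float(_step_eval(g_times, g_vals, t, left=True)) for t in ti])
    if np.any(g_left <= 0):
        raise UndefinedMeasureError(
            "censoring survival estimate is 0 at an event time below tau; "
            "choose a smaller tau"
        )
    w = g_left**-2
    credit = _pair_concordance(phi[ps.pairs[:, 0]], phi[ps.pairs[:, 1]])
    return ConcordanceResult(
        value=float((w * credit).sum() / w.sum()),
        n_comparable=ps.count,
        n_concordant=float(credit.sum()),
        measure_label="Uno's C",
        transform_label=risk.label,
    )
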