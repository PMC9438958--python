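"""Time-dependent discrimination: Antolini's C and cumulative/dynamic AUC.

Antolini's concordance compares *distribution* predictions directly: a
comparable pair (T_i < T_j, delta_i = 1) is concordant when the predicted
survival probability of the earlier failer is lower at the earlier outcome
time, S_i(T_i) < S_j(T_i).  No reduction to a single risk is involved, so
the measure applies only to models that predict survival curves — its
values are not comparable with risk-based concordances.

The cumulative/dynamic AUC at cutoff t discriminates *cases* (subjects with
an observed event by t) from *controls* (subjects still event-free past t)
using a single risk per subject; the estimator here is the plain empirical
rank statistic (the Mann–Whitney form of the integral of the time-dependent
ROC curve), named explicitly in the result label.  Weighting the
incident/dynamic AUC over the event times by the Kaplan–Meier plug-in
weights 2*f(t)*S(t) yields a concordance estimate, which is how the AUC
family connects back to C (see :func:`integrated_auc`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concordance import ConcordanceResult, _pair_concordance, comparable_pairs
from .data import (
    RiskVector,
    SurvivalCurveMatrix,
    SurvivalOutcomes,
    align_by_id,
    step_survival_all,
    validate_curves,
)
from .exceptions import UndefinedMeasureError
from .km import kaplan_meier

__all__ = ["AucCurve", "antolini_c", "cumulative_dynamic_auc", "integrated_auc"]


@dataclass(frozen=True)
class AucCurve:
    """AUC(t) evaluated on a sequence of cutoffs, with case/control counts."""

    times: np.ndarray
    auc: np.ndarray
    n_cases: np.ndarray
    n_controls: np.ndarray


def antolini_c(outcomes: SurvivalOutcomes, curves: SurvivalCurveMatrix) -> ConcordanceResult:
    """Antolini's time-dependent concordance on survival-curve predictions.

    Over comparable pairs, concordance credit is 1 when S_i(T_i) < S_j(T_i)
    (step-function evaluation), 1/2 on ties.  Observed times before the
    first grid point evaluate both curves to 1 and therefore tie.
    """
    validate_curves(curves)
    idx = align_by_id(outcomes, curves.subject_ids, "curves")
    probs = curves.probabilities[idx]
    aligned = SurvivalCurveMatrix(curves.grid, probs, outcomes.subject_id)

    ps = comparable_pairs(outcomes)
    if ps.count == 0:
        raise UndefinedMeasureError("concordance undefined: no comparable pairs")
    credit = np.empty(ps.count)
    # evaluate S_.(T_i) once per distinct earlier-failer
    for i in np.unique(ps.pairs[:, 0]):
        sel = ps.pairs[:, 0] == i
        s_at_ti = step_survival_all(aligned, float(outcomes.time[i]))
        # lower survival for the earlier failer is the concordant direction
        credit[sel] = _pair_concordance(-s_at_ti[i], -s_at_ti[ps.pairs[sel, 1]])
    n_conc = float(credit.sum())
    return ConcordanceResult(
        value=n_conc / ps.count,
        n_comparable=ps.count,
        n_concordant=n_conc,
        measure_label="Antolini's C",
        transform_label="distribution",
    )


def cumulative_dynamic_auc(outcomes: SurvivalOutcomes, risk: RiskVector, t: float) -> float:
    """Empirical cumulative/dynamic AUC at cutoff ``t``.

    Cases are subjects with an observed event by t (T_i <= t, delta_i = 1),
    controls are subjects with T_j > t.  The value is the proportion of
    case/control pairs ranked correctly by risk, ties at 1/2.
    """
    idx = align_by_id(outcomes, risk.subject_ids, "risks")
    phi = risk.risk[idx]
    cases = (outcomes.time <= t) & (outcomes.status == 1)
    controls = outcomes.time > t
    if not cases.any() or not controls.any():
        raise UndefinedMeasureError(f"AUC undefined at t={t}: no cases or no controls")
    pc, pk = phi[cases], phi[controls]
    credit = _pair_concordance(pc[:, None], pk[None, :])
    return float(credit.mean())


def auc_curve(outcomes: SurvivalOutcomes, risk: RiskVector, times: np.ndarray) -> AucCurve:
    """AUC(t) at each requested cutoff where it is defined."""
    ts, aucs, ncase, nctrl = [], [], [], []
    for t in np.asarray(times, dtype=float):
        cases = (outcomes.time <= t) & (outcomes.status == 1)
        controls = outcomes.time > t
        if not cases.any() or not controls.any():
            continue
        ts.append(t)
        aucs.append(cumulative_dynamic_auc(outcomes, risk, t))
        ncase.append(int(cases.sum()))
        nctrl.append(int(controls.sum()))
    return AucCurve(np.array(ts), np.array(aucs), np.array(ncase), np.array(nctrl))


def integrated_auc(outcomes: SurvivalOutcomes, risk: RiskVector) -> ConcordanceResult:
    """Concordance estimate from the weighted integral of the time-dependent AUC.

    The identity C = int 2 f(t) S(t) AUC(t) dt holds for the
    *incident*/dynamic AUC — cases are the subjects failing exactly at t,
    controls those surviving past t — so that is the estimator integrated
    here: AUC(t_k) over the distinct event times t_k, weighted by
    w_k proportional to 2 * f(t_k) * S(t_k) with f the Kaplan–Meier
    probability mass at t_k and S the Kaplan–Meier survival just past t_k,
    normalised to sum to 1.  On uncensored data the weights reduce to the
    comparable-pair counts and the value equals Harrell's C exactly; with
    one event time it reduces to the single cumulative/dynamic AUC.
    """
    event_times = np.unique(outcomes.time[outcomes.status == 1])
    if event_times.size == 0:
        raise UndefinedMeasureError("no observed events: integrated AUC undefined")

    idx = align_by_id(outcomes, risk.subject_ids, "risks")
    phi = risk.risk[idx]
    km = kaplan_meier(outcomes)
    km_t, km_s = km.grid.times, km.probabilities[0]
    s_after = np.interp(event_times, km_t, km_s)  # KM grid == event times, right-continuous value
    s_before = np.concatenate([[1.0], s_after[:-1]])
    mass = s_before - s_after

    ts, aucs, ws = [], [], []
    for t, f_t, s_t in zip(event_times, mass, s_after):
        cases = (outcomes.time == t) & (outcomes.status == 1)
        controls = outcomes.time > t
        if not cases.any() or not controls.any():
            continue
        credit = _pair_concordance(phi[cases][:, None], phi[controls][None, :])
        ts.append(t)
        aucs.append(float(credit.mean()))
        ws.append(2.0 * f_t * s_t)
    if not ts:
        raise UndefinedMeasureError("no event time with a defined AUC")
    w = np.array(ws)
    if w.sum() <= 0:
        raise UndefinedMeasureError("all integration weights are zero")
    w = w / w.sum()
    value = float(w @ np.array(aucs))
    n_pairs = comparable_pairs(outcomes).count
    return ConcordanceResult(
        value=value,
        n_comparable=n_pairs,
        n_concordant=value * n_pairs,
        measure_label="Integrated AUC (incident/dynamic, KM-weighted)",
        transform_label=risk.label,
    )
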