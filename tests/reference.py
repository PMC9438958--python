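"""Brute-force reference implementations used as independent oracles.

Each function is a direct transliteration of the defining formula as an
explicit loop over subjects/pairs, with no vectorisation and no shared code
with the package under test.
"""

import math


def brute_km(times, status):
    """Product-limit estimator by explicit loop; returns (event_times, survival)."""
    event_times = sorted({t for t, d in zip(times, status) if d == 1})
    surv, s = [], 1.0
    for et in event_times:
        n_at_risk = sum(1 for t in times if t >= et)
        d_at = sum(1 for t, d in zip(times, status) if t == et and d == 1)
        s *= 1.0 - d_at / n_at_risk
        surv.append(s)
    return event_times, surv


def _km_step(event_times, surv, t, left=False):
    """Evaluate the step function at t (left=True gives the left limit)."""
    value = 1.0
    for et, s in zip(event_times, surv):
        if (et < t) if left else (et <= t):
            value = s
        else:
            break
    return value


def _credit(a, b):
    if a == b or (math.isinf(a) and math.isinf(b) and a > 0 and b > 0):
        return 0.5
    return 1.0 if a > b else 0.0


def brute_harrell(times, status, phi):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i != j and times[i] < times[j] and status[i] == 1:
                den += 1
                num += _credit(phi[i], phi[j])
    return num / den


def brute_uno(times, status, phi, tau):
    """IPCW concordance with pair weight G(T_i-)^-2, G the censoring KM."""
    g_times, g_surv = brute_km(times, [1 - d for d in status])
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i != j and times[i] < times[j] and status[i] == 1 and times[i] < tau:
                g = _km_step(g_times, g_surv, times[i], left=True)
                w = g**-2
                den += w
                num += w * _credit(phi[i], phi[j])
    return num / den


def brute_antolini(times, status, grid, probs):
    """Time-dependent concordance comparing S_i(T_i) vs S_j(T_i) per pair."""

    def step(row, t):
        value = 1.0
        for gt, p in zip(grid, row):
            if gt <= t:
                value = p
            else:
                break
        return value

    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i != j and times[i] < times[j] and status[i] == 1:
                den += 1
                si = step(probs[i], times[i])
                sj = step(probs[j], times[i])
                num += _credit(-si, -sj)
    return num / den


def brute_auc(times, status, phi, cutoff):
    """Cumulative/dynamic AUC as an explicit case/control double loop."""
    cases = [i for i in range(len(times)) if times[i] <= cutoff and status[i] == 1]
    controls = [j for j in range(len(times)) if times[j] > cutoff]
    num = 0.0
    for i in cases:
        for j in controls:
            num += _credit(phi[i], phi[j])
    return num / (len(cases) * len(controls))
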