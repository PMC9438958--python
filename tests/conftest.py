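import numpy as np
import pytest

import survdisc as sd


@pytest.fixture
def three_events():
    """Three subjects, all events, at times 1 < 2 < 3."""
    return sd.SurvivalOutcomes([1, 2, 3], [1.0, 2.0, 3.0], [1, 1, 1])


@pytest.fixture
def small_curves():
    """Two subjects over grid (10, 20): one steep, one shallow curve."""
    return sd.SurvivalCurveMatrix(
        sd.TimeGrid([10.0, 20.0]),
        np.array([[0.8, 0.6], [0.9, 0.85]]),
        np.array([1, 2]),
    )


@pytest.fixture(scope="session")
def ph_cohort():
    """Strong-signal uncensored PH cohort with true curves on a grid that
    starts below every observed time (so step evaluation never ties at 1)."""
    cfg = sd.PHSimConfig(n_subjects=300, beta=(1.0,), seed=42)
    cohort = sd.simulate_ph_cohort(cfg)
    t = cohort.outcomes.time
    grid = sd.TimeGrid(np.linspace(t.min() * 0.5, t.max(), 100))
    curves = sd.true_curve_matrix(cohort, grid)
    return cohort, curves


def random_instance(rng, n=None, censoring=True, tie_times=False):
    """A small random censored dataset with risks, for oracle comparisons."""
    n = n or int(rng.integers(4, 31))
    if tie_times:
        t = rng.integers(1, 8, size=n).astype(float)
    else:
        t = rng.exponential(10.0, size=n)
    d = rng.integers(0, 2, size=n) if censoring else np.ones(n, dtype=int)
    if d.sum() == 0:
        d[int(np.argmin(t))] = 1
    phi = rng.normal(size=n)
    return t, d, phi
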