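import numpy as np
import pytest

from drsf.evaluation import (
    bootstrap_ci,
    cumulative_dynamic_auc,
    evaluate_markers,
    harrell_c,
)
from drsf.exceptions import UndefinedMetricError


# --- brute-force oracles ----------------------------------------------------

def brute_harrell(markers, times, events):
    conc = comp = 0.0
    n = len(markers)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                comp += 1
                if markers[i] > markers[j]:
                    conc += 1
                elif markers[i] == markers[j]:
                    conc += 0.5
    return conc / comp


def brute_auc_uncensored(markers, times, events, horizon):
    cases = [i for i in range(len(markers)) if times[i] <= horizon and events[i]]
    ctrls = [i for i in range(len(markers)) if times[i] > horizon or (times[i] == horizon and not events[i])]
    num = 0.0
    for i in cases:
        for j in ctrls:
            if markers[i] > markers[j]:
                num += 1
            elif markers[i] == markers[j]:
                num += 0.5
    return num / (len(cases) * len(ctrls))


# --- Harrell's C ------------------------------------------------------------

def test_harrell_perfect_concordance():
    assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0


def test_harrell_pair_enumeration_example():
    # comparable pairs (1,2) and (1,3); both concordant
    assert harrell_c([3, 1, 2], [1, 2, 3], [1, 0, 1]) == 1.0


def test_harrell_null_marker_near_half(rng):
    n = 2000
    times = rng.integers(1, 180, n)
    events = rng.random(n) < 0.5
    markers = rng.standard_normal(n)
    assert 0.47 <= harrell_c(markers, times, events) <= 0.53


def test_harrell_reversal_identity(rng):
    for _ in range(10):
        n = 25
        m = rng.standard_normal(n)  # continuous: tie-free
        t = rng.permutation(n) + 1.0
        e = (rng.random(n) < 0.7).astype(int)
        if not e.any():
            continue
        assert harrell_c(m, t, e) + harrell_c(-m, t, e) == pytest.approx(1.0, abs=1e-12)


def test_harrell_agrees_with_lifelines_on_distinct_times(rng):
    from lifelines.utils import concordance_index

    for _ in range(10):
        n = 40
        t = rng.permutation(n) + 1.0
        m = rng.standard_normal(n)
        e = (rng.random(n) < 0.6).astype(int)
        if not e.any():
            continue
        assert harrell_c(m, t, e) == pytest.approx(1.0 - concordance_index(t, m, e), abs=1e-12)


def test_harrell_undefined_cases():
    with pytest.raises(UndefinedMetricError):
        harrell_c([1, 2], [5, 6], [0, 0])
    with pytest.raises(UndefinedMetricError):
        harrell_c([1, 2], [5, 5], [1, 1])  # tied times: no comparable pair


# --- time-dependent AUC -----------------------------------------------------

def test_auc_perfect_separation():
    auc = cumulative_dynamic_auc([0.9, 0.8, 0.1, 0.2], [30, 50, 200, 210], [1, 1, 1, 1], 60)
    assert auc == 1.0


def test_auc_constant_marker_is_half():
    auc = cumulative_dynamic_auc([1.0] * 6, [10, 20, 30, 100, 200, 300], [1, 1, 1, 1, 1, 1], 60)
    assert auc == 0.5


def test_auc_matches_brute_force_without_censoring(rng):
    for _ in range(20):
        n = 30
        t = rng.integers(1, 200, n).astype(float)
        m = rng.standard_normal(n)
        e = np.ones(n, dtype=int)
        if not ((t <= 90) & (e == 1)).any() or not (t > 90).any():
            continue
        assert cumulative_dynamic_auc(m, t, e, 90) == pytest.approx(
            brute_auc_uncensored(m, t, e, 90), abs=1e-12
        )


def test_auc_agrees_with_scikit_survival_under_censoring(rng):
    # independent-oracle check of the IPCW estimator under censoring; the
    # two implementations differ only in tie conventions (G evaluated at
    # t- here, and subjects censored exactly at the horizon kept as
    # controls), so agreement is to ~5e-3, exact when censoring is absent
    from sksurv.metrics import cumulative_dynamic_auc as sk_auc
    from sksurv.util import Surv

    for seed in range(5):
        r = np.random.default_rng(seed)
        n = 200
        t = r.integers(1, 180, n).astype(float)
        e = r.random(n) < 0.6
        e[t > 150] = True  # keep the censoring KM positive at all event times
        m = r.standard_normal(n) + 0.01 * t
        y = Surv.from_arrays(e, t)
        theirs = sk_auc(y, y, m, [100])[0][0]
        ours = cumulative_dynamic_auc(m, t, e, 100)
        assert ours == pytest.approx(theirs, abs=5e-3)

    # without censoring before the horizon the two agree exactly
    r = np.random.default_rng(10)
    t = r.integers(1, 180, 150).astype(float)
    e = np.ones(150, dtype=bool)
    m = r.standard_normal(150)
    theirs = sk_auc(Surv.from_arrays(e, t), Surv.from_arrays(e, t), m, [100])[0][0]
    assert cumulative_dynamic_auc(m, t, e, 100) == pytest.approx(theirs, abs=1e-12)


def test_auc_monotone_transform_invariance(rng):
    n = 50
    t = rng.integers(1, 200, n).astype(float)
    e = (rng.random(n) < 0.7).astype(int)
    m = rng.standard_normal(n)
    base = cumulative_dynamic_auc(m, t, e, 90)
    assert cumulative_dynamic_auc(np.exp(2 * m), t, e, 90) == pytest.approx(base, abs=1e-12)
    base_c = harrell_c(m, t, e)
    assert harrell_c(np.exp(2 * m), t, e) == pytest.approx(base_c, abs=1e-12)


def test_auc_undefined_without_cases_or_controls():
    with pytest.raises(UndefinedMetricError):
        cumulative_dynamic_auc([1, 2], [100, 150], [1, 1], 60)  # no cases by 60


# --- bootstrap --------------------------------------------------------------

def test_bootstrap_deterministic_under_seed(rng):
    n = 120
    t = rng.integers(1, 180, n).astype(float)
    e = (rng.random(n) < 0.4).astype(int)
    m = rng.standard_normal(n) - 0.01 * t
    a = bootstrap_ci(m, t, e, harrell_c, n_boot=500, seed=42)
    b = bootstrap_ci(m, t, e, harrell_c, n_boot=500, seed=42)
    assert a == b
    lo, hi = a
    assert lo <= harrell_c(m, t, e) <= hi


def test_bootstrap_degenerate_metric_constant():
    lo, hi = bootstrap_ci([5, 4, 1, 0], [1, 2, 100, 100], [1, 1, 0, 0],
                          harrell_c, n_boot=50, seed=1)
    assert lo == hi == 1.0


def test_evaluate_markers_composition(rng):
    n = 150
    t = rng.integers(1, 181, n).astype(float)
    e = (rng.random(n) < 0.4).astype(int)
    t[e == 0] = 180
    m = rng.standard_normal(n) - 0.01 * t
    report = evaluate_markers(m, t, e, horizons=(60, 180), n_boot=0)
    assert report.harrell_c == harrell_c(m, t, e)
    assert report.auc_by_horizon[60] == cumulative_dynamic_auc(m, t, e, 60)
    assert report.auc_by_horizon[180] == cumulative_dynamic_auc(m, t, e, 180)
    assert report.n_subjects == n and report.n_events == e.sum()


def test_auc_curve_skips_undefined_days(rng):
    from drsf.evaluation import auc_curve

    n = 100
    t = rng.integers(30, 181, n).astype(float)
    e = (rng.random(n) < 0.5).astype(int)
    t[e == 0] = 180
    m = -0.01 * t + rng.standard_normal(n) * 0.1
    curve = auc_curve(m, t, e, range(10, 181, 10))
    assert (curve["day"] >= 30).all()  # no cases before day 30
    assert curve["auc"].between(0, 1).all()
    for _, row in curve.iloc[:3].iterrows():
        assert row["auc"] == cumulative_dynamic_auc(m, t, e, row["day"])


def test_evaluate_markers_all_censored_surfaces_cleanly(rng):
    with pytest.raises(UndefinedMetricError):
        evaluate_markers([1.0, 2.0, 3.0], [180, 180, 180], [0, 0, 0], n_boot=0)
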