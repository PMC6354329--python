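import numpy as np
import pandas as pd
import pytest

from drsf.exceptions import ContractViolationError
from drsf.forest import (
    RandomSurvivalForest,
    TwoStepForestSelector,
    ensemble_mortality,
    fit_forest,
    fit_tree,
    logrank_split_statistic,
    nelson_aalen,
    predict_chf,
)
from drsf.simulate import STRONG_SIGNAL_FEATURES, simulate_survival_table, strong_signal_config

from conftest import random_survival_sample


# --- independent textbook oracles -----------------------------------------

def brute_logrank(times, events, mask):
    """Two-sample log-rank |O-E|/sqrt(V) straight from the formula."""
    times, events, mask = map(np.asarray, (times, events, mask))
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events.astype(bool)]):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & mask).sum()
        d = ((times == t) & events.astype(bool)).sum()
        d1 = ((times == t) & events.astype(bool) & mask).sum()
        if n > 1:
            o_minus_e += d1 - d * n1 / n
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if var <= 0 else abs(o_minus_e) / np.sqrt(var)


def brute_nelson_aalen(times, events):
    times, events = map(np.asarray, (times, events))
    grid = np.unique(times[events.astype(bool)])
    values = []
    h = 0.0
    for t in grid:
        h += ((times == t) & events.astype(bool)).sum() / (times >= t).sum()
        values.append(h)
    return grid, np.array(values)


# --- elemental operations ---------------------------------------------------

def test_logrank_hand_value():
    stat = logrank_split_statistic([1, 2, 3, 4], [1, 1, 1, 1], [True, False, True, False])
    assert stat == pytest.approx((2 / 3) / np.sqrt(13 / 18), abs=1e-12)


def test_logrank_symmetric_groups_zero():
    # paired duplicates: identical survival experience on both sides
    times = [1, 1, 4, 4, 7, 7]
    events = [1, 1, 0, 0, 1, 1]
    mask = [True, False, True, False, True, False]
    assert logrank_split_statistic(times, events, mask) == 0.0


def test_logrank_agrees_with_lifelines():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(7)
    for _ in range(20):
        times, events = random_survival_sample(rng)
        mask = rng.random(times.size) < 0.5
        if mask.all() or not mask.any():
            continue
        ours = logrank_split_statistic(times, events, mask)
        res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
        assert ours == pytest.approx(np.sqrt(res.test_statistic), abs=1e-8)


def test_logrank_validation():
    with pytest.raises(ValueError):
        logrank_split_statistic([1, 2], [1, 1], [True, True])
    with pytest.raises(ValueError):
        logrank_split_statistic([1, 2], [0, 0], [True, False])


def test_nelson_aalen_examples():
    single = nelson_aalen([5.0], [1])
    assert single(5) == 1.0 and single(4.9) == 0.0

    na = nelson_aalen([1, 2, 3], [1, 1, 0])
    assert na(1) == pytest.approx(1 / 3)
    assert na(2) == pytest.approx(1 / 3 + 1 / 2)

    censored = nelson_aalen([1, 2, 3], [0, 0, 0])
    assert len(censored) == 0 and censored(10) == 0.0


def test_nelson_aalen_agrees_with_lifelines():
    from lifelines import NelsonAalenFitter

    rng = np.random.default_rng(11)
    for _ in range(10):
        times, events = random_survival_sample(rng)
        ours = nelson_aalen(times, events)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(times, events)
        for t in np.unique(times):
            assert ours(t) == pytest.approx(naf.cumulative_hazard_at_times(t).iloc[0], abs=1e-10)


# --- trees ------------------------------------------------------------------

def _toy_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    times = np.where(X[:, 0] > 0, rng.integers(1, 20, n), rng.integers(60, 120, n)).astype(float)
    events = np.ones(n, dtype=int)
    return X, times, events


def test_tree_single_leaf_when_nodesize_exceeds_n():
    X, times, events = _toy_data(30)
    tree = fit_tree(X, times, events, mtry=3, nodesize=30, nsplit=10, rng=1)
    assert tree.n_leaves == 1
    grid, values = brute_nelson_aalen(times[tree.inbag], events[tree.inbag])
    np.testing.assert_allclose(tree.leaf_H[0], nelson_aalen(times[tree.inbag], events[tree.inbag])(tree.grid))


def test_tree_perfect_split_found_at_root():
    # feature 0 perfectly separates early from late events
    X, times, events = _toy_data(100, seed=3)
    tree = fit_tree(X, times, events, mtry=3, nodesize=5, nsplit=20, rng=5)
    assert tree.feature[0] == 0


def test_tree_deterministic_under_seed():
    X, times, events = _toy_data(80, seed=2)
    a = fit_tree(X, times, events, 2, 5, 10, rng=9)
    b = fit_tree(X, times, events, 2, 5, 10, rng=9)
    np.testing.assert_array_equal(a.feature, b.feature)
    np.testing.assert_array_equal(a.threshold, b.threshold)
    np.testing.assert_array_equal(a.inbag, b.inbag)


# --- forest -----------------------------------------------------------------

def test_forest_of_one_tree_equals_the_tree():
    X, times, events = _toy_data(60, seed=4)
    f = RandomSurvivalForest(n_estimators=1, min_samples_leaf=5, random_state=3).fit(
        X, (events, times)
    )
    rows = f.trees_[0].predict_hazard_rows(X)
    np.testing.assert_array_equal(f.predict_cumulative_hazard(X), rows)


def test_predict_chf_is_tree_average_and_monotone():
    X, times, events = _toy_data(120, seed=5)
    f = RandomSurvivalForest(n_estimators=10, min_samples_leaf=5, random_state=7).fit(X, (events, times))
    chf = f.predict_cumulative_hazard(X[:20])
    brute = np.mean([t.predict_hazard_rows(X[:20]) for t in f.trees_], axis=0)
    np.testing.assert_allclose(chf, brute, atol=1e-12)
    assert (np.diff(chf, axis=1) >= -1e-12).all()


def test_ensemble_mortality_brute_force_and_linearity():
    X, times, events = _toy_data(60, seed=6)
    f = RandomSurvivalForest(n_estimators=5, min_samples_leaf=5, random_state=1).fit(X, (events, times))
    chf = f.predict_cumulative_hazard(X[:5])
    np.testing.assert_allclose(f.predict(X[:5]), chf.sum(axis=1), atol=1e-12)
    # scaling every leaf CHF by c scales mortality by c
    c = 2.5
    for tree in f.trees_:
        tree.leaf_H *= c
    np.testing.assert_allclose(f.predict(X[:5]), c * chf.sum(axis=1), rtol=1e-12)


def test_prediction_invariant_to_tree_order():
    X, times, events = _toy_data(60, seed=8)
    f = RandomSurvivalForest(n_estimators=8, min_samples_leaf=5, random_state=2).fit(X, (events, times))
    before = f.predict(X[:10])
    f.trees_ = f.trees_[::-1]
    np.testing.assert_allclose(f.predict(X[:10]), before, atol=1e-12)


def test_forest_reproducible_and_dataframe_contract():
    tab = simulate_survival_table(strong_signal_config(n_beneficiaries=300, seed=5),
                                  feature_columns=list(STRONG_SIGNAL_FEATURES))
    X, y = tab[list(STRONG_SIGNAL_FEATURES)], tab[["time_days", "event"]]
    a = RandomSurvivalForest(n_estimators=10, random_state=4).fit(X, y)
    b = RandomSurvivalForest(n_estimators=10, random_state=4).fit(X, y)
    np.testing.assert_array_equal(a.predict(X), b.predict(X))
    with pytest.raises(ContractViolationError, match="missing features"):
        a.predict(X.drop(columns=["severity_ed"]))


def test_serialization_round_trip():
    X, times, events = _toy_data(60, seed=9)
    f = RandomSurvivalForest(n_estimators=5, min_samples_leaf=5, random_state=6).fit(X, (events, times))
    g = RandomSurvivalForest.from_json(f.to_json())
    np.testing.assert_allclose(g.predict(X), f.predict(X), atol=1e-15)


def test_sklearn_params_round_trip():
    f = RandomSurvivalForest(n_estimators=7, min_samples_leaf=3)
    params = f.get_params()
    assert params["n_estimators"] == 7
    f.set_params(n_estimators=9)
    assert f.n_estimators == 9


# --- importance and selection ----------------------------------------------

@pytest.fixture(scope="module")
def signal_fit():
    tab = simulate_survival_table(strong_signal_config(n_beneficiaries=800, seed=31),
                                  feature_columns=list(STRONG_SIGNAL_FEATURES))
    X, y = tab[list(STRONG_SIGNAL_FEATURES)], tab[["time_days", "event"]]
    forest = RandomSurvivalForest(n_estimators=100, random_state=1).fit(X, y)
    return X, y, forest


def test_vimp_signal_positive_noise_small(signal_fit):
    X, y, forest = signal_fit
    report = forest.permutation_importance(random_state=0)
    for f in ("severity_ed", "severity_op", "severity_rx"):
        assert report.importance[f] > 0.01
    noise = report.importance.drop(list(("severity_ed", "severity_op", "severity_rx")))
    assert noise.abs().max() < 0.01
    assert report.split_frequency.between(0, 1).all()


def test_two_step_selects_signal_prefix(signal_fit):
    X, y, _ = signal_fit
    sel = TwoStepForestSelector(n_estimators=100, random_state=2).fit(X, y)
    assert set(("severity_ed", "severity_op", "severity_rx")) <= set(sel.selected_features_)
    assert sel.transform(X).shape[1] == len(sel.selected_features_)


def test_two_step_degenerate_rules():
    tab = simulate_survival_table(strong_signal_config(n_beneficiaries=400, seed=41),
                                  feature_columns=list(STRONG_SIGNAL_FEATURES))
    X, y = tab[list(STRONG_SIGNAL_FEATURES)], tab[["time_days", "event"]]
    # delta = inf: the nested walk stops immediately at the top-2 model
    sel = TwoStepForestSelector(delta=np.inf, n_estimators=25, random_state=3).fit(X, y)
    assert len(sel.selected_features_) == 2
    # p = 2: both features are returned outright
    two = X[["severity_ed", "severity_op"]]
    sel2 = TwoStepForestSelector(n_estimators=25, random_state=4).fit(two, y)
    assert set(sel2.selected_features_) == {"severity_ed", "severity_op"}


def test_two_step_all_negative_returns_top_with_warning():
    # pure-noise draw on which every permutation importance is negative
    r = np.random.default_rng(1)
    n = 300
    X = pd.DataFrame(r.standard_normal((n, 3)), columns=["a", "b", "c"])
    y = pd.DataFrame({"time_days": r.integers(1, 180, n), "event": (r.random(n) < 0.3).astype(int)})
    sel = TwoStepForestSelector(n_estimators=20, random_state=0)
    with pytest.warns(UserWarning, match="negative importance"):
        sel.fit(X, y)
    assert (sel.importances_ < 0).all()
    assert sel.selected_features_ == [sel.importances_.index[0]]


def test_functional_wrappers(signal_fit):
    X, y, forest = signal_fit
    records = X.join(y)
    f2 = fit_forest(records, n_estimators=5, random_state=0)
    step = predict_chf(f2, X.iloc[0])
    assert step.values[-1] >= 0 and len(step) == len(f2.event_times_)
    assert ensemble_mortality(f2, X.iloc[0]) == pytest.approx(step.values.sum())
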