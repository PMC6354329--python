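import numpy as np
import pandas as pd
import pytest

from drsf.dynamic import (
    DRSFEnsemble,
    WindowModel,
    WindowSchedule,
    global_importance,
    make_schedule,
    train_window,
)
from drsf.exceptions import UndefinedMetricError


def stub_model(pred_index, horizon=180, freqs=None):
    """WindowModel shell for hazard-combination tests (no forest needed)."""
    pred_index = pd.Timestamp(pred_index)
    return WindowModel(
        train_index_date=pred_index - pd.Timedelta(days=horizon),
        prediction_index_date=pred_index,
        horizon_days=horizon,
        selected_features=[],
        forest=None,
        validation_c=float("nan"),
        split_frequencies=freqs if freqs is not None else pd.Series(dtype=float),
        n_train=0,
        n_validation=0,
    )


# --- schedule ---------------------------------------------------------------

def test_make_schedule_calendar_arithmetic():
    sched = make_schedule("2014-02-01", 3, 1)
    assert [d.date().isoformat() for d in sched] == ["2014-02-01", "2014-03-01", "2014-04-01"]


def test_make_schedule_singleton():
    sched = make_schedule("2014-02-01", 1)
    assert len(sched) == 1 and sched.index_dates[0] == pd.Timestamp("2014-02-01")


def test_schedule_monthly_slides_cover_study_span():
    # 14 monthly windows starting Feb 1 2014: strictly increasing monthly
    # index dates whose month-long slides cover through Apr 1 2015
    sched = make_schedule("2014-02-01", 14, 1)
    dates = sched.index_dates
    assert len(dates) == 14
    assert all((b - a).days in (28, 29, 30, 31) for a, b in zip(dates, dates[1:]))
    assert sched.coverage_end == pd.Timestamp("2015-04-01")


# --- ensemble combination ---------------------------------------------------

def test_single_window_identity():
    m = stub_model("2015-03-01", horizon=5)
    inc = np.array([[0.1, 0.0, 0.2, 0.0, 0.05]])
    ens = DRSFEnsemble([m], "2015-03-01", horizon_days=5)
    ens.set_member_increments(["s"], [inc])
    hbar, _ = ens.hazard_matrix()
    np.testing.assert_array_equal(hbar, inc)
    assert ens.hazard_at(["s"], 3)[0] == inc[0, 2]
    assert ens.survival_at(["s"], 5)[0] == pytest.approx(np.exp(-inc.sum()))


def test_mean_of_identical_members_equals_either():
    horizon = 4
    inc = np.array([[0.1, 0.2, 0.0, 0.3]])
    m1 = stub_model("2015-03-01", horizon)
    m2 = stub_model("2015-03-01", horizon)
    ens = DRSFEnsemble([m1, m2], "2015-03-01", horizon_days=horizon)
    ens.set_member_increments(["s"], [inc, inc])
    hbar, counts = ens.hazard_matrix()
    np.testing.assert_allclose(hbar, inc, atol=1e-15)
    assert (counts == 2).all()


def test_arbitrary_members_match_brute_force(rng):
    horizon = 6
    offsets = [0, 2, 4]
    members = [stub_model(pd.Timestamp("2015-03-01") - pd.Timedelta(days=o), horizon) for o in offsets]
    incs = [rng.random((2, horizon)) * 0.1 for _ in offsets]
    ens = DRSFEnsemble(members, "2015-03-01", horizon_days=horizon)
    ens.set_member_increments(["a", "b"], list(reversed(incs)), offsets=list(reversed(offsets)))
    hbar, _ = ens.hazard_matrix()
    # brute force: for target day t, average inc[:, offset + t - 1] over
    # members whose own window still covers that day
    for t in range(1, horizon + 1):
        for row in range(2):
            vals = [
                inc[row, o + t - 1]
                for inc, o in zip(reversed(incs), reversed(offsets))
                if o + t - 1 < horizon
            ]
            assert hbar[row, t - 1] == pytest.approx(np.mean(vals), abs=1e-12)


def test_duplicate_member_pulls_mean_toward_it():
    horizon = 3
    a = np.array([[0.1, 0.1, 0.1]])
    b = np.array([[0.4, 0.4, 0.4]])
    members = [stub_model("2015-03-01", horizon) for _ in range(2)]
    ens = DRSFEnsemble(members, "2015-03-01", horizon_days=horizon)
    ens.set_member_increments(["s"], [a, b])
    base = ens.hazard_matrix()[0].copy()
    members3 = [stub_model("2015-03-01", horizon) for _ in range(3)]
    ens3 = DRSFEnsemble(members3, "2015-03-01", horizon_days=horizon)
    ens3.set_member_increments(["s"], [a, b, b])
    shifted = ens3.hazard_matrix()[0]
    assert (shifted > base).all()  # moved toward the duplicated (larger) member


def test_survival_monotone_nonincreasing_property(rng):
    horizon = 30
    for _ in range(100):
        n_members = int(rng.integers(1, 4))
        members = [
            stub_model(pd.Timestamp("2015-03-01") - pd.Timedelta(days=int(rng.integers(0, 10))), horizon)
            for _ in range(n_members)
        ]
        ens = DRSFEnsemble(members, "2015-03-01", horizon_days=horizon)
        incs = [rng.random((1, horizon)) * 0.2 for _ in range(n_members)]
        ens.set_member_increments(["s"], incs)
        surv = np.array([ens.survival_at(["s"], t)[0] for t in range(1, horizon + 1)])
        assert surv[0] <= 1.0 + 1e-12
        assert (np.diff(surv) <= 1e-12).all()


def test_dominance_pointwise_larger_hazard():
    horizon = 5
    m = stub_model("2015-03-01", horizon)
    ens = DRSFEnsemble([m], "2015-03-01", horizon_days=horizon)
    low = np.array([0.01, 0.02, 0.0, 0.01, 0.03])
    high = low + 0.05
    ens.set_member_increments(["lo", "hi"], [np.vstack([low, high])])
    lo_curve = ens.instant_risk_curve("lo")
    hi_curve = ens.instant_risk_curve("hi")
    assert (hi_curve.to_numpy() >= lo_curve.to_numpy()).all()


def test_instant_risk_empty_grid():
    m = stub_model("2015-03-01", 5)
    ens = DRSFEnsemble([m], "2015-03-01", horizon_days=5)
    ens.set_member_increments(["s"], [np.zeros((1, 5))])
    assert len(ens.instant_risk_curve("s", grid=[])) == 0


def test_constant_hazard_members_give_flat_curve():
    m = stub_model("2015-03-01", 5)
    ens = DRSFEnsemble([m], "2015-03-01", horizon_days=5)
    ens.set_member_increments(["s"], [np.full((1, 5), 0.07)])
    curve = ens.instant_risk_curve("s")
    assert np.allclose(curve.to_numpy(), 0.07)


def test_no_available_window_is_explicit():
    m = stub_model("2015-03-01", 5)
    ens = DRSFEnsemble([m], "2015-03-01", horizon_days=5)
    ens.set_member_increments(["s"], [None])
    with pytest.raises(UndefinedMetricError, match="N = 0"):
        ens.survival_at(["s"], 3)


# --- global importance ------------------------------------------------------

def test_global_importance_window_counts():
    def freqs(d):
        return pd.Series(d)

    models = [
        stub_model("2014-08-01", freqs=freqs({"a": 0.9, "b": 0.2, "c": 0.0})),
        stub_model("2014-09-01", freqs=freqs({"a": 0.5, "b": 0.35, "c": 0.0})),
        stub_model("2014-10-01", freqs=freqs({"a": 0.31, "b": 0.1, "c": 0.0})),
    ]
    table = global_importance(models, tree_fraction_threshold=0.30)
    assert table.loc["a", "n_windows_selected"] == 3
    assert table.loc["b", "n_windows_selected"] == 1
    assert table.loc["c", "n_windows_selected"] == 0
    # threshold 0 counts windows where the feature is used at all
    degenerate = global_importance(models, tree_fraction_threshold=0.0)
    assert degenerate.loc["b", "n_windows_selected"] == 3
    assert degenerate.loc["c", "n_windows_selected"] == 0


# --- train_window on a simulated stream -------------------------------------

@pytest.fixture(scope="module")
def small_stream():
    from drsf.simulate import simulate, strong_signal_config

    return simulate(strong_signal_config(n_beneficiaries=250, seed=99))


def test_train_window_deterministic(small_stream):
    data = small_stream
    kw = dict(n_estimators=20, seed=11, min_cohort_size=20)
    a = train_window(data.claims, data.roster, "2014-06-01", **kw)
    b = train_window(data.claims, data.roster, "2014-06-01", **kw)
    assert a.selected_features == b.selected_features
    assert a.validation_c == b.validation_c
    np.testing.assert_array_equal(
        a.forest.predict(np.eye(len(a.selected_features))),
        b.forest.predict(np.eye(len(b.selected_features))),
    )


def test_window_model_json_round_trip(small_stream):
    data = small_stream
    model = train_window(data.claims, data.roster, "2014-06-01",
                         n_estimators=10, seed=2, min_cohort_size=20)
    clone = WindowModel.from_json(model.to_json())
    assert clone.selected_features == model.selected_features
    assert clone.prediction_index_date == model.prediction_index_date
    X = np.zeros((3, len(model.selected_features)))
    np.testing.assert_allclose(clone.forest.predict(X), model.forest.predict(X), atol=1e-15)


def test_train_window_skips_tiny_cohort(small_stream):
    data = small_stream
    with pytest.warns(UserWarning, match="skipped"):
        model = train_window(data.claims, data.roster, "2014-06-01",
                             n_estimators=5, seed=1, min_cohort_size=10**6)
    assert model is None
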