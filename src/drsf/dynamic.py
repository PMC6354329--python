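"""The dynamic layer: sliding windows, per-window models, hazard ensembling.

A window model is a survival forest trained on the cohort of one index
date (with its own two-step feature selection) and deployed one horizon
later on the contiguous prediction window, where features are re-extracted
at the deployment index date.  A window ensemble combines the N most
recent window models available for a target prediction window: each
member contributes the daily jumps of its predicted cumulative hazard,
aligned on a common daily grid relative to the target index date, and the
ensembled hazard at day t is the arithmetic mean over the members whose
prediction interval covers that calendar day and whose cohort contains the
subject.  The ensembled survival is S(t) = exp(-sum_{u<=t} hbar(u)).

With a single member the ensemble arithmetic reduces exactly (bitwise) to
the plain forest pipeline on the most recent window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortSpec, build_outcomes, identify_cohort
from .evaluation import harrell_c
from .exceptions import UndefinedMetricError
from .features import FeatureSpec, extract_features
from .forest import RandomSurvivalForest, TwoStepForestSelector

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class WindowSchedule:
    """Monthly-stepped sequence of training index dates.

    ``coverage_end`` is the end of the span the schedule's month-long
    slides cover: ``first_index_date + n_windows * step_months`` months.
    """

    first_index_date: pd.Timestamp
    n_windows: int
    step_months: int = 1
    window_length_days: int = 180

    def __post_init__(self):
        self.first_index_date = pd.Timestamp(self.first_index_date)
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")

    @property
    def index_dates(self) -> list[pd.Timestamp]:
        return [
            self.first_index_date + pd.DateOffset(months=k * self.step_months)
            for k in range(self.n_windows)
        ]

    @property
    def coverage_end(self) -> pd.Timestamp:
        return self.first_index_date + pd.DateOffset(months=self.n_windows * self.step_months)

    def __iter__(self):
        return iter(self.index_dates)

    def __len__(self):
        return self.n_windows


def make_schedule(first_index_date, n_windows, step_months=1, window_length_days=180) -> WindowSchedule:
    return WindowSchedule(first_index_date, n_windows, step_months, window_length_days)


# ---------------------------------------------------------------------------
# one window
# ---------------------------------------------------------------------------

@dataclass
class WindowModel:
    """A forest trained at one index date, deployed one horizon later."""

    train_index_date: pd.Timestamp
    prediction_index_date: pd.Timestamp
    horizon_days: int
    selected_features: list
    forest: RandomSurvivalForest
    validation_c: float
    split_frequencies: pd.Series
    n_train: int
    n_validation: int

    def predict_daily_cumhaz(self, X) -> np.ndarray:
        """Predicted H at whole days 1..horizon for each row of X."""
        chf = self.forest.predict_cumulative_hazard(X[self.selected_features] if isinstance(X, pd.DataFrame) else X)
        grid = self.forest.event_times_
        days = np.arange(1, self.horizon_days + 1, dtype=float)
        idx = np.searchsorted(grid, days, side="right")
        padded = np.concatenate([np.zeros((chf.shape[0], 1)), chf], axis=1)
        return padded[:, idx]

    def predict_daily_increments(self, X) -> np.ndarray:
        """Daily hazard jumps h(t) = H(t) - H(t-1), t = 1..horizon."""
        daily = self.predict_daily_cumhaz(X)
        return np.diff(np.concatenate([np.zeros((daily.shape[0], 1)), daily], axis=1), axis=1)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "version": "drsf-window-v1",
                "train_index_date": str(self.train_index_date.date()),
                "prediction_index_date": str(self.prediction_index_date.date()),
                "horizon_days": self.horizon_days,
                "selected_features": list(self.selected_features),
                "validation_c": self.validation_c,
                "split_frequencies": self.split_frequencies.to_dict(),
                "n_train": self.n_train,
                "n_validation": self.n_validation,
                "forest": self.forest.to_json(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WindowModel":
        import json

        doc = json.loads(text)
        if doc.get("version") != "drsf-window-v1":
            raise ValueError(f"unsupported window-model version {doc.get('version')!r}")
        return cls(
            train_index_date=pd.Timestamp(doc["train_index_date"]),
            prediction_index_date=pd.Timestamp(doc["prediction_index_date"]),
            horizon_days=int(doc["horizon_days"]),
            selected_features=list(doc["selected_features"]),
            forest=RandomSurvivalForest.from_json(doc["forest"]),
            validation_c=float(doc["validation_c"]),
            split_frequencies=pd.Series(doc["split_frequencies"], dtype=float),
            n_train=int(doc["n_train"]),
            n_validation=int(doc["n_validation"]),
        )


def train_window(
    claims: pd.DataFrame,
    roster: pd.DataFrame,
    index_date,
    *,
    horizon_days: int = 180,
    cohort_spec: CohortSpec | None = None,
    feature_spec: FeatureSpec | None = None,
    n_estimators: int = 500,
    max_features="sqrt",
    min_samples_leaf: int = 15,
    n_splits: int = 10,
    delta: float = 0.005,
    select_features: bool = True,
    val_fraction: float = 0.33,
    min_cohort_size: int = 50,
    seed=None,
) -> WindowModel | None:
    """Cohort -> features -> two-step selection -> forest for one window.

    Trains on a random 67% of the window's cohort and records Harrell's C
    on the held-out 33%.  Returns None (with a warning) when the cohort is
    smaller than ``min_cohort_size``.
    """
    index_date = pd.Timestamp(index_date)
    cohort_spec = cohort_spec or CohortSpec(horizon_days=horizon_days)
    ids = identify_cohort(claims, roster, index_date, cohort_spec)
    if len(ids) < min_cohort_size:
        warnings.warn(f"window {index_date.date()}: cohort size {len(ids)} < {min_cohort_size}; skipped")
        return None
    X = extract_features(claims, roster, ids, index_date, feature_spec)
    outcomes = build_outcomes(claims, ids, index_date, cohort_spec).set_index("beneficiary_id")
    y = outcomes.loc[X.index, ["time_days", "event"]]

    seeds = np.random.SeedSequence(seed).generate_state(3)
    rng = np.random.default_rng(int(seeds[0]))
    n = len(X)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    val_rows, train_rows = perm[:n_val], perm[n_val:]
    X_tr, y_tr = X.iloc[train_rows], y.iloc[train_rows]
    X_va, y_va = X.iloc[val_rows], y.iloc[val_rows]

    if select_features and X.shape[1] >= 2:
        selector = TwoStepForestSelector(
            delta=delta, n_estimators=n_estimators, max_features=max_features,
            min_samples_leaf=min_samples_leaf, n_splits=n_splits, random_state=int(seeds[1]),
        ).fit(X_tr, y_tr)
        selected = list(selector.selected_features_)
    else:
        selected = list(X.columns)

    forest = RandomSurvivalForest(
        n_estimators=n_estimators, max_features=max_features,
        min_samples_leaf=min_samples_leaf, n_splits=n_splits, random_state=int(seeds[2]),
    ).fit(X_tr[selected], y_tr)

    try:
        val_c = harrell_c(forest.predict(X_va[selected]), y_va["time_days"], y_va["event"])
    except UndefinedMetricError:
        val_c = float("nan")

    freq = forest.split_frequencies_.reindex(X.columns, fill_value=0.0)
    return WindowModel(
        train_index_date=index_date,
        prediction_index_date=index_date + pd.Timedelta(days=horizon_days),
        horizon_days=horizon_days,
        selected_features=selected,
        forest=forest,
        validation_c=float(val_c),
        split_frequencies=freq,
        n_train=len(train_rows),
        n_validation=len(val_rows),
    )


# ---------------------------------------------------------------------------
# window ensemble
# ---------------------------------------------------------------------------

class DRSFEnsemble:
    """Hazard-averaging combination of the N most recent window models.

    Parameters
    ----------
    models : list of WindowModel
        Members ordered oldest to newest by prediction index date; the
        newest member's prediction index must equal ``target_index_date``.
    target_index_date : date-like
        Index date of the target prediction window.
    weights : sequence of float, optional
        Optional per-member weights (newest-last).  The default is the
        unweighted mean; recency then enters only through member
        eligibility per calendar day.
    """

    def __init__(self, models, target_index_date, horizon_days=180, weights=None):
        models = sorted(models, key=lambda m: m.prediction_index_date)
        if not models:
            raise ValueError("need at least one window model")
        self.models = models
        self.target_index_date = pd.Timestamp(target_index_date)
        self.horizon_days = int(horizon_days)
        if weights is not None and len(weights) != len(models):
            raise ValueError("weights must match the number of models")
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        for m in models:
            if m.prediction_index_date > self.target_index_date:
                raise ValueError("member prediction windows must start at or before the target index date")
        self._prepared = None

    @property
    def n_windows(self) -> int:
        return len(self.models)

    def prepare(self, claims, roster, subject_ids, feature_spec=None, cohort_spec=None):
        """Extract each member's features and hazard increments for the subjects.

        For every member window the subjects present in that window's
        cohort get the member's predicted daily hazard jumps, aligned from
        the member's own prediction index date.  Subjects in no member
        cohort get no prediction.
        """
        subject_ids = sorted(subject_ids)
        self._subjects = pd.Index(subject_ids, name="beneficiary_id")
        self._member_inc = []
        self._member_rows = []
        self._member_offset = []
        for m in self.models:
            p_idx = m.prediction_index_date
            cohort = identify_cohort(claims, roster, p_idx, cohort_spec) & set(subject_ids)
            offset = (self.target_index_date - p_idx).days
            if not cohort:
                self._member_inc.append(None)
                self._member_rows.append(None)
                self._member_offset.append(offset)
                continue
            Xm = extract_features(claims, roster, cohort, p_idx, feature_spec)
            inc = m.predict_daily_increments(Xm)
            rows = self._subjects.get_indexer(Xm.index)
            self._member_inc.append(inc)
            self._member_rows.append(rows)
            self._member_offset.append(offset)
        self._prepared = True
        self._hazard_cache = None
        return self

    def set_member_increments(self, subjects, increments_per_member, offsets=None):
        """Directly supply per-member daily increments (for prepared features)."""
        self._subjects = pd.Index(subjects, name="beneficiary_id")
        self._member_inc = []
        self._member_rows = []
        self._member_offset = []
        for k, inc in enumerate(increments_per_member):
            off = (self.target_index_date - self.models[k].prediction_index_date).days if offsets is None else offsets[k]
            self._member_inc.append(np.asarray(inc, dtype=float) if inc is not None else None)
            self._member_rows.append(np.arange(len(self._subjects)) if inc is not None else None)
            self._member_offset.append(off)
        self._prepared = True
        self._hazard_cache = None
        return self

    def _check_prepared(self):
        if not self._prepared:
            raise RuntimeError("call prepare() (or set_member_increments) before predicting")

    def hazard_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(hbar, n_available): daily ensembled hazard and member counts.

        ``hbar[i, t-1]`` is the mean hazard jump at target-window day t for
        subject i over the members available to that subject on that day.
        Days with no available member contribute hazard 0.
        """
        self._check_prepared()
        if getattr(self, "_hazard_cache", None) is not None:
            return self._hazard_cache
        n = len(self._subjects)
        H = self.horizon_days
        sums = np.zeros((n, H))
        counts = np.zeros((n, H))
        for k, inc in enumerate(self._member_inc):
            if inc is None:
                continue
            off = self._member_offset[k]
            span = inc.shape[1] - off  # target days this member covers
            if span <= 0:
                continue
            span = min(span, H)
            w = 1.0 if self.weights is None else self.weights[k]
            rows = self._member_rows[k]
            sums[rows, :span] += w * inc[:, off:off + span]
            counts[rows, :span] += w
        with np.errstate(invalid="ignore"):
            hbar = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
        self._hazard_cache = (hbar, counts)
        return hbar, counts

    def available_windows(self) -> pd.Series:
        """Number of member windows available per subject (any day)."""
        _, counts = self.hazard_matrix()
        return pd.Series((counts > 0).any(axis=1).astype(int) * (counts.max(axis=1)), index=self._subjects)

    def _rows_for(self, ids) -> np.ndarray:
        idx = self._subjects.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown subject id(s) in prediction request")
        return idx

    def hazard_at(self, ids, t_days: int) -> np.ndarray:
        """Ensembled hazard jump hbar(t) at target-window day t."""
        hbar, counts = self.hazard_matrix()
        rows = self._rows_for(ids)
        if (counts[rows].sum(axis=1) == 0).any():
            raise UndefinedMetricError("subject present in no member window (N = 0)")
        return hbar[rows, int(t_days) - 1]

    def cumulative_hazard_at(self, ids, t_days: int) -> np.ndarray:
        hbar, counts = self.hazard_matrix()
        rows = self._rows_for(ids)
        if (counts[rows].sum(axis=1) == 0).any():
            raise UndefinedMetricError("subject present in no member window (N = 0)")
        return np.cumsum(hbar[rows], axis=1)[:, int(t_days) - 1]

    def survival_at(self, ids, t_days: int) -> np.ndarray:
        """S(t) = exp(-sum_{u<=t} hbar(u)); S(0) = 1, nonincreasing in t."""
        return np.exp(-self.cumulative_hazard_at(ids, t_days))

    def instant_risk_curve(self, subject_id, grid=None) -> pd.Series:
        """hbar(t) on the requested day grid, for monitoring/plotting."""
        grid = np.asarray(grid if grid is not None else np.arange(1, self.horizon_days + 1), dtype=int)
        if grid.size == 0:
            return pd.Series(dtype=float, name=subject_id)
        hbar, counts = self.hazard_matrix()
        row = self._rows_for([subject_id])[0]
        if counts[row].sum() == 0:
            raise UndefinedMetricError("subject present in no member window (N = 0)")
        return pd.Series(hbar[row, grid - 1], index=pd.Index(grid, name="day"), name=subject_id)


# functional wrappers -------------------------------------------------------

def ensemble_hazard(ensemble: DRSFEnsemble, subject_id, t_days: int) -> float:
    return float(ensemble.hazard_at([subject_id], t_days)[0])


def ensemble_survival(ensemble: DRSFEnsemble, subject_id, t_days: int) -> float:
    return float(ensemble.survival_at([subject_id], t_days)[0])


def instant_risk_curve(ensemble: DRSFEnsemble, subject_id, grid=None) -> pd.Series:
    return ensemble.instant_risk_curve(subject_id, grid)


# ---------------------------------------------------------------------------
# variable importance across windows
# ---------------------------------------------------------------------------

def global_importance(window_models, tree_fraction_threshold: float = 0.30) -> pd.DataFrame:
    """Per-feature count of windows selecting it at the tree-vote threshold.

    A feature is "selected" in a window when its split frequency (fraction
    of that window's trees splitting on it at least once) is at least the
    threshold.  Local importance is the per-window split frequency itself,
    returned alongside the window counts.
    """
    if not window_models:
        raise ValueError("need at least one window model")
    freq = pd.DataFrame(
        {m.train_index_date.strftime("%Y-%m-%d"): m.split_frequencies for m in window_models}
    ).fillna(0.0)
    # a feature counts in a window when it is actually used there and its
    # tree vote reaches the threshold (threshold 0 -> "used at all")
    counts = ((freq >= tree_fraction_threshold) & (freq > 0)).sum(axis=1)
    out = freq.copy()
    out.insert(0, "n_windows_selected", counts.astype(int))
    return out.sort_values("n_windows_selected", ascending=False, kind="mergesort")
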