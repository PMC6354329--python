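"""Random survival forest with log-rank splitting, built from scratch.

Trees are grown on bootstrap samples; at each node ``mtry`` features are
drawn at random and up to ``nsplit`` random cut points per feature are
scored by the standardized two-sample log-rank statistic.  Each terminal
node stores the Nelson-Aalen cumulative hazard of its in-bag members, and
the forest prediction for a subject is the tree-averaged cumulative hazard
H(t) on the grid of distinct training event times.  The scalar ranking
marker is the ensemble mortality, the sum of H over that grid.

Variable importance is Breiman-Cutler permutation importance on the
out-of-bag (OOB) data with concordance-based error, plus the split
frequency (fraction of trees using a feature in at least one split).  The
two-step selector drops negative-importance features and then walks a
nested sequence of forests over the top-ranked survivors until the OOB
concordance gain falls below ``delta``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _kernels
from .evaluation import harrell_c
from .exceptions import ContractViolationError
from .stepfunction import StepFunction

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = "drsf-forest-v1"


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard H(t) = sum_{t_j <= t} d_j / n_j.

    ``d_j`` are events and ``n_j`` the number at risk at each distinct
    event time; censored observations tied with events are still at risk
    at that time.  With no events the grid is empty and H is identically 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("need at least one observation")
    order = np.argsort(times, kind="mergesort")
    t = times[order]
    e = events[order]
    # counts at distinct times
    uniq, start = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(int), start)
    removed = np.add.reduceat(np.ones_like(t, dtype=int), start)
    at_risk = t.size - np.concatenate(([0], np.cumsum(removed[:-1])))
    keep = d > 0
    if not keep.any():
        return StepFunction([], [])
    grid = uniq[keep]
    values = np.cumsum(d[keep] / at_risk[keep])
    return StepFunction(grid, values)


def logrank_split_statistic(times, events, left_mask) -> float:
    """Standardized two-sample log-rank statistic |O - E| / sqrt(V).

    ``left_mask`` flags group membership; both groups must be nonempty and
    the pooled sample must contain at least one event.  Degenerate risk
    sets (zero hypergeometric variance) return 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(np.uint8)
    mask = np.asarray(left_mask).astype(np.uint8)
    if mask.all() or not mask.any():
        raise ValueError("both sides of the split must be nonempty")
    if not events.any():
        raise ValueError("need at least one event")
    order = np.argsort(times, kind="mergesort")
    return float(_kernels.logrank_statistic(times[order], events[order], mask[order]))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTree:
    """One grown tree: flat node arrays plus per-leaf hazard curves."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_nodes: np.ndarray
    leaf_H: np.ndarray  # (n_leaves, len(grid))
    grid: np.ndarray
    inbag: np.ndarray
    oob: np.ndarray

    def __post_init__(self):
        self._leaf_row = np.full(self.feature.shape[0], -1, dtype=np.int64)
        self._leaf_row[self.leaf_nodes] = np.arange(self.leaf_nodes.shape[0])

    def apply(self, X: np.ndarray) -> np.ndarray:
        return _kernels.apply_tree(self.feature, self.threshold, self.left, self.right, X)

    def predict_hazard_rows(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_H[self._leaf_row[self.apply(X)]]

    @property
    def n_leaves(self) -> int:
        return int(self.leaf_nodes.shape[0])

    def features_used(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])


def fit_tree(X, times, events, mtry, nodesize, nsplit, rng, grid=None, inbag=None) -> SurvivalTree:
    """Grow a single survival tree (bootstrap drawn from ``rng`` if needed)."""
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(np.uint8)
    n = X.shape[0]
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if inbag is None:
        inbag = rng.integers(0, n, size=n)
    inbag = np.asarray(inbag, dtype=np.int64)
    oob = np.setdiff1d(np.arange(n), inbag)
    if grid is None:
        grid = np.unique(times[events.astype(bool)])
    seed = int(rng.integers(0, 2**31 - 1))
    feature, threshold, left, right, n_nodes, work, node_of = _kernels.grow_tree(
        X, times, events, inbag, int(mtry), int(nodesize), int(nsplit), seed
    )
    leaf_nodes = np.unique(node_of)
    leaf_H = _kernels.leaf_hazards(node_of, work, times, events, leaf_nodes, np.asarray(grid, dtype=np.float64))
    return SurvivalTree(feature, threshold, left, right, leaf_nodes, leaf_H, np.asarray(grid, float), inbag, oob)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

def _unpack_y(y):
    """Accept (event, time) in several conventions; return (time, event)."""
    if isinstance(y, pd.DataFrame):
        return y["time_days"].to_numpy(float), y["event"].to_numpy(int)
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        ev = "event" if "event" in names else sorted(names)[0]
        tm = "time" if "time" in names else ("time_days" if "time_days" in names else sorted(names)[1])
        return y[tm].astype(float), y[ev].astype(int)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        event, time = y
        return np.asarray(time, float), np.asarray(event, int)
    raise ValueError("y must be a structured array with ('event','time'), a DataFrame with "
                     "['time_days','event'], or an (event, time) pair")


class RandomSurvivalForest(BaseEstimator):
    """Random survival forest with log-rank split search.

    Parameters
    ----------
    n_estimators : int, default 500
        Number of bootstrap trees.
    max_features : "sqrt", int or float, default "sqrt"
        Features drawn (without replacement) at each node; "sqrt" means
        ``ceil(sqrt(p))``.
    min_samples_leaf : int, default 15
        Minimum bootstrap members on each side of every split.
    n_splits : int, default 10
        Random candidate cut points evaluated per drawn feature.
    random_state : int or None
        Seed for the bootstrap and split streams.

    Attributes
    ----------
    trees_ : list of SurvivalTree
    event_times_ : ndarray
        Distinct training event times; the grid every prediction lives on.
    feature_names_in_ : ndarray of str, when fitted with a DataFrame.
    oob_prediction_ : ndarray
        OOB ensemble mortality per training row (NaN if never out of bag).
    """

    def __init__(self, n_estimators=500, max_features="sqrt", min_samples_leaf=15,
                 n_splits=10, random_state=None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.n_splits = n_splits
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _resolve_mtry(self, p: int) -> int:
        mf = self.max_features
        if mf == "sqrt" or mf is None:
            return max(1, int(np.ceil(np.sqrt(p))))
        if isinstance(mf, float) and 0 < mf <= 1:
            return max(1, int(np.ceil(mf * p)))
        mtry = int(mf)
        if not 1 <= mtry <= p:
            raise ValueError(f"max_features={mf!r} outside [1, {p}]")
        return mtry

    def _validate_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = set(self.feature_names_in_) - set(X.columns)
                if missing:
                    raise ContractViolationError(f"missing features: {sorted(missing)}")
                X = X[list(self.feature_names_in_)]
            return np.ascontiguousarray(X.to_numpy(dtype=np.float64))
        arr = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if hasattr(self, "n_features_in_") and arr.shape[1] != self.n_features_in_:
            raise ContractViolationError(
                f"X has {arr.shape[1]} features; the forest was fitted with {self.n_features_in_}"
            )
        return arr

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        elif hasattr(self, "feature_names_in_"):
            del self.feature_names_in_
        time, event = _unpack_y(y)
        Xa = self._validate_X(X)
        n, p = Xa.shape
        if n != time.shape[0]:
            raise ValueError("X and y lengths differ")
        if not (event == 1).any():
            raise ValueError("training data must contain at least one event")
        if (time <= 0).any():
            raise ValueError("survival times must be positive")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        self.n_features_in_ = p
        mtry = self._resolve_mtry(p)
        self.event_times_ = np.unique(time[event == 1])
        rng = np.random.default_rng(np.random.SeedSequence(self.random_state))
        self.trees_ = []
        for _ in range(self.n_estimators):
            self.trees_.append(
                fit_tree(Xa, time, event, mtry, self.min_samples_leaf, self.n_splits,
                         rng, grid=self.event_times_)
            )
        self._fit_X = Xa
        self._fit_time = time.astype(float)
        self._fit_event = event.astype(np.uint8)
        self._compute_oob()
        return self

    def _compute_oob(self):
        n = self._fit_X.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree in self.trees_:
            if tree.oob.size == 0:
                continue
            rows = tree.predict_hazard_rows(self._fit_X[tree.oob])
            sums[tree.oob] += rows.sum(axis=1)
            counts[tree.oob] += 1
        with np.errstate(invalid="ignore"):
            self.oob_prediction_ = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        self._oob_counts = counts

    # -- prediction -------------------------------------------------------

    def predict_cumulative_hazard(self, X) -> np.ndarray:
        """Tree-averaged H(t) on ``event_times_`` for each row of X."""
        Xa = self._validate_X(X)
        out = np.zeros((Xa.shape[0], self.event_times_.shape[0]))
        for tree in self.trees_:
            out += tree.predict_hazard_rows(Xa)
        out /= len(self.trees_)
        return out

    def predict_cumulative_hazard_function(self, X) -> list[StepFunction]:
        chf = self.predict_cumulative_hazard(X)
        return [StepFunction(self.event_times_, row) for row in chf]

    def predict(self, X) -> np.ndarray:
        """Ensemble mortality: H summed over the distinct training event times."""
        return self.predict_cumulative_hazard(X).sum(axis=1)

    def oob_concordance(self) -> float:
        """Harrell's C of the OOB ensemble mortality on the training data."""
        mask = self._oob_counts > 0
        return harrell_c(self.oob_prediction_[mask], self._fit_time[mask], self._fit_event[mask])

    # -- importance -------------------------------------------------------

    @property
    def split_frequencies_(self) -> pd.Series:
        used = np.zeros(self.n_features_in_)
        for tree in self.trees_:
            used[tree.features_used()] += 1
        return pd.Series(used / len(self.trees_), index=self._feature_index())

    def _feature_index(self):
        if hasattr(self, "feature_names_in_"):
            return pd.Index(self.feature_names_in_)
        return pd.RangeIndex(self.n_features_in_)

    def permutation_importance(self, random_state=None) -> "VimpReport":
        """Breiman-Cutler permutation importance on the OOB data.

        For each feature, its OOB values are permuted within every tree's
        OOB sample, the OOB ensemble mortality is recomputed, and the
        importance is the increase in OOB error (1 - Harrell's C) over the
        baseline.
        """
        rng = np.random.default_rng(np.random.SeedSequence(random_state))
        n = self._fit_X.shape[0]
        mask = self._oob_counts > 0
        baseline_err = 1.0 - self.oob_concordance()
        importances = np.zeros(self.n_features_in_)
        for j in range(self.n_features_in_):
            sums = np.zeros(n)
            col = self._fit_X[:, j]
            if np.all(col == col[0]):
                importances[j] = 0.0
                continue
            for tree in self.trees_:
                if tree.oob.size == 0:
                    continue
                Xp = self._fit_X[tree.oob].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                sums[tree.oob] += tree.predict_hazard_rows(Xp).sum(axis=1)
            marker = sums[mask] / self._oob_counts[mask]
            err = 1.0 - harrell_c(marker, self._fit_time[mask], self._fit_event[mask])
            importances[j] = err - baseline_err
        return VimpReport(
            importance=pd.Series(importances, index=self._feature_index()),
            split_frequency=self.split_frequencies_,
            baseline_error=baseline_err,
        )

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "version": SERIALIZATION_VERSION,
            "params": self.get_params(),
            "feature_names": list(map(str, self.feature_names_in_)) if hasattr(self, "feature_names_in_") else None,
            "n_features": int(self.n_features_in_),
            "event_times": self.event_times_.tolist(),
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "leaf_nodes": t.leaf_nodes.tolist(),
                    "leaf_H": t.leaf_H.tolist(),
                }
                for t in self.trees_
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "RandomSurvivalForest":
        doc = json.loads(text)
        if doc.get("version") != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported serialization version {doc.get('version')!r}")
        model = cls(**doc["params"])
        model.n_features_in_ = doc["n_features"]
        if doc["feature_names"] is not None:
            model.feature_names_in_ = np.asarray(doc["feature_names"], dtype=object)
        model.event_times_ = np.asarray(doc["event_times"], dtype=float)
        grid = model.event_times_
        model.trees_ = [
            SurvivalTree(
                feature=np.asarray(t["feature"], np.int64),
                threshold=np.asarray(t["threshold"], np.float64),
                left=np.asarray(t["left"], np.int64),
                right=np.asarray(t["right"], np.int64),
                leaf_nodes=np.asarray(t["leaf_nodes"], np.int64),
                leaf_H=np.asarray(t["leaf_H"], np.float64).reshape(len(t["leaf_nodes"]), grid.size),
                grid=grid,
                inbag=np.empty(0, np.int64),
                oob=np.empty(0, np.int64),
            )
            for t in doc["trees"]
        ]
        return model


@dataclass
class VimpReport:
    """Permutation importance and split frequency per feature."""

    importance: pd.Series
    split_frequency: pd.Series
    baseline_error: float


# ---------------------------------------------------------------------------
# spec-style functional wrappers over the estimator
# ---------------------------------------------------------------------------

def _records_to_xy(records: pd.DataFrame):
    X = records.drop(columns=[c for c in ("time_days", "event", "beneficiary_id", "index_date") if c in records])
    return X, records[["time_days", "event"]]


def fit_forest(records: pd.DataFrame, **params) -> RandomSurvivalForest:
    """Fit a forest on a record table with ``time_days``/``event`` columns."""
    X, y = _records_to_xy(records)
    return RandomSurvivalForest(**params).fit(X, y)


def predict_chf(forest: RandomSurvivalForest, x) -> StepFunction:
    """Ensemble cumulative hazard function for one subject."""
    if isinstance(x, pd.Series):
        x = x.to_frame().T
    return forest.predict_cumulative_hazard_function(x)[0]


def ensemble_mortality(forest: RandomSurvivalForest, x) -> float:
    """Expected cumulative hazard summed over the training event-time grid."""
    if isinstance(x, pd.Series):
        x = x.to_frame().T
    return float(forest.predict(x)[0])


def permutation_vimp(forest: RandomSurvivalForest, random_state=None) -> VimpReport:
    return forest.permutation_importance(random_state=random_state)


# ---------------------------------------------------------------------------
# two-step feature selection
# ---------------------------------------------------------------------------

class TwoStepForestSelector(BaseEstimator):
    """Two-step variable selection for survival forests.

    Step 1 fits a forest on all candidates and drops every feature with
    negative permutation importance.  Step 2 ranks the survivors by
    importance and fits nested forests on the top-2, top-3, ... features,
    stopping once the OOB concordance gain drops below ``delta``; the
    selected set is the last prefix that still improved.

    Attributes
    ----------
    selected_features_ : list
        Chosen features, by decreasing step-1 importance.
    importances_ : pd.Series
    oob_path_ : dict
        OOB concordance of each nested prefix size that was fitted.
    """

    def __init__(self, delta=0.005, n_estimators=100, max_features="sqrt",
                 min_samples_leaf=15, n_splits=10, random_state=None):
        self.delta = delta
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.n_splits = n_splits
        self.random_state = random_state

    def _forest(self, seed):
        return RandomSurvivalForest(
            n_estimators=self.n_estimators, max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf, n_splits=self.n_splits,
            random_state=seed,
        )

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        if X.shape[1] < 2:
            raise ValueError("need at least 2 candidate features")
        seeds = np.random.SeedSequence(self.random_state).generate_state(X.shape[1] + 2)
        full = self._forest(int(seeds[0])).fit(X, y)
        vimp = full.permutation_importance(random_state=int(seeds[1]))
        self.importances_ = vimp.importance.sort_values(ascending=False, kind="mergesort")
        survivors = [f for f in self.importances_.index if vimp.importance[f] >= 0]
        self.oob_path_ = {}
        if len(survivors) == 0:
            top = self.importances_.index[0]
            warnings.warn("all features had negative importance; keeping the top-ranked one")
            self.selected_features_ = [top]
            return self
        if len(survivors) <= 2:
            self.selected_features_ = survivors
            return self
        prev_c = self._forest(int(seeds[2])).fit(X[survivors[:2]], y).oob_concordance()
        self.oob_path_[2] = prev_c
        selected = survivors[:2]
        for k in range(3, len(survivors) + 1):
            c_k = self._forest(int(seeds[k])).fit(X[survivors[:k]], y).oob_concordance()
            self.oob_path_[k] = c_k
            if c_k - prev_c < self.delta:
                break
            selected = survivors[:k]
            prev_c = c_k
        self.selected_features_ = selected
        return self

    def get_support(self):
        return self.selected_features_

    def transform(self, X):
        return X[self.selected_features_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def two_step_select(records: pd.DataFrame, delta=0.005, **forest_params) -> list:
    """Functional wrapper: selected feature names for a record table."""
    X, y = _records_to_xy(records)
    sel = TwoStepForestSelector(delta=delta, **forest_params).fit(X, y)
    return sel.selected_features_
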