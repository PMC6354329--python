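"""Survival-prediction metrics and bootstrap uncertainty.

Harrell's concordance from scalar risk markers, the IPCW
cumulative/dynamic time-dependent AUC at fixed horizons, and the
stratified percentile bootstrap for confidence intervals.  All metric
functions operate on plain arrays (marker, time, event) so any model that
produces a ranking marker can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedMetricError

_CHUNK = 256


def _as_arrays(markers, times, events):
    m = np.asarray(markers, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (m.shape == t.shape == e.shape) or m.ndim != 1:
        raise ValueError("markers, times and events must be 1-d arrays of equal length")
    return m, t, e


def harrell_c(markers, times, events) -> float:
    """Harrell's concordance index of a risk marker.

    A pair is comparable when the strictly shorter time ends in an event;
    it is concordant when the shorter-lived subject carries the larger
    marker, and marker ties count 1/2.
    """
    m, t, e = _as_arrays(markers, times, events)
    n = m.size
    if n < 2 or not e.any():
        raise UndefinedMetricError("need at least two subjects and one event")
    conc = 0.0
    comp = 0
    case_idx = np.flatnonzero(e)
    for lo in range(0, case_idx.size, _CHUNK):
        idx = case_idx[lo:lo + _CHUNK]
        later = t[None, :] > t[idx, None]            # (chunk, n)
        comp += int(later.sum())
        greater = m[idx, None] > m[None, :]
        ties = m[idx, None] == m[None, :]
        conc += float((later & greater).sum()) + 0.5 * float((later & ties).sum())
    if comp == 0:
        raise UndefinedMetricError("no comparable pairs")
    return conc / comp


def _censoring_km(times, events):
    """Kaplan-Meier of the censoring distribution G(t) (censorings as events)."""
    t = np.asarray(times, float)
    c = ~np.asarray(events).astype(bool)
    order = np.argsort(t, kind="mergesort")
    ts, cs = t[order], c[order]
    uniq, start = np.unique(ts, return_index=True)
    d = np.add.reduceat(cs.astype(int), start)
    removed = np.add.reduceat(np.ones_like(ts, dtype=int), start)
    at_risk = ts.size - np.concatenate(([0], np.cumsum(removed[:-1])))
    surv = np.cumprod(1.0 - d / at_risk)
    def G(query, before=False):
        q = np.asarray(query, dtype=float)
        side = "left" if before else "right"
        idx = np.searchsorted(uniq, q, side=side)
        padded = np.concatenate(([1.0], surv))
        return padded[idx]
    return G


def cumulative_dynamic_auc(markers, times, events, horizon) -> float:
    """Cumulative/dynamic time-dependent AUC at ``horizon``.

    Cases are subjects with an event by the horizon, controls those still
    event-free past it.  Cases are weighted by the inverse probability of
    censoring 1/G(t-) estimated by Kaplan-Meier; with no censoring before
    the horizon this reduces to the empirical case/control AUC.  Marker
    ties count 1/2.
    """
    m, t, e = _as_arrays(markers, times, events)
    horizon = float(horizon)
    case = (t <= horizon) & e
    # administrative censoring exactly at the horizon means event-free
    # through it: such subjects are controls
    ctrl = (t > horizon) | (~e & (t == horizon))
    if not case.any() or not ctrl.any():
        raise UndefinedMetricError("need at least one case and one control at the horizon")
    G = _censoring_km(t, e)
    w = 1.0 / G(t[case], before=True)
    mc, mk = m[case], m[ctrl]
    greater = (mc[:, None] > mk[None, :]).astype(float)
    ties = (mc[:, None] == mk[None, :]).astype(float)
    num = (w[:, None] * (greater + 0.5 * ties)).sum()
    den = w.sum() * mk.size
    return float(num / den)


def bootstrap_ci(markers, times, events, metric, n_boot=500, seed=None,
                 alpha=0.05, max_retries=100) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for a marker metric.

    Cases (event = 1) and controls are resampled separately with
    replacement, preserving the observed case/control counts; the metric
    is recomputed per replicate and the empirical ``alpha/2`` and
    ``1 - alpha/2`` percentiles are returned.  A replicate on which the
    metric is undefined is redrawn (up to ``max_retries`` consecutive
    times).
    """
    m, t, e = _as_arrays(markers, times, events)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(e)
    ctrl_idx = np.flatnonzero(~e)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            take = np.concatenate([
                rng.choice(case_idx, size=case_idx.size, replace=True),
                rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
            ])
            try:
                stats[b] = metric(m[take], t[take], e[take])
                break
            except UndefinedMetricError:
                if attempt == max_retries:
                    raise
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass
class EvaluationReport:
    """Discrimination summary of one prediction window."""

    harrell_c: float
    auc_by_horizon: dict[int, float]
    n_subjects: int
    n_events: int
    mean_time_to_event: float
    ci_by_metric: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def evaluate_markers(markers, times, events, horizons=(60, 180), n_boot=500,
                     seed=None) -> EvaluationReport:
    """Full report (C, per-horizon AUC, bootstrap CIs) for a marker vector."""
    m, t, e = _as_arrays(markers, times, events)
    report = EvaluationReport(
        harrell_c=harrell_c(m, t, e),
        auc_by_horizon={int(h): cumulative_dynamic_auc(m, t, e, h) for h in horizons},
        n_subjects=int(m.size),
        n_events=int(e.sum()),
        mean_time_to_event=float(t.mean()),
        n_boot=int(n_boot),
    )
    if n_boot >= 2:
        seeds = np.random.SeedSequence(seed).generate_state(1 + len(horizons))
        report.ci_by_metric["harrell_c"] = bootstrap_ci(m, t, e, harrell_c, n_boot, int(seeds[0]))
        for i, h in enumerate(horizons):
            metric = lambda mm, tt, ee, _h=h: cumulative_dynamic_auc(mm, tt, ee, _h)
            report.ci_by_metric[f"auc_{int(h)}"] = bootstrap_ci(m, t, e, metric, n_boot, int(seeds[1 + i]))
    return report


def auc_curve(markers, times, events, days) -> "pd.DataFrame":
    """Cumulative/dynamic AUC over a grid of horizons, as (day, auc) rows.

    Days where the AUC is undefined (no cases yet, or no controls left)
    are skipped.
    """
    import pandas as pd

    rows = []
    for d in days:
        try:
            rows.append((int(d), cumulative_dynamic_auc(markers, times, events, d)))
        except UndefinedMetricError:
            continue
    return pd.DataFrame(rows, columns=["day", "auc"])


def evaluate_window(model, test_records, horizons=(60, 180), n_boot=500, seed=None) -> EvaluationReport:
    """Score a fitted window model (or window ensemble) on test records.

    ``test_records`` carries feature columns plus ``time_days``/``event``.
    The ranking marker is the forest's ensemble mortality, or for a window
    ensemble the cumulative ensembled hazard at the longest horizon.
    """
    from .forest import RandomSurvivalForest, _records_to_xy  # local import to avoid a cycle

    X, y = _records_to_xy(test_records)
    t = y["time_days"].to_numpy(float)
    e = y["event"].to_numpy(int)
    if isinstance(model, RandomSurvivalForest):
        markers = model.predict(X)
    else:  # window ensemble: cumulative ensembled hazard at the last horizon
        markers = model.cumulative_hazard_at(X.index, int(max(horizons)))
    return evaluate_markers(markers, t, e, horizons=horizons, n_boot=n_boot, seed=seed)
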