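"""End-to-end orchestration: simulate -> windows -> ensembles -> reports.

A single :class:`RunConfig` drives the whole workflow; one global seed
fans out to per-stage substreams so each stage is independently
reproducible, and every artifact is traceable to the config hash + seed
recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, build_outcomes, identify_cohort
from .dynamic import DRSFEnsemble, WindowSchedule, train_window
from .dynamic import global_importance as _global_importance
from .evaluation import evaluate_markers, evaluate_window
from .exceptions import ConfigurationError
from .features import extract_features
from .simulate import GeneratorConfig, null_config, simulate, strong_signal_config, write_dataset

logger = logging.getLogger(__name__)

_PRESETS = {"default": GeneratorConfig, "null": null_config, "strong_signal": strong_signal_config}


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    seed: int = 0
    generator_preset: str = "default"
    generator: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    first_index_date: str = "2014-02-01"
    n_windows: int = 5
    step_months: int = 1
    n_ensemble_windows: int = 5
    forest: dict = field(default_factory=lambda: {"n_estimators": 100})
    selection_delta: float = 0.005
    select_features: bool = True
    min_cohort_size: int = 50
    horizons: tuple = (60, 180)
    n_boot: int = 500

    def __post_init__(self):
        if self.generator_preset not in _PRESETS:
            raise ConfigurationError(f"unknown generator_preset {self.generator_preset!r}")
        self.cohort_spec = CohortSpec(**self.cohort)
        if max(self.horizons) > self.cohort_spec.horizon_days:
            raise ConfigurationError(
                f"evaluation horizons {tuple(self.horizons)} exceed the "
                f"{self.cohort_spec.horizon_days}-day prediction window"
            )
        if self.n_ensemble_windows < 1 or self.n_ensemble_windows > self.n_windows:
            raise ConfigurationError("n_ensemble_windows must be in [1, n_windows]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        d["horizons"] = list(self.horizons)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


def _report_dict(report):
    d = dataclasses.asdict(report)
    d["auc_by_horizon"] = {str(k): v for k, v in d["auc_by_horizon"].items()}
    return d


def run_pipeline(config: RunConfig, out_dir) -> pathlib.Path:
    """Run the full dynamic-forest workflow and write all artifacts.

    Trains one window model per schedule index date, scores each on its
    contiguous prediction window, then combines the most recent models
    into window ensembles of size 1..n_ensemble_windows on the final
    prediction window.  Writes models, evaluation reports, importance
    tables, example risk curves and a reproducibility manifest.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4)

    gen_config = _PRESETS[config.generator_preset](**{"seed": int(seeds[0]), **config.generator})
    logger.info("stage simulate: n=%d", gen_config.n_beneficiaries)
    data = simulate(gen_config)
    write_dataset(data, out / "data")

    schedule = WindowSchedule(config.first_index_date, config.n_windows, config.step_months,
                              config.cohort_spec.horizon_days)
    model_seeds = np.random.SeedSequence(int(seeds[1])).generate_state(config.n_windows)
    models = []
    window_reports = {}
    (out / "models").mkdir(exist_ok=True)
    for k, t_idx in enumerate(schedule):
        logger.info("stage train_window: %s", t_idx.date())
        model = train_window(
            data.claims, data.roster, t_idx,
            horizon_days=config.cohort_spec.horizon_days,
            cohort_spec=config.cohort_spec,
            delta=config.selection_delta, select_features=config.select_features,
            min_cohort_size=config.min_cohort_size, seed=int(model_seeds[k]),
            **config.forest,
        )
        if model is None:
            continue
        models.append(model)
        (out / "models" / f"window_{t_idx.date()}.json").write_text(model.to_json())
        # score on the contiguous prediction window
        p_idx = model.prediction_index_date
        cohort = identify_cohort(data.claims, data.roster, p_idx, config.cohort_spec)
        X = extract_features(data.claims, data.roster, cohort, p_idx)
        outcome = build_outcomes(data.claims, cohort, p_idx, config.cohort_spec).set_index("beneficiary_id")
        records = X.join(outcome[["time_days", "event"]])
        report = evaluate_window(model.forest, records[model.selected_features + ["time_days", "event"]],
                                 horizons=config.horizons, n_boot=config.n_boot, seed=int(seeds[2]) + k)
        window_reports[str(t_idx.date())] = _report_dict(report)
    if not models:
        raise RuntimeError("stage train_window: no window model could be trained")

    # ensembles on the final prediction window
    target = models[-1].prediction_index_date
    target_cohort = identify_cohort(data.claims, data.roster, target, config.cohort_spec)
    target_outcome = build_outcomes(data.claims, target_cohort, target, config.cohort_spec).set_index("beneficiary_id")
    ensemble_reports = {}
    last_ensemble = None
    for n_win in range(1, min(config.n_ensemble_windows, len(models)) + 1):
        members = models[-n_win:]
        ens = DRSFEnsemble(members, target, horizon_days=config.cohort_spec.horizon_days)
        ens.prepare(data.claims, data.roster, target_cohort, cohort_spec=config.cohort_spec)
        records = target_outcome.loc[sorted(target_cohort), ["time_days", "event"]]
        report = evaluate_window(ens, records, horizons=config.horizons,
                                 n_boot=config.n_boot, seed=int(seeds[3]) + n_win)
        ensemble_reports[f"drsf_{n_win}_windows"] = _report_dict(report)
        last_ensemble = ens

    importance = _global_importance(models)
    importance.to_csv(out / "importance.csv")

    # time-dependent AUC curve of the widest ensemble across the test window
    from .evaluation import auc_curve

    markers = last_ensemble.cumulative_hazard_at(sorted(target_cohort), config.cohort_spec.horizon_days)
    curve = auc_curve(markers, target_outcome.loc[sorted(target_cohort), "time_days"],
                      target_outcome.loc[sorted(target_cohort), "event"],
                      range(15, config.cohort_spec.horizon_days + 1, 15))
    curve.to_csv(out / "auc_curve.csv", index=False)

    # example instant-risk curves: the highest- and lowest-risk subjects
    cum = last_ensemble.cumulative_hazard_at(sorted(target_cohort), config.cohort_spec.horizon_days)
    order = np.argsort(cum)
    examples = [sorted(target_cohort)[order[-1]], sorted(target_cohort)[order[0]]]
    curves = []
    for sid in examples:
        curve = last_ensemble.instant_risk_curve(sid)
        surv = np.exp(-np.cumsum(curve.to_numpy()))
        curves.append(pd.DataFrame({"beneficiary_id": sid, "day": curve.index,
                                    "hazard": curve.to_numpy(), "survival": surv}))
    pd.concat(curves).to_csv(out / "risk_curves.csv", index=False)

    metrics = {"windows": window_reports, "ensembles": ensemble_reports}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "drsf_version": __version__,
        "n_window_models": len(models),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
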