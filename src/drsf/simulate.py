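"""Seeded synthetic claim-stream generator with a known ground-truth hazard.

The generator emulates the statistical shape of a monthly claim feed for a
congestive-heart-failure (CHF) sub-cohort of elderly beneficiaries:

* a beneficiary roster with demographics and Medicare status codes;
* per-beneficiary ground-truth covariates: chronic-condition indicators
  (Bernoulli, with Table-1-like default prevalences) and continuous
  utilization-severity scores (standard normal) that scale the intensity of
  the ED / outpatient / prescription claim streams;
* background claim lines arriving as Poisson streams at a configurable
  monthly intensity, plus scheduled "evidence" lines that stamp each flagged
  condition's ICD-9 codes into the record (a CHF-flagged beneficiary carries
  CHF-coded lines in every trailing 12-month window);
* hospital admissions as a homogeneous Poisson process per beneficiary with
  rate ``baseline_hazard * exp(beta . x)``; the first admission after any
  index date is therefore exponentially distributed with that rate, and the
  stream is stationary across sliding windows.  Admissions materialize as
  inpatient claim lines whose principal diagnosis is a CHF code.

The baseline hazard is calibrated so that with all beta = 0 the 180-day
admission probability equals ``target_event_rate_6mo``.  Everything is a
pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import codes
from .exceptions import ConfigurationError

SETTINGS = ("IP", "OP", "ED", "SNF", "HHA", "DME", "RX")

# Share of the background monthly claim intensity carried by each setting.
_SETTING_SHARE = {"OP": 0.40, "RX": 0.30, "ED": 0.10, "DME": 0.07, "SNF": 0.05, "HHA": 0.08}

# Settings whose stream intensity is scaled by a severity score.
SEVERITY_SETTINGS = {"severity_ed": "ED", "severity_op": "OP", "severity_rx": "RX"}

_CHARGE_SCALE = {"IP": 12000.0, "OP": 150.0, "ED": 800.0, "SNF": 5000.0, "HHA": 300.0, "DME": 200.0, "RX": 60.0}

_MEDICARE_STATUS = np.array(["10", "11", "20", "21", "31"])
_MEDICARE_STATUS_P = np.array([4372, 141, 351, 31, 4], dtype=float)
_DUAL_STATUS = np.array(["01", "02", "03", "04", "06", "08", "NA"])
_DUAL_STATUS_P = np.array([21, 261, 25, 59, 28, 366, 4150], dtype=float)
_RACE_P = np.array([22, 4470, 261, 51, 65, 38, 3], dtype=float)

_DAY = pd.Timedelta(days=1)


def _default_prevalences() -> dict[str, float]:
    return {
        "chf": 0.90,
        "hypertension": 0.94,
        "pulmonary_circulation_disorders": 0.21,
        "chronic_pulmonary_disease": 0.50,
        "diabetes": 0.49,
        "rheumatic_disease": 0.13,
        "renal_failure": 0.39,
        "liver_disease": 0.11,
        "psychoses": 0.13,
        "depression": 0.33,
        "obesity": 0.27,
    }


def _default_log_hazard_ratios() -> dict[str, float]:
    # Modest proportional-hazards effects on comorbidities that the source
    # cohort shows to be strongly associated with CHF admission.
    return {
        "renal_failure": 0.5,
        "pulmonary_circulation_disorders": 0.7,
        "chronic_pulmonary_disease": 0.4,
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic claim-stream generator.

    ``baseline_hazard`` (events/day) defaults to the rate calibrated so the
    180-day event probability at the covariate null equals
    ``target_event_rate_6mo``.  ``severity_scale`` is the log-intensity
    effect of each utilization-severity score on its claim stream; the
    stream mean is corrected so ``monthly_claim_intensity`` stays the exact
    mean number of background lines per beneficiary-month.
    """

    n_beneficiaries: int = 5000
    start_date: str | pd.Timestamp = "2011-02-01"
    end_date: str | pd.Timestamp = "2015-09-30"
    comorbidity_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    baseline_hazard: float | None = None
    log_hazard_ratios: dict[str, float] = field(default_factory=_default_log_hazard_ratios)
    monthly_claim_intensity: float = 1.5
    target_event_rate_6mo: float = 0.05
    seed: int = 0
    male_fraction: float = 0.435
    severity_scale: float = 0.7
    risk_start_date: str | pd.Timestamp | None = None
    mean_los_days: float = 4.0

    def __post_init__(self):
        self.start_date = pd.Timestamp(self.start_date)
        self.end_date = pd.Timestamp(self.end_date)
        if self.n_beneficiaries < 0:
            raise ConfigurationError("n_beneficiaries must be nonnegative")
        span_months = (self.end_date - self.start_date).days / 30.44
        if span_months < 42:
            raise ConfigurationError(
                "end_date must exceed start_date by at least 42 months "
                f"(got ~{span_months:.1f})"
            )
        for name, p in self.comorbidity_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"comorbidity_prevalences[{name!r}] must be in [0, 1]")
            if name not in codes.CONDITION_ICD9:
                raise ConfigurationError(f"comorbidity_prevalences names unknown condition {name!r}")
        if not 0.0 <= self.target_event_rate_6mo < 1.0:
            raise ConfigurationError("target_event_rate_6mo must be in [0, 1)")
        if self.monthly_claim_intensity < 0:
            raise ConfigurationError("monthly_claim_intensity must be nonnegative")
        if self.baseline_hazard is not None and self.baseline_hazard < 0:
            raise ConfigurationError("baseline_hazard must be nonnegative")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must be in [0, 1]")
        if self.risk_start_date is None:
            self.risk_start_date = self.start_date + pd.DateOffset(months=36)
        else:
            self.risk_start_date = pd.Timestamp(self.risk_start_date)
        if not self.start_date <= self.risk_start_date < self.end_date:
            raise ConfigurationError("risk_start_date must lie within [start_date, end_date)")

    @property
    def effective_baseline_hazard(self) -> float:
        if self.baseline_hazard is not None:
            return self.baseline_hazard
        return -np.log1p(-self.target_event_rate_6mo) / 180.0

    @property
    def truth_feature_names(self) -> list[str]:
        return sorted(self.comorbidity_prevalences) + sorted(SEVERITY_SETTINGS)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("start_date", "end_date", "risk_start_date"):
            d[k] = str(pd.Timestamp(d[k]).date())
        return d


def null_config(**overrides) -> GeneratorConfig:
    """A no-signal stream: every log hazard ratio is zero."""
    overrides.setdefault("log_hazard_ratios", {})
    return GeneratorConfig(**overrides)


#: The p = 10 candidate features of the strong-signal validation stream.
STRONG_SIGNAL_FEATURES: tuple[str, ...] = (
    "severity_ed",
    "severity_op",
    "severity_rx",
    "hypertension",
    "diabetes",
    "depression",
    "obesity",
    "renal_failure",
    "liver_disease",
    "psychoses",
)

#: The three features carrying |beta| = 1 in the strong-signal stream.
STRONG_SIGNAL_TRUE_FEATURES: tuple[str, ...] = ("severity_ed", "severity_op", "severity_rx")


def strong_signal_config(**overrides) -> GeneratorConfig:
    """A strong-signal stream: three |beta| = 1 utilization-severity scores.

    The signal features are continuous N(0, 1) scores so the oracle model's
    concordance (~0.79 for the exponential model with this linear-predictor
    spread) comfortably exceeds the discrimination a well-built forest is
    expected to reach; three Bernoulli(0.5) indicators at the same |beta|
    would cap even the oracle near 0.69.  Claim intensities are raised so
    the severity scores are recoverable from window claim counts.
    """
    overrides.setdefault(
        "log_hazard_ratios",
        {"severity_ed": 1.0, "severity_op": 1.0, "severity_rx": -1.0},
    )
    overrides.setdefault(
        "comorbidity_prevalences",
        {
            "chf": 1.0,
            "hypertension": 0.5,
            "diabetes": 0.5,
            "depression": 0.3,
            "obesity": 0.3,
            "renal_failure": 0.4,
            "liver_disease": 0.15,
            "psychoses": 0.15,
        },
    )
    overrides.setdefault("monthly_claim_intensity", 4.0)
    return GeneratorConfig(**overrides)


# ---------------------------------------------------------------------------
# per-stage RNG streams
# ---------------------------------------------------------------------------

_STAGES = {"roster": 0, "truth": 1, "claims": 2, "admissions": 3}


def _rng(config: GeneratorConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGES[stage],)))


# ---------------------------------------------------------------------------
# roster & ground truth
# ---------------------------------------------------------------------------

def simulate_roster(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the beneficiary roster (one row per beneficiary)."""
    rng = rng or _rng(config, "roster")
    n = config.n_beneficiaries
    ids = np.array([f"BENE{i:07d}" for i in range(n)])
    age_years = rng.uniform(60.0, 99.0, n)
    birth = config.start_date - pd.to_timedelta(np.round(age_years * 365.25), unit="D")
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    race = rng.choice(7, size=n, p=_RACE_P / _RACE_P.sum())
    mstat = rng.choice(_MEDICARE_STATUS, size=n, p=_MEDICARE_STATUS_P / _MEDICARE_STATUS_P.sum())
    dstat = rng.choice(_DUAL_STATUS, size=n, p=_DUAL_STATUS_P / _DUAL_STATUS_P.sum())
    return pd.DataFrame(
        {
            "beneficiary_id": ids,
            "birth_date": birth,
            "sex": sex,
            "race_code": race.astype(int),
            "medicare_status_code": mstat,
            "dual_status_code": dstat,
        }
    )


def simulate_truth(
    roster: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the ground-truth covariates the hazard model acts on."""
    rng = rng or _rng(config, "truth")
    n = len(roster)
    out = {}
    for name in sorted(config.comorbidity_prevalences):
        out[name] = (rng.random(n) < config.comorbidity_prevalences[name]).astype(int)
    for name in sorted(SEVERITY_SETTINGS):
        out[name] = rng.standard_normal(n)
    return pd.DataFrame(out, index=pd.Index(roster["beneficiary_id"], name="beneficiary_id"))


def hazard_rates(features_truth: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Per-beneficiary event rate (per day): baseline * exp(beta . x)."""
    lp = np.zeros(len(features_truth))
    for name, beta in config.log_hazard_ratios.items():
        if name not in features_truth.columns:
            raise ConfigurationError(f"log_hazard_ratios names unknown feature {name!r}")
        lp += beta * features_truth[name].to_numpy(dtype=float)
    return config.effective_baseline_hazard * np.exp(lp)


# ---------------------------------------------------------------------------
# claim lines
# ---------------------------------------------------------------------------

def _uniform_dates(rng, n, start: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
    span = (end - start).days
    offs = rng.integers(0, span + 1, size=n)
    return start + pd.to_timedelta(offs, unit="D")


def _evidence_lines(roster, truth, config, rng) -> list[pd.DataFrame]:
    """Scheduled visits stamping each flagged condition's codes into claims.

    CHF evidence recurs roughly quarterly (so every trailing 12-month window
    contains at least one line); other conditions recur roughly yearly
    (covering the 36-month chronic lookback).
    """
    frames = []
    start, end = config.start_date, config.end_date
    for name in sorted(config.comorbidity_prevalences):
        flagged = truth.index[truth[name].to_numpy() == 1]
        if len(flagged) == 0:
            continue
        period, jitter = (91, 30) if name == "chf" else (300, 60)
        n_visits = (end - start).days // period + 1
        pool = np.array(sorted(codes.CONDITION_ICD9[name]))
        for k in range(n_visits):
            base = start + pd.Timedelta(days=k * period)
            offs = rng.integers(-jitter, jitter + 1, size=len(flagged))
            dates = pd.Series(base + pd.to_timedelta(offs, unit="D")).clip(start, end).to_numpy()
            dx = pool[rng.integers(0, len(pool), size=len(flagged))]
            frames.append(
                pd.DataFrame(
                    {
                        "beneficiary_id": flagged,
                        "service_start": dates,
                        "service_end": dates,
                        "setting": "OP",
                        "dx_codes": dx,
                        "principal_dx": dx,
                        "charge": np.round(rng.gamma(2.0, _CHARGE_SCALE["OP"] / 2.0, len(flagged)), 2),
                    }
                )
            )
    return frames


def _background_lines(roster, truth, config, rng) -> list[pd.DataFrame]:
    frames = []
    start, end = config.start_date, config.end_date
    months = (end - start).days / 30.44
    n = len(roster)
    ids = roster["beneficiary_id"].to_numpy()
    gamma = config.severity_scale
    generic = np.array(codes.GENERIC_ICD9)
    for setting, share in _SETTING_SHARE.items():
        rate = config.monthly_claim_intensity * share * np.ones(n)
        for score, scored_setting in SEVERITY_SETTINGS.items():
            if scored_setting == setting and gamma != 0.0:
                z = truth[score].to_numpy()
                # exp(g z - g^2/2) has mean 1: configured intensity stays the mean.
                rate = rate * np.exp(gamma * z - 0.5 * gamma**2)
        counts = rng.poisson(rate * months)
        total = int(counts.sum())
        if total == 0:
            continue
        line_ids = np.repeat(ids, counts)
        dates = _uniform_dates(rng, total, start, end)
        dx = generic[rng.integers(0, len(generic), size=total)]
        if setting == "OP":
            echo = rng.random(total) < 0.08
            pool = np.array(sorted(codes.CARDIO_ECHO_CODES | codes.SPIROMETRY_CODES | codes.PULM_FUNCTION_CODES))
            proc = pool[rng.integers(0, len(pool), size=total)]
            dx = np.where(echo, proc, dx)
        if setting == "DME":
            oxy = rng.random(total) < 0.3
            pool = np.array(sorted(codes.OXYGEN_DME_CODES))
            dx = np.where(oxy, pool[rng.integers(0, len(pool), size=total)], dx)
        if setting == "ED":
            exac = rng.random(total) < 0.25
            pool = np.array(sorted(codes.EXACERBATION_ICD9))
            dx = np.where(exac, pool[rng.integers(0, len(pool), size=total)], dx)
        charge = np.round(rng.gamma(2.0, _CHARGE_SCALE[setting] / 2.0, total), 2)
        frames.append(
            pd.DataFrame(
                {
                    "beneficiary_id": line_ids,
                    "service_start": dates,
                    "service_end": dates,
                    "setting": setting,
                    "dx_codes": dx,
                    "principal_dx": dx,
                    "charge": charge,
                }
            )
        )
    return frames


_CLAIM_COLUMNS = ["beneficiary_id", "service_start", "service_end", "setting", "dx_codes", "principal_dx", "charge"]


def _empty_claims() -> pd.DataFrame:
    df = pd.DataFrame(columns=_CLAIM_COLUMNS)
    df["service_start"] = pd.to_datetime(df["service_start"])
    df["service_end"] = pd.to_datetime(df["service_end"])
    df["charge"] = df["charge"].astype(float)
    return df


def simulate_claims(
    roster: pd.DataFrame,
    config: GeneratorConfig,
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the background + condition-evidence claim stream (no admissions)."""
    if len(roster) == 0:
        raise ConfigurationError("roster must be nonempty")
    rng = rng or _rng(config, "claims")
    if truth is None:
        truth = simulate_truth(roster, config)
    frames = _evidence_lines(roster, truth, config, rng) + _background_lines(roster, truth, config, rng)
    if not frames:
        return _empty_claims()
    claims = pd.concat(frames, ignore_index=True)
    claims = claims.sort_values(["beneficiary_id", "service_start", "setting", "dx_codes"], kind="mergesort")
    return claims.reset_index(drop=True)


# ---------------------------------------------------------------------------
# admissions / events
# ---------------------------------------------------------------------------

def simulate_admissions(
    roster: pd.DataFrame,
    features_truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw CHF admissions as a homogeneous Poisson process per beneficiary."""
    rng = rng or _rng(config, "admissions")
    rates = hazard_rates(features_truth, config)
    start, end = config.risk_start_date, config.end_date
    span = (end - start).days
    counts = rng.poisson(rates * span)
    total = int(counts.sum())
    ids = np.repeat(features_truth.index.to_numpy(), counts)
    admit = _uniform_dates(rng, total, start, end)
    los = 1 + rng.poisson(max(config.mean_los_days - 1.0, 0.0), size=total)
    discharge = admit + pd.to_timedelta(los, unit="D")
    pool = np.array(sorted(codes.CHF_ICD9))
    dx = pool[rng.integers(0, len(pool), size=total)]
    adm = pd.DataFrame(
        {"beneficiary_id": ids, "admit_date": admit, "discharge_date": discharge, "principal_dx": dx}
    )
    adm = adm.sort_values(["beneficiary_id", "admit_date"], kind="mergesort").reset_index(drop=True)
    return adm


def simulate_events(
    roster: pd.DataFrame,
    features_truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.Timestamp | None]:
    """First admission date per beneficiary (None if none occurs)."""
    adm = simulate_admissions(roster, features_truth, config, rng=rng)
    first = adm.groupby("beneficiary_id")["admit_date"].min()
    return {b: first.get(b, None) for b in roster["beneficiary_id"]}


def inject_admissions(claims: pd.DataFrame, admissions: pd.DataFrame, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Append the inpatient claim lines materializing each admission."""
    if len(admissions) == 0:
        return claims.copy()
    rng = rng or np.random.default_rng(0)
    ip = pd.DataFrame(
        {
            "beneficiary_id": admissions["beneficiary_id"].to_numpy(),
            "service_start": admissions["admit_date"].to_numpy(),
            "service_end": admissions["discharge_date"].to_numpy(),
            "setting": "IP",
            "dx_codes": admissions["principal_dx"].to_numpy(),
            "principal_dx": admissions["principal_dx"].to_numpy(),
            "charge": np.round(rng.gamma(2.0, _CHARGE_SCALE["IP"] / 2.0, len(admissions)), 2),
        }
    )
    out = pd.concat([claims, ip], ignore_index=True)
    out = out.sort_values(["beneficiary_id", "service_start", "setting", "dx_codes"], kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

@dataclass
class SimulatedClaims:
    """Bundle of everything one seeded simulation produces."""

    config: GeneratorConfig
    roster: pd.DataFrame
    truth: pd.DataFrame
    claims: pd.DataFrame
    admissions: pd.DataFrame

    @property
    def first_events(self) -> pd.Series:
        return self.admissions.groupby("beneficiary_id")["admit_date"].min()


def simulate(config: GeneratorConfig) -> SimulatedClaims:
    """Run the full generator: roster, truth, claims (with admissions)."""
    roster = simulate_roster(config)
    truth = simulate_truth(roster, config)
    claims = simulate_claims(roster, config, truth=truth)
    admissions = simulate_admissions(roster, truth, config)
    claims = inject_admissions(claims, admissions, rng=_rng(config, "claims"))
    return SimulatedClaims(config, roster, truth, claims, admissions)


def simulate_survival_table(
    config: GeneratorConfig,
    horizon_days: int = 180,
    feature_columns: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a (features, time, event) table directly from the hazard model.

    Time-to-event from any index date is exponential with the beneficiary's
    rate (the admission process is memoryless), so this table is the exact
    distribution of a window's survival records with administrative
    censoring at ``horizon_days``.  ``time_days`` is a whole day in
    [1, horizon_days].
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    roster = simulate_roster(config)
    truth = simulate_truth(roster, config)
    rates = hazard_rates(truth, config)
    rng = _rng(config, "admissions")
    t = rng.exponential(1.0, size=len(truth)) / np.maximum(rates, 1e-300)
    days = np.ceil(t).astype(int)
    event = (days <= horizon_days) & (rates > 0)
    days = np.clip(days, 1, horizon_days)
    days[~event] = horizon_days
    cols = feature_columns or config.truth_feature_names
    out = truth[list(cols)].copy()
    out["time_days"] = days
    out["event"] = event.astype(int)
    return out


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------

ROSTER_HEADER_VERSION = "drsf-roster-v1"
CLAIMS_HEADER_VERSION = "drsf-claims-v1"


def write_dataset(data: SimulatedClaims, outdir) -> None:
    """Write roster/claims/truth/admissions CSVs plus a seed manifest."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.roster.to_csv(outdir / "roster.csv", index=False, date_format="%Y-%m-%d")
    data.claims.to_csv(outdir / "claims.csv", index=False, date_format="%Y-%m-%d")
    data.truth.to_csv(outdir / "truth.csv", date_format="%Y-%m-%d")
    data.admissions.to_csv(outdir / "admissions.csv", index=False, date_format="%Y-%m-%d")
    manifest = {
        "roster_header": ROSTER_HEADER_VERSION,
        "claims_header": CLAIMS_HEADER_VERSION,
        "seed": data.config.seed,
        "config": data.config.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_roster(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["birth_date"], dtype={"medicare_status_code": str, "dual_status_code": str})


def read_claims(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["service_start", "service_end"], dtype={"dx_codes": str, "principal_dx": str})
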