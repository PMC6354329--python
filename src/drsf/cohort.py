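"""CHF cohort identification and 180-day time-to-admission outcomes.

At an index date the cohort is every beneficiary with claim evidence of CHF
comorbidity (any setting, any diagnosis position) during the trailing
lookback window.  The outcome is the first valid CHF-principal inpatient
admission within the prediction horizon, after dropping 30-day
readmissions; beneficiaries without a valid admission are right-censored
at the horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import CHF_ICD9
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

_DAY = pd.Timedelta(days=1)


@dataclass
class CohortSpec:
    """Cohort inclusion and outcome-construction rules.

    ``chf_icd9_codes`` are matched as exact normalized strings against each
    claim line's diagnosis codes ("428" matches only a literal "428", not
    its children; the children are enumerated in the default set).
    """

    chf_icd9_codes: frozenset = field(default_factory=lambda: frozenset(CHF_ICD9))
    lookback_months: int = 12
    horizon_days: int = 180
    readmission_gap_days: int = 30

    def __post_init__(self):
        for name in ("lookback_months", "horizon_days", "readmission_gap_days"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        self.chf_icd9_codes = frozenset(str(c).strip() for c in self.chf_icd9_codes)


def _dx_long(claims: pd.DataFrame) -> pd.DataFrame:
    """Explode the ';'-delimited dx_codes column to one row per code."""
    dx = claims["dx_codes"].astype(str)
    if not dx.str.contains(";", regex=False).any():
        return claims.assign(dx=dx.str.strip())
    out = claims.assign(dx=dx.str.split(";")).explode("dx")
    out["dx"] = out["dx"].str.strip()
    return out


def identify_cohort(
    claims: pd.DataFrame,
    roster: pd.DataFrame,
    index_date,
    spec: CohortSpec | None = None,
) -> set[str]:
    """Beneficiaries with CHF-coded claim evidence in the lookback window.

    The window is half-open ``[index_date - lookback, index_date)``: a line
    dated on the index date itself is future information and is excluded.
    """
    spec = spec or CohortSpec()
    index_date = pd.Timestamp(index_date)
    if len(claims) == 0:
        logger.warning("identify_cohort: empty claim table at %s", index_date.date())
        return set()
    lo = index_date - pd.DateOffset(months=spec.lookback_months)
    window = claims[(claims["service_start"] >= lo) & (claims["service_start"] < index_date)]
    if len(window) == 0:
        return set()
    dx = _dx_long(window)
    hits = dx[dx["dx"].isin(spec.chf_icd9_codes)]
    ids = set(hits["beneficiary_id"])
    if roster is not None and len(roster):
        ids &= set(roster["beneficiary_id"])
    return ids


def build_outcomes(
    claims: pd.DataFrame,
    cohort_ids,
    index_date,
    spec: CohortSpec | None = None,
) -> pd.DataFrame:
    """One survival record per cohort member at the index date.

    Candidate events are inpatient lines whose principal diagnosis is a CHF
    code with ``service_start`` in ``(index_date, index_date + horizon]``.
    Scanning candidates left to right in time, an admission starting within
    ``readmission_gap_days`` of the discharge (service_end) of the previous
    *kept* admission is dropped as a readmission (a dropped readmission
    does not reset the discharge anchor).  The first kept admission defines
    ``(time_days, event=1)``; otherwise the record is censored at the
    horizon.  An admission on the index date itself is prevalent, not
    incident, and is excluded with a warning.
    """
    spec = spec or CohortSpec()
    index_date = pd.Timestamp(index_date)
    cohort_ids = sorted(cohort_ids)
    horizon_end = index_date + pd.Timedelta(days=spec.horizon_days)

    ip = claims[
        (claims["setting"] == "IP")
        & claims["principal_dx"].astype(str).str.strip().isin(spec.chf_icd9_codes)
        & claims["beneficiary_id"].isin(cohort_ids)
    ]
    prevalent = ip[ip["service_start"] == index_date]
    if len(prevalent):
        logger.warning(
            "build_outcomes: %d admission(s) on the index date %s excluded as prevalent",
            len(prevalent), index_date.date(),
        )
    ip = ip[(ip["service_start"] > index_date) & (ip["service_start"] <= horizon_end)]
    ip = ip.sort_values(["beneficiary_id", "service_start", "service_end"], kind="mergesort")

    times = {}
    gap = pd.Timedelta(days=spec.readmission_gap_days)
    for bene, grp in ip.groupby("beneficiary_id", sort=False):
        anchor_discharge = None
        first_kept = None
        for start, end in zip(grp["service_start"], grp["service_end"]):
            if anchor_discharge is not None and start <= anchor_discharge + gap:
                continue  # readmission: dropped, anchor unchanged
            if first_kept is None:
                first_kept = start
            anchor_discharge = end
        if first_kept is not None:
            times[bene] = (first_kept - index_date).days

    records = pd.DataFrame(
        {
            "beneficiary_id": cohort_ids,
            "index_date": index_date,
            "time_days": [times.get(b, spec.horizon_days) for b in cohort_ids],
            "event": [int(b in times) for b in cohort_ids],
        }
    )
    records["time_days"] = records["time_days"].astype(int)
    return records


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["index_date"])
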