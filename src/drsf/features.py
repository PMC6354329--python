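"""Lookback feature extraction at an index date.

Features are grouped into the claim-feed categories (demographics,
socioeconomics, chronic conditions, health-care service, acute
exacerbation, DME, disease-specific procedures, medication, care location,
cost), each with its own trailing lookback window: 36 months for chronic
conditions, 12 for procedures and cost, 6 for service / exacerbation /
DME, 3 for medication, 1 for care location.  Demographics are evaluated at
the index date.  All windows are half-open ``[index - L, index)``, so no
claim dated on or after the index date can influence any feature.

Categorical features are one-hot encoded with an explicit ``NA`` level.
The chronic-condition and exacerbation code sets are configurable; the
defaults in :mod:`drsf.codes` are small illustrative stand-ins for the
richer condition lists a production feed would use.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np
import pandas as pd

from . import codes
from .exceptions import ConfigurationError

CATEGORY_LOOKBACK_MONTHS: dict[str, int | str] = {
    "demographics": "at-index",
    "socioeconomics": "at-index",
    "chronic": 36,
    "service": 6,
    "exacerbation": 6,
    "dme": 6,
    "procedure": 12,
    "medication": 3,
    "location": 1,
    "cost": 12,
}

LOCATION_LEVELS = ("home", "HHA", "SNF", "Inpatient", "Outpatient")

# Tie-break on equal dates: highest acuity wins.
_LOCATION_PRECEDENCE = {"Inpatient": 3, "SNF": 2, "HHA": 1, "Outpatient": 0}

_SETTING_TO_LOCATION = {"IP": "Inpatient", "SNF": "SNF", "HHA": "HHA", "OP": "Outpatient", "ED": "Outpatient"}


@dataclass
class FeatureDef:
    """One named feature: an extractor rule plus its lookback window."""

    name: str
    category: str
    extractor: str
    lookback_months: int | str | None = None  # None -> category default
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORY_LOOKBACK_MONTHS:
            raise ConfigurationError(f"unknown feature category {self.category!r}")
        if self.lookback_months is None:
            self.lookback_months = CATEGORY_LOOKBACK_MONTHS[self.category]
        if self.extractor not in _EXTRACTORS:
            raise ConfigurationError(f"unknown extractor {self.extractor!r} for feature {self.name!r}")


@dataclass
class FeatureSpec:
    """An ordered pool of feature definitions with unique names."""

    features: list[FeatureDef]

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigurationError("feature names must be unique")

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureSpec":
        return cls([FeatureDef(**d) for d in doc["features"]])

    @classmethod
    def from_yaml(cls, path) -> "FeatureSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {"features": [asdict(f) for f in self.features]}


def default_feature_spec(
    condition_codes: dict[str, frozenset] | None = None,
    exacerbation_codes: frozenset | None = None,
) -> FeatureSpec:
    """The default feature pool mirroring the claim-feed category table."""
    cond = condition_codes or {k: v for k, v in codes.CONDITION_ICD9.items() if k != "chf"}
    exac = exacerbation_codes or codes.EXACERBATION_ICD9
    defs: list[FeatureDef] = [
        FeatureDef("age", "demographics", "age"),
        FeatureDef("sex_male", "demographics", "sex_male"),
        FeatureDef("race", "demographics", "categorical", params={"field": "race_code", "levels": [str(i) for i in range(7)]}),
        FeatureDef("medicare_status", "socioeconomics", "categorical", params={"field": "medicare_status_code", "levels": ["10", "11", "20", "21", "31"]}),
        FeatureDef("dual_status", "socioeconomics", "categorical", params={"field": "dual_status_code", "levels": ["01", "02", "03", "04", "06", "08"]}),
    ]
    for name, cset in sorted(cond.items()):
        defs.append(FeatureDef(f"has_{name}", "chronic", "any_line_with_dx", params={"codes": sorted(cset)}))
    defs += [
        FeatureDef("count_chronic_conditions", "chronic", "condition_count", params={"code_sets": {k: sorted(v) for k, v in sorted(cond.items())}}),
        FeatureDef("charlson_index", "chronic", "charlson"),
        FeatureDef("count_ed_visits", "service", "count_lines", params={"settings": ["ED"]}),
        FeatureDef("count_ip_admissions", "service", "count_lines", params={"settings": ["IP"]}),
        FeatureDef("count_chf_ip_admissions", "service", "count_lines_with_dx", params={"settings": ["IP"], "codes": sorted(codes.CHF_ICD9), "principal_only": True}),
        FeatureDef("count_snf_stays", "service", "count_lines", params={"settings": ["SNF"]}),
        FeatureDef("count_hha_stays", "service", "count_lines", params={"settings": ["HHA"]}),
        FeatureDef("count_op_visits", "service", "count_lines", params={"settings": ["OP"]}),
        FeatureDef("count_exacerbation_visits", "exacerbation", "count_lines_with_dx", params={"settings": ["ED", "IP"], "codes": sorted(exac)}),
        FeatureDef("any_dme", "dme", "any_lines", params={"settings": ["DME"]}),
        FeatureDef("any_oxygen_dme", "dme", "any_line_with_dx", params={"settings": ["DME"], "codes": sorted(codes.OXYGEN_DME_CODES)}),
        FeatureDef("any_cardio_echo", "procedure", "any_line_with_dx", params={"codes": sorted(codes.CARDIO_ECHO_CODES)}),
        FeatureDef("any_spirometry", "procedure", "any_line_with_dx", params={"codes": sorted(codes.SPIROMETRY_CODES)}),
        FeatureDef("any_pulm_function_test", "procedure", "any_line_with_dx", params={"codes": sorted(codes.PULM_FUNCTION_CODES)}),
        FeatureDef("count_unique_prescriptions", "medication", "count_distinct_dx", params={"settings": ["RX"]}),
        FeatureDef("recent_location", "location", "most_recent_location"),
        FeatureDef("total_charge", "cost", "sum_charge"),
    ]
    return FeatureSpec(defs)


# ---------------------------------------------------------------------------
# scalar ops
# ---------------------------------------------------------------------------

def charlson_score(dx_codes: Iterable[str], mapping: dict[str, tuple[str, ...]] | None = None) -> int:
    """Weighted Charlson comorbidity score of a diagnosis-code collection.

    Categories are detected by ICD-9 prefix (Quan mapping by default), each
    category counts once, and within the diabetes / liver / malignancy
    hierarchies only the severe member contributes.
    """
    mapping = mapping or codes.QUAN_CHARLSON_ICD9_PREFIXES
    norm = {codes.normalize_icd9(c) for c in dx_codes if c}
    present = set()
    for category, prefixes in mapping.items():
        for code in norm:
            if code.startswith(tuple(prefixes)):
                present.add(category)
                break
    for mild, severe in codes.CHARLSON_HIERARCHY:
        if mild in present and severe in present:
            present.discard(mild)
    return sum(codes.CHARLSON_WEIGHTS[c] for c in present)


def most_recent_location(claims: pd.DataFrame, index_date) -> str:
    """Care setting of the latest claim line in the 1-month lookback.

    Only lines from care locations count (IP, SNF, HHA, OP; ED counts as
    Outpatient).  With no qualifying line the beneficiary is at home.  Ties
    on the same service date break by acuity:
    Inpatient > SNF > HHA > Outpatient.
    """
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.DateOffset(months=1)
    w = claims[
        (claims["service_start"] >= lo)
        & (claims["service_start"] < index_date)
        & claims["setting"].isin(_SETTING_TO_LOCATION)
    ]
    if len(w) == 0:
        return "home"
    loc = w["setting"].map(_SETTING_TO_LOCATION)
    rank = loc.map(_LOCATION_PRECEDENCE)
    order = pd.DataFrame({"date": w["service_start"], "rank": rank, "loc": loc})
    best = order.sort_values(["date", "rank"], kind="mergesort").iloc[-1]
    return str(best["loc"])


# ---------------------------------------------------------------------------
# vectorized extractors (window claims -> Series indexed by beneficiary_id)
# ---------------------------------------------------------------------------

def _dx_match_mask(claims: pd.DataFrame, code_list, principal_only=False) -> pd.Series:
    cset = {str(c).strip() for c in code_list}
    if principal_only:
        return claims["principal_dx"].astype(str).str.strip().isin(cset)
    dx = claims["dx_codes"].astype(str)
    mask = dx.isin(cset)  # fast path: single-code lines
    multi = dx.str.contains(";", regex=False) & ~mask
    if multi.any():
        split = dx[multi].str.split(";")
        mask.loc[multi] = split.map(lambda xs: any(x.strip() in cset for x in xs))
    return mask

def _x_count_lines(w, roster, ids, index_date, p):
    sub = w[w["setting"].isin(p["settings"])] if "settings" in p else w
    return sub.groupby("beneficiary_id").size()

def _x_count_lines_with_dx(w, roster, ids, index_date, p):
    sub = w[w["setting"].isin(p["settings"])] if "settings" in p else w
    sub = sub[_dx_match_mask(sub, p["codes"], p.get("principal_only", False))]
    return sub.groupby("beneficiary_id").size()

def _x_any_lines(w, roster, ids, index_date, p):
    return (_x_count_lines(w, roster, ids, index_date, p) > 0).astype(int)

def _x_any_line_with_dx(w, roster, ids, index_date, p):
    return (_x_count_lines_with_dx(w, roster, ids, index_date, p) > 0).astype(int)

def _x_sum_charge(w, roster, ids, index_date, p):
    return w.groupby("beneficiary_id")["charge"].sum()

def _explode_dx(df: pd.DataFrame) -> pd.DataFrame:
    dx = df["dx_codes"].astype(str)
    if not dx.str.contains(";", regex=False).any():
        return df.assign(dx=dx.str.strip())
    out = df.assign(dx=dx.str.split(";")).explode("dx")
    out["dx"] = out["dx"].str.strip()
    return out

def _x_count_distinct_dx(w, roster, ids, index_date, p):
    sub = w[w["setting"].isin(p["settings"])] if "settings" in p else w
    dx = _explode_dx(sub)
    return dx.groupby("beneficiary_id")["dx"].nunique()

def _x_condition_count(w, roster, ids, index_date, p):
    total = None
    for _, cset in p["code_sets"].items():
        ind = (_x_count_lines_with_dx(w, roster, ids, index_date, {"codes": cset}) > 0).astype(int)
        total = ind if total is None else total.add(ind, fill_value=0)
    return total if total is not None else pd.Series(dtype=float)

def _x_charlson(w, roster, ids, index_date, p):
    # Vectorized over the (small) set of distinct codes in the window.
    dx = _explode_dx(w)
    if len(dx) == 0:
        return pd.Series(dtype=float)
    mapping = p.get("mapping") or codes.QUAN_CHARLSON_ICD9_PREFIXES
    code_cats = {}
    for code in dx["dx"].unique():
        norm = codes.normalize_icd9(code)
        cats = [cat for cat, prefixes in mapping.items() if norm.startswith(tuple(prefixes))]
        if cats:
            code_cats[code] = cats
    hits = dx[dx["dx"].isin(code_cats)][["beneficiary_id", "dx"]].copy()
    if len(hits) == 0:
        return pd.Series(dtype=float)
    hits["cat"] = hits["dx"].map(code_cats)
    hits = hits.explode("cat").drop_duplicates(["beneficiary_id", "cat"])
    pres = pd.crosstab(hits["beneficiary_id"], hits["cat"]).astype(bool)
    for mild, severe in codes.CHARLSON_HIERARCHY:
        if mild in pres.columns and severe in pres.columns:
            pres[mild] &= ~pres[severe]
    weights = pd.Series({c: codes.CHARLSON_WEIGHTS[c] for c in pres.columns})
    return pres.astype(int) @ weights

def _x_age(w, roster, ids, index_date, p):
    age = (index_date - roster["birth_date"]).dt.days / 365.25
    return pd.Series(age.to_numpy(), index=roster["beneficiary_id"])

def _x_sex_male(w, roster, ids, index_date, p):
    return pd.Series((roster["sex"] == "M").astype(int).to_numpy(), index=roster["beneficiary_id"])

_EXTRACTORS = {
    "count_lines": _x_count_lines,
    "count_lines_with_dx": _x_count_lines_with_dx,
    "any_lines": _x_any_lines,
    "any_line_with_dx": _x_any_line_with_dx,
    "sum_charge": _x_sum_charge,
    "count_distinct_dx": _x_count_distinct_dx,
    "condition_count": _x_condition_count,
    "charlson": _x_charlson,
    "age": _x_age,
    "sex_male": _x_sex_male,
    "categorical": None,           # handled inline (multi-column)
    "most_recent_location": None,  # handled inline (multi-column)
}


def _one_hot(series: pd.Series, levels, prefix: str) -> pd.DataFrame:
    vals = series.astype(str).fillna("NA")
    vals = vals.where(vals.isin([str(l) for l in levels]), "NA")
    out = {}
    for level in list(levels) + ["NA"]:
        out[f"{prefix}_{level}"] = (vals == str(level)).astype(int)
    return pd.DataFrame(out, index=series.index)


def extract_features(
    claims: pd.DataFrame,
    roster: pd.DataFrame,
    ids,
    index_date,
    spec: FeatureSpec | None = None,
) -> pd.DataFrame:
    """Feature matrix (one row per id) at the index date.

    Purely a function of the claims inside each feature's lookback window,
    the roster, and the index date; claims dated on or after the index
    date never contribute.
    """
    spec = spec or default_feature_spec()
    index_date = pd.Timestamp(index_date)
    ids = sorted(ids)
    idx = pd.Index(ids, name="beneficiary_id")
    roster_sub = roster[roster["beneficiary_id"].isin(ids)].set_index("beneficiary_id").loc[ids].reset_index()
    claims_sub = claims[claims["beneficiary_id"].isin(ids) & (claims["service_start"] < index_date)]

    window_cache: dict[object, pd.DataFrame] = {}

    def window(lookback):
        if lookback in window_cache:
            return window_cache[lookback]
        if lookback == "at-index":
            w = claims_sub.iloc[0:0]
        else:
            lo = index_date - pd.DateOffset(months=int(lookback))
            w = claims_sub[claims_sub["service_start"] >= lo]
        window_cache[lookback] = w
        return w

    cols: list[pd.DataFrame | pd.Series] = []
    for fdef in spec.features:
        w = window(fdef.lookback_months)
        if fdef.extractor == "categorical":
            src = roster_sub.set_index("beneficiary_id")[fdef.params["field"]]
            cols.append(_one_hot(src.reindex(idx), fdef.params["levels"], fdef.name))
        elif fdef.extractor == "most_recent_location":
            wl = w[w["setting"].isin(_SETTING_TO_LOCATION)]
            if len(wl):
                ranked = pd.DataFrame(
                    {
                        "beneficiary_id": wl["beneficiary_id"],
                        "date": wl["service_start"],
                        "rank": wl["setting"].map(_SETTING_TO_LOCATION).map(_LOCATION_PRECEDENCE),
                        "loc": wl["setting"].map(_SETTING_TO_LOCATION),
                    }
                ).sort_values(["beneficiary_id", "date", "rank"], kind="mergesort")
                latest = ranked.groupby("beneficiary_id")["loc"].last()
            else:
                latest = pd.Series(dtype=object)
            series = latest.reindex(idx).fillna("home")
            series.name = fdef.name
            onehot = {}
            for level in LOCATION_LEVELS:
                onehot[f"{fdef.name}_{level}"] = (series == level).astype(int)
            cols.append(pd.DataFrame(onehot, index=idx))
        else:
            fn = _EXTRACTORS[fdef.extractor]
            series = fn(w, roster_sub, ids, index_date, fdef.params)
            series = series.reindex(idx).fillna(0.0)
            series.name = fdef.name
            cols.append(series.astype(float))
    mat = pd.concat(cols, axis=1)
    mat.index = idx
    return mat.astype(float)
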