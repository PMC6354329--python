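"""ICD-9-CM code sets shared by the simulator, cohort and feature modules.

The congestive-heart-failure (CHF) set follows Quan's update of the
Elixhauser comorbidity definition and is matched as exact normalized
strings (the cohort rules enumerate codes rather than prefixes).  The
per-condition evidence sets and the exacerbation/procedure/DME sets are
small illustrative defaults: real claim feeds carry far richer coding,
and users are expected to supply their own sets through the cohort and
feature specs.
"""

from __future__ import annotations

# Exact-match CHF definition (cohort inclusion + outcome principal dx).
CHF_ICD9: frozenset[str] = frozenset(
    {
        "398.91",
        "402.01",
        "402.11",
        "402.91",
        "404.01",
        "404.03",
        "404.11",
        "404.13",
        "404.91",
        "404.93",
        "428",
        "428.0",
        "428.1",
        "428.9",
    }
)

# Illustrative evidence codes for the chronic conditions the simulator
# can stamp into claim lines.  Keys double as ground-truth feature names.
CONDITION_ICD9: dict[str, frozenset[str]] = {
    "chf": CHF_ICD9,
    "hypertension": frozenset({"401.1", "401.9"}),
    "pulmonary_circulation_disorders": frozenset({"416.0", "416.8", "417.9"}),
    "chronic_pulmonary_disease": frozenset({"491.21", "492.8", "496"}),
    "diabetes": frozenset({"250.00", "250.02"}),
    "rheumatic_disease": frozenset({"714.0", "710.0"}),
    "renal_failure": frozenset({"585.6", "585.9", "586"}),
    "liver_disease": frozenset({"571.2", "571.5"}),
    "psychoses": frozenset({"295.90", "297.9"}),
    "depression": frozenset({"311", "296.20"}),
    "obesity": frozenset({"278.00", "278.01"}),
}

# Acute exacerbation conditions counted on ED/IP lines (illustrative).
EXACERBATION_ICD9: frozenset[str] = frozenset(
    {"518.81", "786.05", "786.50", "276.2", "584.9"}
)

# Disease-specific procedure markers (illustrative; carried in dx_codes).
CARDIO_ECHO_CODES: frozenset[str] = frozenset({"93306", "93307", "93308"})
SPIROMETRY_CODES: frozenset[str] = frozenset({"94010", "94060"})
PULM_FUNCTION_CODES: frozenset[str] = frozenset({"94726", "94729"})

# Oxygen-related durable medical equipment markers (illustrative).
OXYGEN_DME_CODES: frozenset[str] = frozenset({"E0424", "E0439", "E1390"})

# Filler codes for background utilization lines.
GENERIC_ICD9: tuple[str, ...] = (
    "V70.0",
    "729.5",
    "780.79",
    "719.46",
    "724.2",
    "786.50",
    "530.81",
)

# ---------------------------------------------------------------------------
# Charlson comorbidity index, Quan (2005) ICD-9-CM prefix mapping.
# Prefixes are matched against normalized codes with the dot removed.
# ---------------------------------------------------------------------------

CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular": 1,
    "cerebrovascular": 1,
    "dementia": 1,
    "chronic_pulmonary": 1,
    "rheumatic": 1,
    "peptic_ulcer": 1,
    "mild_liver": 1,
    "diabetes": 1,
    "diabetes_complicated": 2,
    "paralysis": 2,
    "renal": 2,
    "malignancy": 2,
    "severe_liver": 3,
    "metastatic_cancer": 6,
    "aids": 6,
}

# Hierarchical pairs: when both members are present only the severe one counts.
CHARLSON_HIERARCHY: tuple[tuple[str, str], ...] = (
    ("diabetes", "diabetes_complicated"),
    ("mild_liver", "severe_liver"),
    ("malignancy", "metastatic_cancer"),
)

QUAN_CHARLSON_ICD9_PREFIXES: dict[str, tuple[str, ...]] = {
    "myocardial_infarction": ("410", "412"),
    "congestive_heart_failure": (
        "39891", "40201", "40211", "40291", "40401", "40403",
        "40411", "40413", "40491", "40493", "425", "428",
    ),
    "peripheral_vascular": (
        "0930", "4373", "440", "441", "4431", "4432", "4438", "4439",
        "4471", "5571", "5579", "V434",
    ),
    "cerebrovascular": ("36234", "430", "431", "432", "433", "434", "435", "436", "437", "438"),
    "dementia": ("290", "2941", "3312"),
    "chronic_pulmonary": ("4168", "4169", "490", "491", "492", "493", "494", "495", "496", "500", "501", "502", "503", "504", "505", "5064", "5081", "5088"),
    "rheumatic": ("4465", "7100", "7101", "7102", "7103", "7104", "7140", "7141", "7142", "7148", "725"),
    "peptic_ulcer": ("531", "532", "533", "534"),
    "mild_liver": ("07022", "07023", "07032", "07033", "07044", "07054", "0706", "0709", "570", "571", "5733", "5734", "5738", "5739", "V427"),
    "diabetes": ("2500", "2501", "2502", "2503", "2508", "2509"),
    "diabetes_complicated": ("2504", "2505", "2506", "2507"),
    "paralysis": ("3341", "342", "343", "3440", "3441", "3442", "3443", "3444", "3445", "3446", "3449"),
    "renal": ("40301", "40311", "40391", "40402", "40403", "40412", "40413", "40492", "40493", "582", "5830", "5831", "5832", "5834", "5836", "5837", "585", "586", "5880", "V420", "V451", "V56"),
    "malignancy": tuple(str(c) for c in range(140, 173)) + tuple(str(c) for c in range(174, 196)) + ("200", "201", "202", "203", "204", "205", "206", "207", "208", "2386"),
    "severe_liver": ("4560", "4561", "4562", "5722", "5723", "5724", "5728"),
    "metastatic_cancer": ("196", "197", "198", "199"),
    "aids": ("042", "043", "044"),
}


def normalize_icd9(code: str) -> str:
    """Strip whitespace and the decimal point from an ICD-9-CM code."""
    return code.strip().replace(".", "")
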