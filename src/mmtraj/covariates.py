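"""Dummy encoding of patient covariates for the intensity models.

Every model adjusts for age group at entry (reference 18-39) and adds one
exposure block: sex (reference male), ethnicity (reference White), IMD
quintile (reference 5, least deprived), a single risk factor with levels
never/ever/resolved (reference never), or the composite "at least one risk
factor" indicator.
"""

from __future__ import annotations

import numpy as np

AGE_GROUPS = ("18-39", "40-59", "60-79", "80+")
SEXES = ("male", "female")
ETHNICITIES = ("white", "black", "asian", "mixed", "other", "missing")
IMD_LEVELS = (1, 2, 3, 4, 5, "missing")
RISK_FACTORS = (
    "hypertension",
    "obesity",
    "cholesterol",
    "smoking",
    "alcohol",
    "substance",
)
RISK_LEVELS = ("never", "ever", "resolved")

AGE_DUMMIES = ("age_40_59", "age_60_79", "age_80plus")

#: exposure keyword -> dummy names added on top of the age block
EXPOSURES = {
    "sex": ("female",),
    "ethnicity": ("eth_black", "eth_asian", "eth_mixed", "eth_other", "eth_missing"),
    "imd": ("imd_1", "imd_2", "imd_3", "imd_4", "imd_missing"),
    "any_risk": ("any_risk",),
    **{rf: (f"{rf}_ever", f"{rf}_resolved") for rf in RISK_FACTORS},
}


def exposure_covariate_names(exposure: str) -> tuple[str, ...]:
    """Age dummies plus the dummy block for one exposure variable."""
    if exposure not in EXPOSURES:
        raise ValueError(
            f"unknown exposure {exposure!r}; choose from {sorted(EXPOSURES)}"
        )
    return AGE_DUMMIES + EXPOSURES[exposure]


def _dummy_value(patient, name: str) -> float:
    rf = patient.risk_factors
    if name == "age_40_59":
        return float(patient.age_group == "40-59")
    if name == "age_60_79":
        return float(patient.age_group == "60-79")
    if name == "age_80plus":
        return float(patient.age_group == "80+")
    if name == "female":
        return float(patient.sex == "female")
    if name.startswith("eth_"):
        return float(patient.ethnicity == name.removeprefix("eth_"))
    if name.startswith("imd_"):
        level = name.removeprefix("imd_")
        target = level if level == "missing" else int(level)
        return float(patient.imd_quintile == target)
    if name == "any_risk":
        return float(any(v != "never" for v in rf.values()))
    for factor in RISK_FACTORS:
        if name == f"{factor}_ever":
            return float(rf.get(factor, "never") == "ever")
        if name == f"{factor}_resolved":
            return float(rf.get(factor, "never") == "resolved")
    raise ValueError(f"unknown covariate dummy {name!r}")


def encode_covariates(patient, names: tuple[str, ...]) -> np.ndarray:
    """One dummy per name; reference categories encode as all-zero blocks."""
    return np.array([_dummy_value(patient, n) for n in names], dtype=float)


def encode_cohort(patients, names: tuple[str, ...]) -> np.ndarray:
    if not names:
        return np.zeros((len(patients), 0))
    return np.vstack([encode_covariates(p, names) for p in patients])
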