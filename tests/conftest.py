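"""Shared fixtures: catalogues, toy patients, and recovery-study configs."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from mmtraj import CohortConfig, ConditionEvent, PatientRecord, default_catalogue
from mmtraj.covariates import RISK_FACTORS
from mmtraj.intensity import IntensityModel, model_from_rates

#: truth rates for the parameter-recovery study: every transition well
#: observed at n=5000 over a median 4.2-year follow-up
RECOVERY_BASELINES = {
    (0, 1): 0.12, (1, 2): 0.12, (2, 3): 0.12,
    (0, 4): 0.03, (1, 4): 0.03, (2, 4): 0.03, (3, 4): 0.03,
    (1, 0): 0.06, (2, 1): 0.06, (3, 2): 0.06,
}


def recovery_truth(hr_s1_s2: float = 1.5) -> IntensityModel:
    """One binary covariate (female) multiplying the S1->S2 intensity."""
    return model_from_rates(
        RECOVERY_BASELINES, {(1, 2): {"female": hr_s1_s2}}, ("female",)
    )


def recovery_config(n: int, seed: int) -> CohortConfig:
    return CohortConfig(
        n_patients=n,
        seed=seed,
        truth=recovery_truth(),
        initial_state_probs=(0.55, 0.20, 0.15, 0.10),
    )


def cluster_recovery_config(n: int, seed: int) -> CohortConfig:
    """Multimorbidity-enriched cohort so acquisition sequences are dense."""
    truth = model_from_rates(
        {
            (0, 1): 0.25, (1, 2): 0.25, (2, 3): 0.25,
            (0, 4): 0.01, (1, 4): 0.01, (2, 4): 0.01, (3, 4): 0.02,
            (1, 0): 0.05, (2, 1): 0.05, (3, 2): 0.05,
        }
    )
    return CohortConfig(
        n_patients=n,
        seed=seed,
        truth=truth,
        initial_state_probs=(0.30, 0.30, 0.20, 0.20),
        same_cluster_weight=0.7,
    )


def make_patient(
    pid: str = "P1",
    start: date = date(2010, 1, 1),
    years: float = 4.0,
    died: bool = False,
    sex: str = "male",
    age_group: str = "18-39",
    ethnicity: str = "white",
    imd: int | str = 3,
    risk_factors: dict | None = None,
) -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        follow_up_start=start,
        follow_up_end=start + timedelta(days=round(years * 365.25)),
        died=died,
        sex=sex,
        age_group=age_group,
        ethnicity=ethnicity,
        imd_quintile=imd,
        risk_factors=risk_factors or {f: "never" for f in RISK_FACTORS},
    )


def event(pid, condition, onset, resolve=None):
    return ConditionEvent(pid, condition, onset, resolve)


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
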