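"""Synthetic EHR cohort generator for LTC-trajectory analyses.

Simulates patients whose latent five-state path (number of active long-term
conditions capped at 3+, plus death) follows a continuous-time Markov chain
with covariate-dependent intensities, then renders the path as dated
condition onset/resolution events the way a primary-care extract records
them.  The generator provides ground truth for parameter-recovery testing:
the latent path is a pure Markov realisation of the configured truth model
(Gillespie exponential sojourns), and event rendering never alters it.

Rendering guarantees that every downward move resolves a condition that is
currently active and flagged resolvable.  Because the full path is known at
rendering time, a look-ahead demand policy decides at each onset whether the
drawn condition must be resolvable: at any point the number of active
resolvable conditions is kept at or above the maximum net number of future
downward moves, which is always feasible since the path never goes below
zero conditions.  Condition identities otherwise follow a cluster-weighted
preference (conditions tend to follow others from the same A-F cluster),
giving the disease-sequence module recoverable structure.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
from scipy.stats import norm

from .catalogue import Catalogue, default_catalogue
from .covariates import (
    AGE_GROUPS,
    ETHNICITIES,
    IMD_LEVELS,
    RISK_FACTORS,
    RISK_LEVELS,
    SEXES,
    encode_covariates,
)
from .intensity import IntensityModel, model_from_rates, validate_generator
from .states import DEATH, LIVING_STATES

DAYS_PER_YEAR = 365.25


def years_between(d0: date, d1: date) -> float:
    return (d1 - d0).days / DAYS_PER_YEAR


@dataclass
class PatientRecord:
    patient_id: str
    follow_up_start: date
    follow_up_end: date
    died: bool
    sex: str
    age_group: str
    ethnicity: str
    imd_quintile: int | str
    risk_factors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.follow_up_end <= self.follow_up_start:
            raise ValueError(
                f"{self.patient_id}: follow-up end must be after start "
                "(zero-length registrations are excluded)"
            )

    @property
    def follow_up_years(self) -> float:
        return years_between(self.follow_up_start, self.follow_up_end)


@dataclass
class ConditionEvent:
    patient_id: str
    condition: str
    onset_date: date
    resolve_date: Optional[date] = None

    def __post_init__(self):
        if self.resolve_date is not None and self.resolve_date < self.onset_date:
            raise ValueError(
                f"{self.patient_id}/{self.condition}: resolution before onset"
            )


@dataclass(frozen=True)
class TimedEvent:
    """A condition episode in fractional years since follow-up start."""

    condition: str
    onset: float
    resolve: Optional[float] = None


def default_truth() -> IntensityModel:
    """Default truth intensities: plausible per-year rates for an adult
    primary-care population, with age-at-entry and sex effects."""
    names = ("age_40_59", "age_60_79", "age_80plus", "female")
    baselines = {
        (0, 1): 0.028, (1, 2): 0.10, (2, 3): 0.12,
        (0, 4): 0.0012, (1, 4): 0.004, (2, 4): 0.008, (3, 4): 0.02,
        (1, 0): 0.03, (2, 1): 0.045, (3, 2): 0.04,
    }
    hr = {
        (0, 1): {"age_40_59": 1.68, "age_60_79": 3.63, "age_80plus": 4.04, "female": 1.50},
        (1, 2): {"age_40_59": 1.87, "age_60_79": 7.88, "age_80plus": 2.00, "female": 1.17},
        (2, 3): {"age_40_59": 1.33, "age_60_79": 2.22, "age_80plus": 4.49, "female": 1.02},
        (0, 4): {"age_40_59": 3.00, "age_60_79": 36.7, "age_80plus": 60.0, "female": 0.75},
        (1, 4): {"age_40_59": 4.17, "age_60_79": 16.5, "age_80plus": 25.0, "female": 0.43},
        (2, 4): {"age_40_59": 3.22, "age_60_79": 9.70, "age_80plus": 15.0, "female": 0.65},
        (3, 4): {"age_40_59": 2.95, "age_60_79": 10.2, "age_80plus": 33.8, "female": 0.67},
        (1, 0): {"age_40_59": 0.44, "age_60_79": 0.39, "age_80plus": 0.28, "female": 1.05},
        (2, 1): {"age_40_59": 1.31, "age_60_79": 4.90, "age_80plus": 3.00, "female": 1.02},
        (3, 2): {"age_40_59": 0.38, "age_60_79": 0.19, "age_80plus": 0.27, "female": 0.87},
    }
    return model_from_rates(baselines, hr, names)


def default_prevalences() -> dict:
    """Marginal covariate distributions of an urban multi-ethnic borough."""
    return {
        "sex": {"male": 0.48, "female": 0.52},
        "age_group": {"18-39": 0.747, "40-59": 0.182, "60-79": 0.057, "80+": 0.014},
        "ethnicity": {
            "white": 0.539, "black": 0.138, "asian": 0.060,
            "mixed": 0.038, "other": 0.029, "missing": 0.196,
        },
        "imd": {1: 0.174, 2: 0.468, 3: 0.264, 4: 0.069, 5: 0.014, "missing": 0.011},
        "risk_factors": {
            "hypertension": {"never": 0.85, "ever": 0.13, "resolved": 0.02},
            "obesity": {"never": 0.868, "ever": 0.113, "resolved": 0.019},
            "cholesterol": {"never": 0.814, "ever": 0.186, "resolved": 0.0},
            "smoking": {"never": 0.580, "ever": 0.257, "resolved": 0.163},
            "alcohol": {"never": 0.986, "ever": 0.0124, "resolved": 0.0016},
            "substance": {"never": 0.971, "ever": 0.029, "resolved": 0.0},
        },
    }


@dataclass
class CohortConfig:
    n_patients: int
    seed: int = 0
    study_window: tuple[date, date] = (date(2005, 4, 1), date(2020, 5, 1))
    registration_median_years: float = 4.2
    registration_iqr_years: tuple[float, float] = (1.8, 8.4)
    initial_state_probs: tuple[float, ...] = (0.76, 0.15, 0.05, 0.04)
    covariate_prevalences: dict = field(default_factory=default_prevalences)
    truth: IntensityModel = field(default_factory=default_truth)
    same_cluster_weight: float = 0.7
    prior_onset_window_years: float = 10.0
    catalogue: Catalogue = field(default_factory=default_catalogue)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if abs(sum(self.initial_state_probs) - 1.0) > 1e-12:
            raise ValueError("initial_state_probs must sum to 1")
        if len(self.initial_state_probs) != 4:
            raise ValueError("initial_state_probs must cover states {0,1,2,3+}")
        if not 0.0 <= self.same_cluster_weight <= 1.0:
            raise ValueError("same_cluster_weight must lie in [0, 1]")
        if self.study_window[1] <= self.study_window[0]:
            raise ValueError("study window end must be after start")
        q1, q3 = self.registration_iqr_years
        if not 0 < q1 < q3:
            raise ValueError("registration IQR must satisfy 0 < q1 < q3")
        prev = self.covariate_prevalences
        blocks = [prev["sex"], prev["age_group"], prev["ethnicity"], prev["imd"]]
        blocks += list(prev["risk_factors"].values())
        for block in blocks:
            if abs(sum(block.values()) - 1.0) > 1e-12:
                raise ValueError(f"category probabilities must sum to 1: {block}")
        # truth model structure is checked by IntensityModel itself


def simulate_path_q(
    Q: np.ndarray,
    t_max: float,
    initial_state: int,
    rng: np.random.Generator,
) -> list[tuple[float, int]]:
    """Gillespie simulation of one path under intensity matrix Q.

    Returns ordered (time, state) pairs starting at (0, initial_state); the
    path ends at t_max (censoring) or on absorption into death.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if initial_state not in LIVING_STATES:
        raise ValueError(
            f"initial state must be a living state, got {initial_state}"
        )
    path = [(0.0, int(initial_state))]
    t, s = 0.0, int(initial_state)
    while True:
        rates = Q[s].copy()
        rates[s] = 0.0
        total = rates.sum()
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        u = rng.random() * total
        s = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        path.append((t, s))
        if s == DEATH:
            break
    return path


def simulate_path(
    model: IntensityModel,
    covariates: np.ndarray | None,
    t_max: float,
    initial_state: int,
    rng: np.random.Generator,
) -> list[tuple[float, int]]:
    return simulate_path_q(model.intensity_matrix(covariates), t_max, initial_state, rng)


def _future_demand(moves: list[int]) -> list[int]:
    """needed[i] = max(0, max prefix sum of moves[i:]) with down=+1, up=-1.

    The value is the number of resolvable conditions that must be active
    before move i for all future downward moves to be servable.
    """
    needed = [0] * (len(moves) + 1)
    m = 0  # max prefix sum of the suffix, possibly negative
    first = True
    for i in range(len(moves) - 1, -1, -1):
        v = 1 if moves[i] < 0 else -1
        m = v + (0 if first else max(0, m))
        first = False
        needed[i] = max(0, m)
    return needed


def _draw_condition(
    candidates: list[str],
    last_cluster: str | None,
    w_same: float,
    catalogue: Catalogue,
    rng: np.random.Generator,
) -> str:
    if not candidates:
        raise RuntimeError("condition pool exhausted during rendering")
    if last_cluster is None or len(candidates) == 1:
        return candidates[int(rng.integers(len(candidates)))]
    counts = Counter(catalogue.cluster_of(c) for c in candidates)
    w = np.array(
        [
            (w_same if catalogue.cluster_of(c) == last_cluster else (1.0 - w_same) / 5.0)
            / counts[catalogue.cluster_of(c)]
            for c in candidates
        ]
    )
    total = w.sum()
    if total <= 0:
        return candidates[int(rng.integers(len(candidates)))]
    u = rng.random() * total
    return candidates[int(np.searchsorted(np.cumsum(w), u, side="right"))]


def render_events(
    path: list[tuple[float, int]],
    catalogue: Catalogue,
    rng: np.random.Generator,
    same_cluster_weight: float = 0.7,
    prior_onset_window_years: float = 10.0,
) -> list[TimedEvent]:
    """Render a latent path as condition episodes (times in years).

    Each upward move becomes an onset, each downward move a resolution of an
    active resolvable condition; a nonzero starting state is supplied with
    prior onsets dated before follow-up start.  Raises if a downward move
    finds no active resolvable condition (internal invariant violation).
    """
    if not path or path[0][0] != 0.0:
        raise ValueError("path must start at time 0")
    c0 = path[0][1]
    if c0 == DEATH:
        raise ValueError("path cannot start in the death state")
    moves: list[tuple[float, int]] = []  # (time, +1/-1), death excluded
    for (t0, s0), (t1, s1) in zip(path, path[1:]):
        if s1 == DEATH:
            break
        moves.append((t1, s1 - s0))
    needed = _future_demand([m for _, m in moves])

    all_codes = list(catalogue.codes)
    resolvable = set(catalogue.resolvable_codes)
    used: set[str] = set()
    active: dict[str, float] = {}  # code -> onset time
    episodes: list[list] = []  # [code, onset, resolve]
    by_code: dict[str, list] = {}
    last_cluster: str | None = None
    n_res_active = 0

    def do_onset(t: float, must_resolvable: bool) -> None:
        nonlocal last_cluster, n_res_active
        pool = [c for c in all_codes if c not in used]
        if must_resolvable:
            pool = [c for c in pool if c in resolvable]
        code = _draw_condition(pool, last_cluster, same_cluster_weight, catalogue, rng)
        used.add(code)
        active[code] = t
        ep = [code, t, None]
        episodes.append(ep)
        by_code[code] = ep
        last_cluster = catalogue.cluster_of(code)
        if code in resolvable:
            n_res_active += 1

    # prior onsets establishing the starting state, ensuring enough
    # resolvable conditions for the whole future demand of the path
    prior_times = np.sort(rng.uniform(-prior_onset_window_years, 0.0, size=c0))
    # exclusive of 0 so a prior onset is never confused with a transition
    prior_times = np.minimum(prior_times, -1e-9)
    for k, t in enumerate(prior_times):
        slots_left = c0 - k
        force = n_res_active + (slots_left - 1) < needed[0]
        do_onset(float(t), force)

    for i, (t, mv) in enumerate(moves):
        if mv == +1:
            do_onset(t, must_resolvable=n_res_active < needed[i + 1])
        else:
            choices = sorted(c for c in active if c in resolvable)
            if not choices:
                raise RuntimeError(
                    "downward move with no active resolvable condition "
                    "(generator invariant violated)"
                )
            code = choices[int(rng.integers(len(choices)))]
            by_code[code][2] = t
            del active[code]
            n_res_active -= 1
    return [TimedEvent(c, on, res) for c, on, res in episodes]


def _sample_categorical(rng, levels, probs_by_level, size):
    p = np.array([probs_by_level[lv] for lv in levels], dtype=float)
    idx = rng.choice(len(levels), size=size, p=p / p.sum())
    return [levels[i] for i in idx]


def _timed_to_dated(
    pid: str, start: date, end_days: int, ev: TimedEvent
) -> ConditionEvent:
    on_day = min(round(ev.onset * DAYS_PER_YEAR), end_days)
    resolve = None
    if ev.resolve is not None:
        res_day = min(round(ev.resolve * DAYS_PER_YEAR), end_days)
        resolve = start + timedelta(days=max(res_day, on_day))
    return ConditionEvent(
        patient_id=pid,
        condition=ev.condition,
        onset_date=start + timedelta(days=on_day),
        resolve_date=resolve,
    )


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[ConditionEvent]]:
    """Simulate a full cohort: patient table plus dated condition events.

    Deterministic given ``config.seed``.  Each patient's follow-up duration
    is lognormal (median/IQR from the registration model, truncated to the
    study window) with entry uniform over the feasible window; the latent
    path is simulated from the truth model given the patient's covariates
    and rendered to events at day resolution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cat = config.catalogue
    prev = config.covariate_prevalences
    window_start, window_end = config.study_window
    window_years = years_between(window_start, window_end)

    sexes = _sample_categorical(rng, SEXES, prev["sex"], n)
    ages = _sample_categorical(rng, AGE_GROUPS, prev["age_group"], n)
    eths = _sample_categorical(rng, ETHNICITIES, prev["ethnicity"], n)
    imds = _sample_categorical(rng, IMD_LEVELS, prev["imd"], n)
    rfs = {
        f: _sample_categorical(rng, RISK_LEVELS, prev["risk_factors"][f], n)
        for f in RISK_FACTORS
    }

    q1, q3 = config.registration_iqr_years
    sigma = math.log(q3 / q1) / (2.0 * norm.ppf(0.75))
    durations = rng.lognormal(math.log(config.registration_median_years), sigma, n)
    durations = np.clip(durations, 2.0 / DAYS_PER_YEAR, window_years)
    entries = rng.uniform(0.0, window_years - durations)
    init_states = rng.choice(
        4, size=n, p=np.asarray(config.initial_state_probs, dtype=float)
    )

    q_cache: dict[tuple, np.ndarray] = {}
    patients: list[PatientRecord] = []
    events: list[ConditionEvent] = []
    for i in range(n):
        pid = f"P{i + 1:06d}"
        start = window_start + timedelta(days=round(entries[i] * DAYS_PER_YEAR))
        record = PatientRecord(
            patient_id=pid,
            follow_up_start=start,
            follow_up_end=start + timedelta(days=1),  # provisional
            died=False,
            sex=sexes[i],
            age_group=ages[i],
            ethnicity=eths[i],
            imd_quintile=imds[i],
            risk_factors={f: rfs[f][i] for f in RISK_FACTORS},
        )
        x = encode_covariates(record, config.truth.covariate_names)
        key = tuple(x)
        Q = q_cache.get(key)
        if Q is None:
            Q = config.truth.intensity_matrix(x)
            validate_generator(Q)
            q_cache[key] = Q
        path = simulate_path_q(Q, float(durations[i]), int(init_states[i]), rng)
        died = path[-1][1] == DEATH
        t_end = path[-1][0] if died else float(durations[i])
        end_days = max(1, round(t_end * DAYS_PER_YEAR))
        record.follow_up_end = start + timedelta(days=end_days)
        record.died = died
        patients.append(record)
        for ev in render_events(
            path, cat, rng, config.same_cluster_weight, config.prior_onset_window_years
        ):
            events.append(_timed_to_dated(pid, start, end_days, ev))
    return patients, events
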