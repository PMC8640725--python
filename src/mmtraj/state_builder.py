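"""Build five-state histories from condition events and classify patients.

A patient's state at time t (years since follow-up start) is the number of
conditions with onset on or before t and no resolution on or before t,
capped at three.  Onsets dated before follow-up start set the starting
state; resolutions dated on/before follow-up start are ignored entirely, so
such conditions count at baseline and never produce downward transitions
(the convention for cancer remission codes, all of which predate follow-up
in the source data).  A death indicator appends the absorbing state at the
end of follow-up.

Same-day records are sequenced deterministically — resolutions before
onsets, then alphabetically by condition code — and separated by a small
epsilon so consecutive states always differ by a single step, independent
of input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ConditionEvent, PatientRecord, years_between
from .covariates import RISK_FACTORS
from .states import DEATH, state_of_count

#: default spacing between same-day records: one day, in years
DEFAULT_EPSILON = 1.0 / 365.25

CLASS_LABELS = ("Stable", "Progressed", "Remitted")


@dataclass
class StateHistory:
    patient_id: str
    observations: list[tuple[float, int]]  # (years since start, state)
    end_time: float  # follow-up duration in years
    censored: bool
    start_count: int  # uncapped LTC count at follow-up start
    end_count: int  # uncapped LTC count at end (at death time if died)
    n_acquired: int = 0  # onsets during follow-up
    n_resolved: int = 0  # resolutions during follow-up

    @property
    def died(self) -> bool:
        return not self.censored


@dataclass(frozen=True)
class TrajectoryClass:
    label: str
    ltc_count_start: int
    ltc_count_end: int
    died: bool


def classify_patient(
    history_start_count: int, history_end_count: int, died: bool
) -> TrajectoryClass:
    """Stable / Progressed / Remitted from uncapped start and end counts.

    Death classifies as Progressed regardless of counts; otherwise more
    conditions at the end is Progressed, fewer is Remitted, equal is Stable.
    """
    if history_start_count < 0 or history_end_count < 0:
        raise ValueError("condition counts must be non-negative")
    if died or history_end_count > history_start_count:
        label = "Progressed"
    elif history_end_count < history_start_count:
        label = "Remitted"
    else:
        label = "Stable"
    return TrajectoryClass(label, history_start_count, history_end_count, died)


def classify_history(history: StateHistory) -> TrajectoryClass:
    return classify_patient(history.start_count, history.end_count, history.died)


def history_from_times(
    patient_id: str,
    end_time: float,
    died: bool,
    episodes: list[tuple[str, float, float | None]],
    epsilon: float = DEFAULT_EPSILON,
    strict: bool = False,
) -> StateHistory:
    """Core builder over (condition, onset_years, resolve_years) episodes."""
    if end_time <= 0:
        raise ValueError(f"{patient_id}: follow-up duration must be positive")
    baseline = 0
    changes: list[tuple[float, int, int, str]] = []  # (t, kind, delta, code)
    n_acq = n_res = 0
    for code, t_on, t_res in episodes:
        if t_res is not None and t_res < t_on:
            raise ValueError(f"{patient_id}/{code}: resolution precedes onset")
        if t_res is not None and t_res <= 0:
            t_res = None  # pre-start resolution: counts at baseline only
        if t_on > end_time:
            msg = f"{patient_id}/{code}: onset after follow-up end"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + "; event dropped", stacklevel=2)
            continue
        if t_res is not None and t_res > end_time:
            t_res = None  # resolves after window: active throughout
        if t_res is not None and t_res == t_on:
            continue  # zero-length episode never affects the count
        if t_on <= 0:
            baseline += 1
        else:
            changes.append((t_on, 1, +1, code))
            n_acq += 1
        if t_res is not None:
            changes.append((t_res, 0, -1, code))
            n_res += 1
    # deterministic same-time order: resolutions first, then by code
    changes.sort(key=lambda c: (c[0], c[1], c[3]))

    # epsilon-space coincident records so each step is a single transition
    limit = end_time - (epsilon if died else 0.0)
    times = []
    prev = 0.0
    overflow_at = None
    for idx, (t, _, _, _) in enumerate(changes):
        t_adj = max(t, prev + epsilon)
        if t_adj > limit:
            overflow_at = idx
            break
        times.append(t_adj)
        prev = t_adj
    if overflow_at is not None:
        # squeeze the remaining records into (prev, limit]
        n_tail = len(changes) - overflow_at
        lo = prev
        if limit <= lo:
            raise ValueError(
                f"{patient_id}: too many same-day records to sequence "
                "before end of follow-up"
            )
        for k in range(n_tail):
            times.append(lo + (limit - lo) * (k + 1) / n_tail)

    count = baseline
    observations = [(0.0, state_of_count(count))]
    for t_adj, (_, _, delta, code) in zip(times, changes):
        if delta < 0 and count == 0:
            raise ValueError(f"{patient_id}/{code}: resolution without prior onset")
        count += delta
        state = state_of_count(count)
        if state != observations[-1][1]:
            observations.append((t_adj, state))
    end_count = count
    if died:
        observations.append((end_time, DEATH))
    return StateHistory(
        patient_id=patient_id,
        observations=observations,
        end_time=end_time,
        censored=not died,
        start_count=baseline,
        end_count=end_count,
        n_acquired=n_acq,
        n_resolved=n_res,
    )


def build_state_history(
    patient: PatientRecord,
    events: list[ConditionEvent],
    epsilon: float = DEFAULT_EPSILON,
    strict: bool = False,
) -> StateHistory:
    """Five-state history of one patient from their dated condition events."""
    start = patient.follow_up_start
    episodes = []
    for ev in events:
        if ev.patient_id != patient.patient_id:
            raise ValueError(
                f"event for {ev.patient_id} passed with patient {patient.patient_id}"
            )
        t_on = years_between(start, ev.onset_date)
        t_res = (
            years_between(start, ev.resolve_date)
            if ev.resolve_date is not None
            else None
        )
        episodes.append((ev.condition, t_on, t_res))
    return history_from_times(
        patient.patient_id,
        patient.follow_up_years,
        patient.died,
        episodes,
        epsilon=epsilon,
        strict=strict,
    )


def build_cohort_histories(
    patients: list[PatientRecord],
    events: list[ConditionEvent],
    epsilon: float = DEFAULT_EPSILON,
    strict: bool = False,
) -> list[StateHistory]:
    by_patient: dict[str, list[ConditionEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    return [
        build_state_history(p, by_patient.get(p.patient_id, []), epsilon, strict)
        for p in patients
    ]


def _suppress(value: int, threshold: int | None) -> object:
    if threshold is not None and 0 < value <= threshold:
        return f"<={threshold}"
    return value


def _crosstab(rows, classes, threshold):
    df = pd.crosstab(pd.Series(rows, name="category"), pd.Series(classes, name="class"))
    for lab in CLASS_LABELS:
        if lab not in df.columns:
            df[lab] = 0
    df = df[list(CLASS_LABELS)]
    totals = df.sum(axis=1)
    out = df.copy()
    pct = df.div(totals.replace(0, np.nan), axis=0) * 100.0
    for lab in CLASS_LABELS:
        out[f"{lab}_pct"] = pct[lab].round(1).fillna(0.0)
    out.insert(0, "total", totals)
    if threshold is not None:
        for lab in ("total", *CLASS_LABELS):
            out[lab] = out[lab].map(lambda v: _suppress(int(v), threshold))
    return out.reset_index()


def _band(n: int) -> str:
    return {0: "0", 1: "1"}.get(n, "2+")


def summarize_cohort(
    patients: list[PatientRecord],
    histories: list[StateHistory],
    classes: list[TrajectoryClass],
    suppress_below: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort descriptives stratified by trajectory class.

    Returns one table per characteristic: counts with row percentages per
    class, follow-up medians (IQR), and LTCs acquired/resolved banded as
    0 / 1 / 2+.  With ``suppress_below`` set, small counts render as
    "<=threshold" (low-number suppression).
    """
    if not len(patients) == len(histories) == len(classes):
        raise ValueError("patients, histories and classes must align")
    labels = [c.label for c in classes]
    tables: dict[str, pd.DataFrame] = {}

    counts = pd.Series(labels).value_counts().reindex(CLASS_LABELS, fill_value=0)
    overall = pd.DataFrame(
        {
            "class": list(CLASS_LABELS),
            "n": [counts[lab] for lab in CLASS_LABELS],
            "pct": [
                round(100.0 * counts[lab] / max(len(classes), 1), 1)
                for lab in CLASS_LABELS
            ],
        }
    )
    if suppress_below is not None:
        overall["n"] = overall["n"].map(lambda v: _suppress(int(v), suppress_below))
    tables["classes"] = overall

    fu = pd.DataFrame({"class": labels, "years": [h.end_time for h in histories]})
    tables["follow_up_years"] = (
        fu.groupby("class")["years"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n="count",
        )
        .reindex(CLASS_LABELS)
        .round(3)
        .reset_index()
    )

    categorical = {
        "sex": [p.sex for p in patients],
        "age_group": [p.age_group for p in patients],
        "ethnicity": [p.ethnicity for p in patients],
        "imd_quintile": [str(p.imd_quintile) for p in patients],
        "ltcs_acquired": [_band(h.n_acquired) for h in histories],
        "ltcs_resolved": [_band(h.n_resolved) for h in histories],
    }
    for factor in RISK_FACTORS:
        categorical[f"rf_{factor}"] = [
            p.risk_factors.get(factor, "never") for p in patients
        ]
    for name, rows in categorical.items():
        tables[name] = _crosstab(rows, labels, suppress_below)
    return tables
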