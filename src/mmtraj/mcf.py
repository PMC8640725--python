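"""Mean cumulative function (MCF) of LTC acquisition over follow-up.

Nelson-Aalen-type recurrent-event estimator: at each distinct onset time u
(years since follow-up start) the curve steps up by

    (number of onsets at u) / (number of subjects still under follow-up at u)

Subjects leave the risk set at the end of follow-up — deregistration or
death — so death acts purely as censoring; resolutions never decrement the
curve, and onsets dated before follow-up start are baseline conditions, not
accumulation.  Ties between an event and a risk-set exit at the same time
are resolved events-first (the standard recurrent-event convention).

The estimator carries no variance band and no competing-risk correction
for death; with state-dependent mortality it can be biased upward, which is
a documented limitation rather than an assertable property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .catalogue import Catalogue, default_catalogue
from .cohort import ConditionEvent, PatientRecord, years_between
from .covariates import RISK_FACTORS


@dataclass
class MCFCurve:
    group_label: str
    times: np.ndarray  # strictly increasing event times (years)
    values: np.ndarray  # non-decreasing MCF values
    n_risk: np.ndarray  # subjects at risk at each step
    n_subjects: int

    def __post_init__(self):
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("step times must be strictly increasing")
        if len(self.values) and (np.diff(self.values) < 0).any():
            raise ValueError("MCF must be non-decreasing")

    @property
    def steps(self) -> list[tuple[float, float, int]]:
        return [
            (float(t), float(v), int(r))
            for t, v, r in zip(self.times, self.values, self.n_risk)
        ]


def mcf_at(curve: MCFCurve, t: float) -> float:
    """Right-continuous evaluation of the step function at time t >= 0."""
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = int(np.searchsorted(curve.times, t, side="right"))
    return 0.0 if idx == 0 else float(curve.values[idx - 1])


def estimate_mcf(
    patients: list[PatientRecord],
    events: list[ConditionEvent],
    group_assignment: Mapping[str, str] | None = None,
) -> list[MCFCurve]:
    """One MCF curve per group (a single "all" group if no assignment).

    ``group_assignment`` maps patient_id to a group label; unassigned
    patients are skipped.  Empty groups are omitted with a warning.
    """
    if group_assignment is None:
        group_assignment = {p.patient_id: "all" for p in patients}
    starts = {p.patient_id: p.follow_up_start for p in patients}
    durations = {p.patient_id: p.follow_up_years for p in patients}

    onsets_by_group: dict[str, list[float]] = {}
    durs_by_group: dict[str, list[float]] = {}
    for g in set(group_assignment.values()):
        durs_by_group.setdefault(g, [])
        onsets_by_group.setdefault(g, [])
    for p in patients:
        g = group_assignment.get(p.patient_id)
        if g is None:
            continue
        durs_by_group.setdefault(g, []).append(durations[p.patient_id])
        onsets_by_group.setdefault(g, [])
    for ev in events:
        g = group_assignment.get(ev.patient_id)
        if g is None or ev.patient_id not in starts:
            if ev.patient_id not in starts:
                warnings.warn(
                    f"onset for unknown patient {ev.patient_id}; excluded",
                    stacklevel=2,
                )
            continue
        t = years_between(starts[ev.patient_id], ev.onset_date)
        if t <= 0:
            continue
        if t > durations[ev.patient_id]:
            warnings.warn(
                f"{ev.patient_id}/{ev.condition}: onset outside follow-up; excluded",
                stacklevel=2,
            )
            continue
        onsets_by_group[g].append(t)

    curves = []
    for g in sorted(durs_by_group):
        durs = np.sort(np.asarray(durs_by_group[g], dtype=float))
        n = len(durs)
        if n == 0:
            warnings.warn(f"empty MCF group {g!r}; curve omitted", stacklevel=2)
            continue
        ts = np.asarray(sorted(onsets_by_group[g]), dtype=float)
        if len(ts) == 0:
            curves.append(
                MCFCurve(g, np.empty(0), np.empty(0), np.empty(0, dtype=int), n)
            )
            continue
        uniq, counts = np.unique(ts, return_counts=True)
        # at risk at u: follow-up end >= u (events processed before exits)
        n_risk = n - np.searchsorted(durs, uniq, side="left")
        increments = counts / n_risk
        curves.append(
            MCFCurve(g, uniq, np.cumsum(increments), n_risk.astype(int), n)
        )
    return curves


STRATIFIERS = (
    "baseline_ltc",
    "age_group",
    "sex",
    "ethnicity",
    "imd",
    "first_condition_cluster",
    *RISK_FACTORS,
)


def _baseline_counts(
    patients: list[PatientRecord], events: list[ConditionEvent]
) -> dict[str, int]:
    starts = {p.patient_id: p.follow_up_start for p in patients}
    counts = {p.patient_id: 0 for p in patients}
    for ev in events:
        start = starts.get(ev.patient_id)
        if start is None:
            continue
        # onset on/before start decides baseline membership; resolutions
        # dated on/before start are ignored (the pre-start-remission rule)
        if years_between(start, ev.onset_date) <= 0:
            counts[ev.patient_id] += 1
    return counts


def _first_condition_cluster(
    patients: list[PatientRecord],
    events: list[ConditionEvent],
    catalogue: Catalogue,
) -> dict[str, str]:
    first: dict[str, tuple] = {}
    for ev in events:
        key = (ev.onset_date, ev.condition)
        if ev.patient_id not in first or key < first[ev.patient_id]:
            first[ev.patient_id] = key
    return {
        p.patient_id: (
            catalogue.cluster_of(first[p.patient_id][1])
            if p.patient_id in first
            else "none"
        )
        for p in patients
    }


def group_assignment_for(
    stratifier: str,
    patients: list[PatientRecord],
    events: list[ConditionEvent],
    catalogue: Catalogue | None = None,
) -> dict[str, str]:
    """Patient -> level mapping for a named stratifier."""
    if stratifier == "baseline_ltc":
        counts = _baseline_counts(patients, events)
        return {
            pid: ("3+" if c >= 3 else str(c)) for pid, c in counts.items()
        }
    if stratifier == "age_group":
        return {p.patient_id: p.age_group for p in patients}
    if stratifier == "sex":
        return {p.patient_id: p.sex for p in patients}
    if stratifier == "ethnicity":
        return {p.patient_id: p.ethnicity for p in patients}
    if stratifier == "imd":
        return {p.patient_id: str(p.imd_quintile) for p in patients}
    if stratifier == "first_condition_cluster":
        return _first_condition_cluster(
            patients, events, catalogue or default_catalogue()
        )
    if stratifier in RISK_FACTORS:
        return {
            p.patient_id: p.risk_factors.get(stratifier, "never") for p in patients
        }
    raise ValueError(
        f"unknown stratifier {stratifier!r}; choose from {STRATIFIERS}"
    )


def mcf_panel(
    patients: list[PatientRecord],
    events: list[ConditionEvent],
    stratifiers: list[str],
    catalogue: Catalogue | None = None,
) -> dict[tuple[str, str], MCFCurve]:
    """Curves keyed by (stratifier, level) for a panel of subgroup plots."""
    out: dict[tuple[str, str], MCFCurve] = {}
    for strat in stratifiers:
        assignment = group_assignment_for(strat, patients, events, catalogue)
        for curve in estimate_mcf(patients, events, assignment):
            out[(strat, curve.group_label)] = curve
    return out


def curve_to_frame(curve: MCFCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"time": curve.times, "mcf": curve.values, "n_risk": curve.n_risk}
    )


def plot_mcf(curves: list[MCFCurve], path=None, ax=None):
    """Step plot of one or more MCF curves (optional matplotlib output)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        if len(c.times) == 0:
            continue
        ax.step(
            np.concatenate([[0.0], c.times]),
            np.concatenate([[0.0], c.values]),
            where="post",
            label=c.group_label,
        )
    ax.set_xlabel("years since start of follow-up")
    ax.set_ylabel("mean cumulative LTCs acquired")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
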