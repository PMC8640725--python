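"""First-order Markov chains over condition-acquisition sequences.

Each patient contributes an ordered sequence of first-ever condition onsets
(same-day ties broken alphabetically by condition code), optionally
terminated by a Death token.  Pooled adjacent pairs give the maximum-
likelihood transition matrix of a first-order (memoryless) chain: entry
(A, B) is the probability that B is the next condition acquired after A,
in one event step.  A condition cannot succeed itself — only first onsets
enter the sequences — so the diagonal is structurally zero, and Death has
no outgoing transitions.

Top-k selection per row (consequents) and per column (antecedents) keeps
all ties at the k-th probability and drops zero-probability entries, so a
list may hold more or fewer than k conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd

from .catalogue import Catalogue, default_catalogue
from .cohort import ConditionEvent, PatientRecord

DEATH_TOKEN = "Death"


@dataclass
class AcquisitionSequence:
    patient_id: str
    items: list[tuple[str, Optional[date]]]  # (condition code, onset date)
    died: bool = False

    @property
    def labels(self) -> list[str]:
        seq = [code for code, _ in self.items]
        return seq + [DEATH_TOKEN] if self.died else seq


def build_sequences(
    patients: list[PatientRecord],
    events: list[ConditionEvent],
    include_prior: bool = True,
) -> list[AcquisitionSequence]:
    """Ordered first-onset sequences per patient, Death appended if died.

    ``include_prior=False`` restricts to onsets dated after follow-up start
    (pre-registration conditions still carry dates and are included by
    default).  Resolutions are ignored; re-recordings of a condition keep
    only the earliest onset.
    """
    by_patient: dict[str, dict[str, date]] = {p.patient_id: {} for p in patients}
    starts = {p.patient_id: p.follow_up_start for p in patients}
    for ev in events:
        if ev.patient_id not in by_patient:
            continue
        if not include_prior and ev.onset_date <= starts[ev.patient_id]:
            continue
        seen = by_patient[ev.patient_id]
        if ev.condition not in seen or ev.onset_date < seen[ev.condition]:
            seen[ev.condition] = ev.onset_date
    out = []
    for p in patients:
        items = sorted(
            ((code, d) for code, d in by_patient[p.patient_id].items()),
            key=lambda cd: (cd[1], cd[0]),
        )
        out.append(AcquisitionSequence(p.patient_id, items, died=p.died))
    return out


@dataclass
class SequenceTransitionMatrix:
    labels: tuple[str, ...]  # condition codes + Death
    counts: np.ndarray  # observed immediate successions
    probs: np.ndarray  # row-normalised; all-zero rows stay zero
    empty_rows: tuple[str, ...] = field(default=())

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def probs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.labels, columns=self.labels)


def estimate_chain(
    sequences: list[AcquisitionSequence],
    catalogue: Catalogue | None = None,
) -> SequenceTransitionMatrix:
    """Pooled pair counts over all patients, row-normalised.

    Sequences with fewer than two labels contribute no transitions.
    """
    catalogue = catalogue or default_catalogue()
    labels = tuple(catalogue.codes) + (DEATH_TOKEN,)
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for seq in sequences:
        labs = seq.labels
        for a, b in zip(labs, labs[1:]):
            if a not in idx or b not in idx:
                raise ValueError(f"unknown condition code in sequence: {a!r}/{b!r}")
            counts[idx[a], idx[b]] += 1
    if counts.diagonal().any():
        raise ValueError("self-succession observed; sequences must be first onsets")
    row_tot = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    nz = row_tot > 0
    probs[nz] = counts[nz] / row_tot[nz, None]
    empty = tuple(lab for lab, tot in zip(labels, row_tot) if tot == 0)
    return SequenceTransitionMatrix(labels, counts, probs, empty_rows=empty)


@dataclass
class TopKSelection:
    k: int
    #: per condition: list of (condition, probability), ties at k-th kept,
    #: zero-probability entries dropped
    consequents: dict[str, list[tuple[str, float]]]
    antecedents: dict[str, list[tuple[str, float]]]


def _top_with_ties(labels, values, k) -> list[tuple[str, float]]:
    pairs = [(lab, float(v)) for lab, v in zip(labels, values) if v > 0.0]
    pairs.sort(key=lambda lv: (-lv[1], lv[0]))
    if len(pairs) <= k:
        return pairs
    threshold = pairs[k - 1][1]
    return [lv for lv in pairs if lv[1] >= threshold]


def select_top(matrix: SequenceTransitionMatrix, k: int = 3) -> TopKSelection:
    """Top-k consequents (rows) and antecedents (columns) per condition."""
    if k < 1:
        raise ValueError("k must be at least 1")
    consequents = {}
    antecedents = {}
    for i, lab in enumerate(matrix.labels):
        consequents[lab] = _top_with_ties(matrix.labels, matrix.probs[i, :], k)
        antecedents[lab] = _top_with_ties(matrix.labels, matrix.probs[:, i], k)
    return TopKSelection(k=k, consequents=consequents, antecedents=antecedents)


def _render(pairs: list[tuple[str, float]]) -> str:
    return "; ".join(f"{lab} ({p:.3f})" for lab, p in pairs)


def chain_report(
    patients: list[PatientRecord],
    events: list[ConditionEvent],
    catalogue: Catalogue | None = None,
    by: str | None = None,
    k: int = 3,
    include_prior: bool = True,
) -> pd.DataFrame:
    """Per-condition antecedent/consequent report, optionally stratified.

    Columns: stratum level, condition, cluster, prevalence in the stratum,
    and rendered top-k antecedent and consequent lists (Death appears as a
    consequent-only token).
    """
    catalogue = catalogue or default_catalogue()
    if by is None:
        strata = {"overall": patients}
    elif by in ("sex", "ethnicity", "imd"):
        strata = {}
        for p in patients:
            level = str(
                {"sex": p.sex, "ethnicity": p.ethnicity, "imd": p.imd_quintile}[by]
            )
            strata.setdefault(level, []).append(p)
        strata = dict(sorted(strata.items()))
    else:
        raise ValueError(f"unsupported stratifier {by!r}")

    rows = []
    for level, group in strata.items():
        pids = {p.patient_id for p in group}
        group_events = [ev for ev in events if ev.patient_id in pids]
        seqs = build_sequences(group, group_events, include_prior=include_prior)
        matrix = estimate_chain(seqs, catalogue)
        sel = select_top(matrix, k=k)
        have = {code: set() for code in catalogue.codes}
        for seq in seqs:
            for code, _ in seq.items:
                have[code].add(seq.patient_id)
        n = max(len(group), 1)
        for code in (*catalogue.codes, DEATH_TOKEN):
            is_cond = code != DEATH_TOKEN
            rows.append(
                {
                    "stratum": by or "overall",
                    "level": level,
                    "condition": code,
                    "cluster": catalogue.cluster_of(code) if is_cond else "",
                    "prevalence": round(len(have[code]) / n, 4) if is_cond else np.nan,
                    "antecedents": _render(sel.antecedents[code]),
                    "consequents": _render(sel.consequents[code]) if is_cond else "",
                }
            )
    return pd.DataFrame(rows)
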