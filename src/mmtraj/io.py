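"""File I/O, validation, configuration and pipeline orchestration.

Tables travel as CSV with ISO-8601 dates.  ``patients.csv`` holds one row
per patient (follow-up window, death flag, covariates, one ``rf_<factor>``
column per risk factor); ``events.csv`` one row per condition episode.
Reading validates against the condition catalogue and collects structured
row-level errors.  ``run_pipeline`` chains simulate -> build-states ->
summarise -> MCF -> multistate fits -> disease chains into one deterministic
run, writing a manifest and a sidecar metadata JSON next to every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalogue import Catalogue, default_catalogue, load_catalogue
from .chain import chain_report
from .cohort import CohortConfig, ConditionEvent, PatientRecord, simulate_cohort
from .covariates import RISK_FACTORS, encode_cohort, exposure_covariate_names
from .mcf import curve_to_frame, mcf_panel
from .msm import fit, hazard_ratios, one_year_report
from .state_builder import (
    build_cohort_histories,
    classify_history,
    summarize_cohort,
)
from .states import STATE_LABELS, transition_label

PATIENT_COLUMNS = (
    "patient_id",
    "follow_up_start",
    "follow_up_end",
    "died",
    "sex",
    "age_group",
    "ethnicity",
    "imd_quintile",
    *(f"rf_{f}" for f in RISK_FACTORS),
)
EVENT_COLUMNS = ("patient_id", "condition", "onset_date", "resolve_date")


class ValidationError(ValueError):
    """Input-table validation failure with row-level diagnostics."""

    def __init__(self, issues: list[dict]):
        self.issues = issues
        lines = [f"  row {i['row']}: [{i['field']}] {i['reason']}" for i in issues[:20]]
        more = "" if len(issues) <= 20 else f"\n  ... and {len(issues) - 20} more"
        super().__init__(f"{len(issues)} validation issue(s):\n" + "\n".join(lines) + more)


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return datetime.strptime(str(value).strip(), "%Y-%m-%d").date()


def write_patients(patients: list[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "follow_up_start": p.follow_up_start.isoformat(),
            "follow_up_end": p.follow_up_end.isoformat(),
            "died": "true" if p.died else "false",
            "sex": p.sex,
            "age_group": p.age_group,
            "ethnicity": p.ethnicity,
            "imd_quintile": str(p.imd_quintile),
        }
        for f in RISK_FACTORS:
            row[f"rf_{f}"] = p.risk_factors.get(f, "never")
        rows.append(row)
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def write_events(events: list[ConditionEvent], path: str | Path) -> None:
    rows = [
        {
            "patient_id": ev.patient_id,
            "condition": ev.condition,
            "onset_date": ev.onset_date.isoformat(),
            "resolve_date": ev.resolve_date.isoformat() if ev.resolve_date else "",
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_patients(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            [{"row": 0, "field": c, "reason": "missing required column"} for c in sorted(missing)]
        )
    issues, patients = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = _parse_date(row.follow_up_start)
            end = _parse_date(row.follow_up_end)
        except ValueError:
            issues.append({"row": i, "field": "follow_up_*", "reason": "unparseable date"})
            continue
        died = str(row.died).strip().lower()
        if died not in ("true", "false"):
            issues.append({"row": i, "field": "died", "reason": f"not true/false: {row.died!r}"})
            continue
        imd: int | str = row.imd_quintile
        if imd != "missing":
            try:
                imd = int(imd)
            except ValueError:
                issues.append({"row": i, "field": "imd_quintile", "reason": f"bad quintile {imd!r}"})
                continue
        try:
            patients.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    follow_up_start=start,
                    follow_up_end=end,
                    died=died == "true",
                    sex=row.sex,
                    age_group=row.age_group,
                    ethnicity=row.ethnicity,
                    imd_quintile=imd,
                    risk_factors={f: getattr(row, f"rf_{f}") for f in RISK_FACTORS},
                )
            )
        except ValueError as exc:
            issues.append({"row": i, "field": "follow_up_end", "reason": str(exc)})
    if issues:
        raise ValidationError(issues)
    return patients


def read_events(path: str | Path, catalogue: Catalogue | None = None) -> list[ConditionEvent]:
    catalogue = catalogue or default_catalogue()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            [{"row": 0, "field": c, "reason": "missing required column"} for c in sorted(missing)]
        )
    issues, events = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.condition not in catalogue:
            issues.append({"row": i, "field": "condition", "reason": f"unknown condition code {row.condition!r}"})
            continue
        try:
            onset = _parse_date(row.onset_date)
        except ValueError:
            issues.append({"row": i, "field": "onset_date", "reason": "unparseable date"})
            continue
        resolve = None
        if str(row.resolve_date).strip():
            try:
                resolve = _parse_date(row.resolve_date)
            except ValueError:
                issues.append({"row": i, "field": "resolve_date", "reason": "unparseable date"})
                continue
            if not catalogue[row.condition].resolvable:
                issues.append(
                    {"row": i, "field": "resolve_date",
                     "reason": f"resolution recorded for non-resolvable condition {row.condition!r}"}
                )
                continue
            if resolve < onset:
                issues.append({"row": i, "field": "resolve_date", "reason": "resolution precedes onset"})
                continue
        events.append(ConditionEvent(row.patient_id, row.condition, onset, resolve))
    if issues:
        raise ValidationError(issues)
    return events


def read_tables(
    patients_path: str | Path,
    events_path: str | Path,
    catalogue_path: str | Path | None = None,
) -> tuple[list[PatientRecord], list[ConditionEvent], Catalogue]:
    catalogue = load_catalogue(catalogue_path)
    patients = read_patients(patients_path)
    events = read_events(events_path, catalogue)
    known = {p.patient_id for p in patients}
    orphans = [
        {"row": i + 2, "field": "patient_id", "reason": f"event for unknown patient {ev.patient_id!r}"}
        for i, ev in enumerate(events)
        if ev.patient_id not in known
    ]
    if orphans:
        raise ValidationError(orphans)
    return patients, events, catalogue


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    output_dir: str = "out"
    seed: int = 1
    simulate: bool = True
    n_patients: int = 2000
    patients_path: str | None = None
    events_path: str | None = None
    catalogue_path: str | None = None
    suppress_below: int | None = None
    exposures: list[str] = field(default_factory=lambda: ["sex"])
    mcf_stratifiers: list[str] = field(default_factory=lambda: ["baseline_ltc", "sex"])
    chain_by: str | None = None
    msm_mode: str = "exact"
    reference_covariates: dict[str, float] = field(
        default_factory=lambda: {"age_40_59": 1.0}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for p in (self.patients_path, self.events_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        for exposure in self.exposures:
            exposure_covariate_names(exposure)  # raises on unknown


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_with_meta(df: pd.DataFrame, path: Path, stage: str, seed: int, inputs: dict):
    df.to_csv(path, index=False)
    meta = {
        "stage": stage,
        "seed": seed,
        "package_version": __version__,
        "inputs": inputs,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run manifest.

    Identical config and seed produce byte-identical outputs.  Any stage
    failure raises with a stage-tagged message.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }

    def stage(name):
        manifest["stages"][name] = {"outputs": []}
        return manifest["stages"][name]

    def record(stage_info, path: Path):
        stage_info["outputs"].append(
            {"path": path.name, "sha256": _sha256(path)}
        )

    try:
        if config.simulate:
            info = stage("simulate")
            cohort_cfg = CohortConfig(n_patients=config.n_patients, seed=config.seed)
            patients, events = simulate_cohort(cohort_cfg)
            catalogue = cohort_cfg.catalogue
            write_patients(patients, out / "patients.csv")
            write_events(events, out / "events.csv")
            record(info, out / "patients.csv")
            record(info, out / "events.csv")
        else:
            patients, events, catalogue = read_tables(
                config.patients_path, config.events_path, config.catalogue_path
            )
            manifest["inputs"] = {
                "patients": _sha256(Path(config.patients_path)),
                "events": _sha256(Path(config.events_path)),
            }
    except ValidationError:
        raise
    except Exception as exc:  # pragma: no cover - stage tagging
        raise RuntimeError(f"[simulate/load] {exc}") from exc

    input_digests = {
        "patients.csv": _sha256(out / "patients.csv") if config.simulate else manifest["inputs"].get("patients", ""),
    }

    try:
        info = stage("build_states")
        histories = build_cohort_histories(patients, events)
        classes = [classify_history(h) for h in histories]
        hist_rows = [
            {"patient_id": h.patient_id, "time": round(t, 8), "state": STATE_LABELS[s]}
            for h in histories
            for t, s in h.observations
        ]
        _write_with_meta(
            pd.DataFrame(hist_rows, columns=["patient_id", "time", "state"]),
            out / "histories.csv", "build_states", config.seed, input_digests,
        )
        class_rows = [
            {
                "patient_id": h.patient_id,
                "label": c.label,
                "ltc_start": c.ltc_count_start,
                "ltc_end": c.ltc_count_end,
                "died": "true" if c.died else "false",
            }
            for h, c in zip(histories, classes)
        ]
        _write_with_meta(
            pd.DataFrame(class_rows), out / "classes.csv",
            "build_states", config.seed, input_digests,
        )
        record(info, out / "histories.csv")
        record(info, out / "classes.csv")

        info = stage("summarize")
        tables = summarize_cohort(patients, histories, classes, config.suppress_below)
        for name, table in tables.items():
            path = out / f"summary_{name}.csv"
            _write_with_meta(table, path, "summarize", config.seed, input_digests)
            record(info, path)
    except ValidationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[build-states] {exc}") from exc

    try:
        info = stage("mcf")
        curves = mcf_panel(patients, events, config.mcf_stratifiers, catalogue)
        for (strat, level), curve in curves.items():
            safe = f"{strat}__{level}".replace("/", "-").replace("+", "plus").replace(" ", "_")
            path = out / f"mcf_{safe}.csv"
            _write_with_meta(curve_to_frame(curve), path, "mcf", config.seed, input_digests)
            record(info, path)
    except Exception as exc:
        raise RuntimeError(f"[mcf] {exc}") from exc

    try:
        info = stage("fit_msm")
        for exposure in config.exposures:
            names = exposure_covariate_names(exposure)
            X = encode_cohort(patients, names)
            result = fit(histories, X, names, mode=config.msm_mode)
            hr = hazard_ratios(result)
            path = out / f"hazard_ratios_{exposure}.csv"
            _write_with_meta(hr, path, "fit_msm", config.seed, input_digests)
            record(info, path)
            report = one_year_report(result, reference=dict(config.reference_covariates))
            pmat = report["matrix"].to_frame().reset_index(names="from_state")
            path = out / f"pmatrix_1y_{exposure}.csv"
            _write_with_meta(pmat, path, "fit_msm", config.seed, input_digests)
            record(info, path)
            soj = pd.DataFrame(
                {"state": STATE_LABELS[:4], "mean_sojourn_years": report["sojourn_years"]}
            )
            path = out / f"sojourn_{exposure}.csv"
            _write_with_meta(soj, path, "fit_msm", config.seed, input_digests)
            record(info, path)
            fitjson = {
                "exposure": exposure,
                "mode": result.mode,
                "loglik": result.loglik,
                "converged": result.converged,
                "n_transitions": {
                    transition_label(t): n
                    for t, n in result.n_transitions_observed.items()
                },
                "baseline_log_rates": {
                    transition_label(t): (None if pd.isna(v) else v)
                    for t, v in result.model.baseline_log_rates.items()
                },
                "coefficients": {
                    transition_label(t): {
                        n: (None if pd.isna(b) else float(b))
                        for n, b in zip(result.model.covariate_names, beta)
                    }
                    for t, beta in result.model.coefficients.items()
                },
                "covariance": {
                    transition_label(t): (None if c is None else c.tolist())
                    for t, c in result.covariance.items()
                },
                "p_up_or_death_from_S0": report["p_up_or_death_from_S0"],
                "p_up_or_death_from_S2": report["p_up_or_death_from_S2"],
            }
            path = out / f"fit_{exposure}.json"
            path.write_text(json.dumps(fitjson, indent=2, sort_keys=True) + "\n")
            record(info, path)
    except Exception as exc:
        raise RuntimeError(f"[fit-msm] {exc}") from exc

    try:
        info = stage("chain")
        report = chain_report(patients, events, catalogue, by=config.chain_by)
        path = out / "top3_report.csv"
        _write_with_meta(report, path, "chain", config.seed, input_digests)
        record(info, path)
        from .chain import build_sequences, estimate_chain

        matrix = estimate_chain(build_sequences(patients, events), catalogue)
        path = out / "transition_counts.csv"
        _write_with_meta(
            matrix.counts_frame().reset_index(names="from"), path,
            "chain", config.seed, input_digests,
        )
        record(info, path)
        path = out / "transition_probs.csv"
        _write_with_meta(
            matrix.probs_frame().round(6).reset_index(names="from"), path,
            "chain", config.seed, input_digests,
        )
        record(info, path)
    except Exception as exc:
        raise RuntimeError(f"[chain] {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
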