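"""Readers/writers for respondent-level microdata.

The on-disk layout is two delimited text tables:

* a respondent table — one row per woman: id, round, interview month
  (century-month code), the five recoded demographics, and the ACASI
  counts; and
* a pregnancy table — one row per FTF pregnancy, keyed by respondent id,
  with the raw outcome code and end month (empty for an ongoing
  pregnancy).

A schema mapping (YAML/JSON-friendly dict) renames columns and recodes
values, so files exported from the NCHS public-use releases can flow
through the same loader as simulated cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import model
from .errors import CohortError, MissingModeError, OrphanRecordError, SchemaError
from .model import AcasiResponse, Cohort, PregnancyRecord, Respondent

log = logging.getLogger(__name__)

RESPONDENT_FIELDS = (
    "id",
    "round",
    "interview_month",
    "age_group",
    "race_ethnicity",
    "poverty",
    "marital",
    "religiosity",
    "acasi_birth",
    "acasi_loss",
    "acasi_abortion",
)
OPTIONAL_RESPONDENT_FIELDS = ("acasi_lifetime_total", "acasi_currently_pregnant")
PREGNANCY_FIELDS = ("id", "outcome", "end_month")
OPTIONAL_PREGNANCY_FIELDS = ("is_current",)

DEFAULT_SCHEMA: dict = {
    # canonical field -> column name in the file
    "respondent_columns": {f: f for f in RESPONDENT_FIELDS + OPTIONAL_RESPONDENT_FIELDS},
    "pregnancy_columns": {f: f for f in PREGNANCY_FIELDS + OPTIONAL_PREGNANCY_FIELDS},
    # per canonical field: raw value -> canonical value
    "value_maps": {},
    # raw values treated as refused / not ascertained
    "missing_sentinels": ["", "NA", ".", "R", "D"],
}


def nsfg_schema() -> dict:
    """Column/value schema for CSV extracts of the NSFG public-use files.

    The public-use female respondent and pregnancy files are distributed
    as fixed-width/SAS data; this schema expects a plain CSV export
    keeping the original variable names (CASEID, OUTCOME, DATEND, CMINTVW,
    ...) and recodes the numeric outcome codes of the pregnancy file onto
    the harmonized raw-outcome vocabulary.
    """
    schema = {
        "respondent_columns": {
            "id": "CASEID",
            "round": "ROUND",
            "interview_month": "CMINTVW",
            "age_group": "AGEGRP",
            "race_ethnicity": "RACEETH",
            "poverty": "POVGRP",
            "marital": "MARGRP",
            "religiosity": "RELGRP",
            "acasi_birth": "JB_BIRTH",
            "acasi_loss": "JB_LOSS",
            "acasi_abortion": "JB_ABORT",
            "acasi_lifetime_total": "JB_TOTAL",
            "acasi_currently_pregnant": "JB_PREGNOW",
        },
        "pregnancy_columns": {
            "id": "CASEID",
            "outcome": "OUTCOME",
            "end_month": "DATEND",
            "is_current": "CURRPREG",
        },
        "value_maps": {
            # FTF show-card codes
            "outcome": {
                "1": "miscarriage",
                "2": "stillbirth",
                "3": "abortion",
                "4": "ectopic",
                "5": "live_birth_cesarean",
                "6": "live_birth_vaginal",
            },
        },
        "missing_sentinels": ["", "NA", ".", "98", "99"],
    }
    return schema


@dataclass
class ReadReport:
    """Per-row account of what the loader rejected."""

    n_read: int = 0
    n_loaded: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _merge_schema(schema: Optional[dict]) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else list(v)) for k, v in DEFAULT_SCHEMA.items()}
    if schema:
        for key in ("respondent_columns", "pregnancy_columns", "value_maps"):
            if key in schema:
                merged[key].update(schema[key])
        if "missing_sentinels" in schema:
            merged["missing_sentinels"] = list(schema["missing_sentinels"])
    return merged


def _clean(value, sentinels) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s.endswith(".0"):
        s = s[:-2]
    return None if s in sentinels else s


def _mapped(field_name: str, value: Optional[str], value_maps: dict) -> Optional[str]:
    if value is None:
        return None
    vm = value_maps.get(field_name)
    return vm.get(value, value) if vm else value


def read_cohort(
    respondents_path: str | Path,
    pregnancies_path: Optional[str | Path] = None,
    schema: Optional[dict] = None,
    sep: str = ",",
) -> tuple[Cohort, ReadReport]:
    """Load and validate a cohort from delimited text.

    Respondents missing the self-administered module (absent or refused
    counts) are excluded and reported, as are rows failing any domain
    invariant. A pregnancy row whose id matches no respondent raises
    :class:`OrphanRecordError`; mixing survey rounds raises
    :class:`CohortError`.
    """
    sch = _merge_schema(schema)
    sentinels = set(sch["missing_sentinels"])
    rcols = sch["respondent_columns"]
    pcols = sch["pregnancy_columns"]
    vmaps = sch["value_maps"]

    rdf = pd.read_csv(respondents_path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for f, c in rcols.items()
                    if f in RESPONDENT_FIELDS and c not in rdf.columns]
    if missing_cols:
        raise SchemaError(f"respondent file lacks mandatory columns: {missing_cols}")

    events: dict[str, list[PregnancyRecord]] = {}
    if pregnancies_path is not None:
        pdf = pd.read_csv(pregnancies_path, sep=sep, dtype=str, keep_default_na=False)
        missing_cols = [c for f, c in pcols.items()
                        if f in PREGNANCY_FIELDS and c not in pdf.columns]
        if missing_cols:
            raise SchemaError(f"pregnancy file lacks mandatory columns: {missing_cols}")
        known_ids = set(rdf[rcols["id"]].astype(str))
        for _, row in pdf.iterrows():
            rid = str(row[pcols["id"]]).strip()
            if rid not in known_ids:
                raise OrphanRecordError(f"pregnancy row for unknown respondent {rid!r}")
            is_current = False
            if pcols.get("is_current") in pdf.columns:
                flag = _clean(row[pcols["is_current"]], sentinels)
                is_current = flag in ("1", "true", "True")
            end_raw = _clean(row[pcols["end_month"]], sentinels)
            outcome = _mapped("outcome", _clean(row[pcols["outcome"]], sentinels), vmaps)
            rec = PregnancyRecord(
                outcome_raw=outcome,
                end_month=None if is_current else int(end_raw),
                is_current=is_current,
            )
            events.setdefault(rid, []).append(rec)

    report = ReadReport(n_read=len(rdf))
    respondents: list[Respondent] = []
    rounds_seen: set[str] = set()
    for _, row in rdf.iterrows():
        rid = str(row[rcols["id"]]).strip()
        try:
            rnd = _mapped("round", _clean(row[rcols["round"]], sentinels), vmaps)
            counts = {}
            for cat in model.CATEGORIES:
                raw = _clean(row[rcols[f"acasi_{cat}"]], sentinels)
                counts[cat] = None if raw is None else int(raw)
            if any(v is None for v in counts.values()):
                raise MissingModeError("ACASI module missing or refused")
            lifetime_total = None
            col = rcols.get("acasi_lifetime_total")
            if col in rdf.columns:
                raw = _clean(row[col], sentinels)
                lifetime_total = None if raw is None else int(raw)
            currently_pregnant = None
            col = rcols.get("acasi_currently_pregnant")
            if col in rdf.columns:
                raw = _clean(row[col], sentinels)
                currently_pregnant = None if raw is None else raw in ("1", "true", "True")
            acasi = AcasiResponse(
                period_kind="lifetime" if rnd == model.ROUND_2002 else "five_year",
                count_birth=counts["birth"],
                count_loss=counts["loss"],
                count_abortion=counts["abortion"],
                lifetime_total=lifetime_total,
                currently_pregnant=currently_pregnant,
            )
            demo = {
                axis: _mapped(axis, _clean(row[rcols[axis]], sentinels), vmaps)
                for axis in model.DEMOGRAPHIC_AXES
            }
            resp = Respondent(
                id=rid,
                round=rnd,
                interview_month=int(_clean(row[rcols["interview_month"]], sentinels)),
                pregnancies=tuple(events.get(rid, ())),
                acasi=acasi,
                **demo,
            )
        except (MissingModeError, ValueError, TypeError) as exc:
            report.excluded.append((rid, str(exc)))
            continue
        except Exception as exc:  # coding errors carry the row context
            report.excluded.append((rid, str(exc)))
            continue
        rounds_seen.add(resp.round)
        respondents.append(resp)

    if len(rounds_seen) > 1:
        raise CohortError(f"file mixes survey rounds: {sorted(rounds_seen)}")
    if not respondents:
        raise CohortError("no valid respondents loaded")
    report.n_loaded = len(respondents)
    if report.n_excluded:
        log.info("excluded %d of %d respondents", report.n_excluded, report.n_read)
    return Cohort(round=rounds_seen.pop(), respondents=respondents), report


def write_cohort(
    cohort: Cohort,
    respondents_path: str | Path,
    pregnancies_path: str | Path,
    sep: str = ",",
) -> None:
    """Write a cohort in the default schema (inverse of :func:`read_cohort`)."""
    rrows, prows = [], []
    for r in cohort:
        rrows.append(
            {
                "id": r.id,
                "round": r.round,
                "interview_month": r.interview_month,
                "age_group": r.age_group,
                "race_ethnicity": r.race_ethnicity,
                "poverty": r.poverty,
                "marital": r.marital,
                "religiosity": r.religiosity,
                "acasi_birth": r.acasi.count_birth,
                "acasi_loss": r.acasi.count_loss,
                "acasi_abortion": r.acasi.count_abortion,
                "acasi_lifetime_total": "" if r.acasi.lifetime_total is None
                else r.acasi.lifetime_total,
                "acasi_currently_pregnant": "" if r.acasi.currently_pregnant is None
                else int(r.acasi.currently_pregnant),
            }
        )
        for p in r.pregnancies:
            prows.append(
                {
                    "id": r.id,
                    "outcome": p.outcome_raw,
                    "end_month": "" if p.end_month is None else p.end_month,
                    "is_current": int(p.is_current),
                }
            )
    pd.DataFrame(rrows).to_csv(respondents_path, sep=sep, index=False)
    cols = ["id", "outcome", "end_month", "is_current"]
    pd.DataFrame(prows, columns=cols).to_csv(pregnancies_path, sep=sep, index=False)


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Unweighted sample composition: N and % per demographic level."""
    rows = [{"axis": "total", "level": "total", "n": len(cohort), "pct": 100.0}]
    n = len(cohort)
    for axis, levels in model.DEMOGRAPHIC_AXES.items():
        for level in levels:
            k = sum(1 for r in cohort if getattr(r, axis) == level)
            rows.append(
                {"axis": axis, "level": level, "n": k, "pct": round(100.0 * k / n, 1)}
            )
    return pd.DataFrame(rows)
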