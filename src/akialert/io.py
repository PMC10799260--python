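"""Tabular input/output for admissions, labs, events and ground truth.

File dialect: comma-separated UTF-8 with an explicit header row, ISO-8601
timestamps, empty string for missing.  Creatinine is mg/dL internally; a
`unit` column on the labs table may declare umol/L per row, in which case
values are converted (divided by 88.4) on read.

Tables:

* admissions.csv — one row per admission (id, times, ward/ICU, demographics,
  exclusion flags, cost)
* labs.csv — timestamped serum creatinine per patient
* events.csv — typed clinical events (death, dialysis_start, care-process
  interventions, nephrotoxin exposures, hemoglobin values, documentation)
* ground_truth.csv — generator-injected truth, written by the simulator

In memory, lab and event times are hours relative to the patient's
admission (negative = pre-admission historic values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .kdigo import MGDL_PER_UMOLL, Demographics, LabSeries, Measurement

__all__ = ["Admission", "EventRecord", "Cohort", "read_tables", "write_tables",
           "EVENT_KINDS"]

EVENT_KINDS = frozenset({
    "death", "dialysis_start", "iv_fluids", "urinalysis", "fluid_io",
    "ultrasound", "hemoglobin", "nephrology_consult", "scr_measured",
    "contrast", "aminoglycoside", "vancomycin", "chemotherapy", "nsaid",
    "acei_arb", "aki_documented",
})

_ADMISSION_COLS = [
    "patient_id", "admit_time", "discharge_time", "ward_type", "icu",
    "age", "sex", "eskd_admission", "kidney_transplant_history", "total_cost",
]
_LAB_COLS = ["patient_id", "time", "scr", "unit"]
_EVENT_COLS = ["patient_id", "time", "kind", "value"]


@dataclass
class Admission:
    """One inpatient admission; ward_type x icu defines the randomization
    stratum."""

    patient_id: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    ward_type: str  # medical | surgical
    icu: bool
    demographics: Demographics
    eskd_admission: bool = False
    kidney_transplant_history: bool = False
    total_cost: Optional[float] = None

    def __post_init__(self) -> None:
        if self.discharge_time <= self.admit_time:
            raise ValueError(
                f"{self.patient_id}: discharge_time must follow admit_time"
            )

    @property
    def stay_hours(self) -> float:
        return (self.discharge_time - self.admit_time) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class EventRecord:
    """A typed clinical event; time is hours since the patient's admission."""

    patient_id: str
    time: float
    kind: str
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class Cohort:
    """Object graph tying admissions to their lab series and events."""

    admissions: list[Admission]
    labs: dict[str, LabSeries]
    events: dict[str, list[EventRecord]] = field(default_factory=dict)
    ground_truth: Optional[pd.DataFrame] = None

    def admission(self, patient_id: str) -> Admission:
        for a in self.admissions:
            if a.patient_id == patient_id:
                return a
        raise KeyError(patient_id)


def _check_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"{name}: unknown column(s) {', '.join(unknown)}")
    missing = [c for c in expected if c not in df.columns and c not in
               ("unit", "value", "total_cost")]
    if missing:
        raise ValueError(f"{name}: missing column(s) {', '.join(missing)}")


def _parse_times(raw: pd.Series, name: str) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.len() > 0)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(f"{name}: unparseable timestamp at line(s) {lines}")
    return parsed


def read_tables(
    admissions_path: str | Path,
    labs_path: str | Path,
    events_path: Optional[str | Path] = None,
    ground_truth_path: Optional[str | Path] = None,
) -> Cohort:
    """Load and cross-validate the cohort tables.

    Referential integrity is enforced: every lab and event row must name a
    patient present in the admissions table.  Lab values with a declared
    umol/L unit are converted to mg/dL.
    """
    adf = pd.read_csv(admissions_path, dtype={"patient_id": str})
    _check_columns(adf, _ADMISSION_COLS, "admissions")
    adf["admit_time"] = _parse_times(adf["admit_time"], "admissions")
    adf["discharge_time"] = _parse_times(adf["discharge_time"], "admissions")

    admissions = []
    for row in adf.itertuples(index=False):
        admissions.append(
            Admission(
                patient_id=row.patient_id,
                admit_time=row.admit_time,
                discharge_time=row.discharge_time,
                ward_type=row.ward_type,
                icu=bool(row.icu),
                demographics=Demographics(age=float(row.age), sex=row.sex),
                eskd_admission=bool(getattr(row, "eskd_admission", False)),
                kidney_transplant_history=bool(
                    getattr(row, "kidney_transplant_history", False)
                ),
                total_cost=(
                    float(row.total_cost)
                    if "total_cost" in adf.columns and pd.notna(row.total_cost)
                    else None
                ),
            )
        )
    admit_by_id = {a.patient_id: a.admit_time for a in admissions}

    ldf = pd.read_csv(labs_path, dtype={"patient_id": str})
    _check_columns(ldf, _LAB_COLS, "labs")
    ldf["time"] = _parse_times(ldf["time"], "labs")
    orphans = sorted(set(ldf["patient_id"]) - set(admit_by_id))
    if orphans:
        raise ValueError(f"labs: rows reference unknown patient id(s) {orphans}")
    if "unit" in ldf.columns:
        umol = ldf["unit"].fillna("mg/dL").str.lower().isin(
            ["umol/l", "µmol/l", "micromol/l"]
        )
        ldf.loc[umol, "scr"] = ldf.loc[umol, "scr"] / MGDL_PER_UMOLL

    labs: dict[str, LabSeries] = {}
    for pid, grp in ldf.groupby("patient_id"):
        t0 = admit_by_id[pid]
        hours = (grp["time"] - t0) / pd.Timedelta(hours=1)
        labs[pid] = LabSeries(
            [Measurement(float(h), float(s)) for h, s in zip(hours, grp["scr"])]
        )

    events: dict[str, list[EventRecord]] = {a.patient_id: [] for a in admissions}
    if events_path is not None and Path(events_path).exists():
        edf = pd.read_csv(events_path, dtype={"patient_id": str})
        _check_columns(edf, _EVENT_COLS, "events")
        edf["time"] = _parse_times(edf["time"], "events")
        orphans = sorted(set(edf["patient_id"]) - set(admit_by_id))
        if orphans:
            raise ValueError(
                f"events: rows reference unknown patient id(s) {orphans}"
            )
        for row in edf.itertuples(index=False):
            t0 = admit_by_id[row.patient_id]
            h = (row.time - t0) / pd.Timedelta(hours=1)
            val = float(row.value) if "value" in edf.columns and pd.notna(row.value) else None
            events[row.patient_id].append(
                EventRecord(row.patient_id, float(h), row.kind, val)
            )

    gt = None
    if ground_truth_path is not None and Path(ground_truth_path).exists():
        gt = pd.read_csv(ground_truth_path, dtype={"patient_id": str})
    return Cohort(admissions=admissions, labs=labs, events=events, ground_truth=gt)


def write_tables(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort back out as the canonical CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    adf = pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in cohort.admissions],
            "admit_time": [a.admit_time.isoformat() for a in cohort.admissions],
            "discharge_time": [
                a.discharge_time.isoformat() for a in cohort.admissions
            ],
            "ward_type": [a.ward_type for a in cohort.admissions],
            "icu": [a.icu for a in cohort.admissions],
            "age": [a.demographics.age for a in cohort.admissions],
            "sex": [a.demographics.sex for a in cohort.admissions],
            "eskd_admission": [a.eskd_admission for a in cohort.admissions],
            "kidney_transplant_history": [
                a.kidney_transplant_history for a in cohort.admissions
            ],
            "total_cost": [a.total_cost for a in cohort.admissions],
        }
    )
    paths["admissions"] = outdir / "admissions.csv"
    adf.to_csv(paths["admissions"], index=False)

    lab_rows = []
    for a in cohort.admissions:
        series = cohort.labs.get(a.patient_id)
        if series is None:
            continue
        for m in series.measurements:
            lab_rows.append(
                {
                    "patient_id": a.patient_id,
                    "time": (a.admit_time + pd.Timedelta(hours=m.time)).isoformat(),
                    "scr": round(m.scr, 4),
                    "unit": "mg/dL",
                }
            )
    paths["labs"] = outdir / "labs.csv"
    pd.DataFrame(lab_rows, columns=_LAB_COLS).to_csv(paths["labs"], index=False)

    ev_rows = []
    for a in cohort.admissions:
        for e in cohort.events.get(a.patient_id, []):
            ev_rows.append(
                {
                    "patient_id": a.patient_id,
                    "time": (a.admit_time + pd.Timedelta(hours=e.time)).isoformat(),
                    "kind": e.kind,
                    "value": e.value,
                }
            )
    paths["events"] = outdir / "events.csv"
    pd.DataFrame(ev_rows, columns=_EVENT_COLS).to_csv(paths["events"], index=False)

    if cohort.ground_truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.csv"
        cohort.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths
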