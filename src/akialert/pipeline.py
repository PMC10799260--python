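"""End-to-end orchestration: detect -> screen -> randomize -> outcomes -> analyze.

Admissions are processed in table order; eligible patients consume
consecutive draws from their stratum's seeded randomization stream, so a
regenerated cohort and a re-read cohort yield identical assignments.
Outputs are plain CSV tables (assignments, outcomes, analysis), a
line-delimited alert-message log, and a run log with the config hash and
stagewise patient accounting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import yaml

from . import alerts as al
from .alerts import Randomizer, emit_alert, screen_eligibility, stratum_of
from .config import PipelineConfig
from .io import Cohort
from .kdigo import detect_aki, rolling_min
from .outcomes import (NEPHROTOXINS, care_outcomes, primary_outcome,
                       secondary_outcomes)
from .stats import (ContingencyCounts, hodges_lehmann, mann_whitney,
                    risk_difference_ci)

__all__ = ["screen_cohort", "compute_outcomes", "analyze_outcomes",
           "run_pipeline"]

BINARY_OUTCOMES = (
    ["death_7d", "death_28d", "death_90d", "in_hospital_death", "dialysis_7d",
     "in_hospital_dialysis", "aki_progression_any", "recovery_at_discharge",
     "alive_dialysis_dependent_90d", "iv_fluids_2d", "urinalysis_2d",
     "fluid_io_2d", "scr_measured_2d", "ultrasound_2d", "anemia_corrected_2d",
     "nephrology_consult_2d", "aki_documented"]
    + [f"{k}_3d" for k in NEPHROTOXINS]
    + [f"{k}_7d" for k in NEPHROTOXINS]
)
CONTINUOUS_OUTCOMES = ["max_abs_egfr_change", "max_rel_egfr_change_pct",
                       "los_days", "total_cost"]


def screen_cohort(
    cohort: Cohort, config: Optional[PipelineConfig] = None
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Detect, screen and randomize every admission.

    Returns the assignments table (one row per admission with a detected
    episode), a map patient_id -> (episode, assignment-or-None), and the
    rendered alert messages (alert arm only, capped at three per
    admission).
    """
    cfg = config or PipelineConfig()
    randomizer = Randomizer(universal_seed=cfg.universal_seed,
                            blocked=cfg.block_size)
    rows, episodes, messages = [], {}, []
    seen_patients: set[str] = set()
    for adm in cohort.admissions:
        series = cohort.labs.get(adm.patient_id)
        if series is None:
            continue
        episode = detect_aki(
            series, adm.demographics,
            delta_threshold=cfg.delta_threshold,
            delta_window=cfg.delta_window_h,
            ratio_threshold=cfg.ratio_threshold,
            baseline_window=cfg.baseline_window_h,
        )
        if episode is None:
            continue
        elig = screen_eligibility(adm, episode, series,
                                  prior_patient_ids=seen_patients)
        seen_patients.add(adm.patient_id)
        assignment = None
        if elig.eligible:
            assignment = randomizer.assign(stratum_of(adm.ward_type, adm.icu))
            if assignment.arm == al.ALERT:
                n_sent = 0
                for m in series.measurements:
                    if m.time < episode.onset_time:
                        continue
                    base7 = rolling_min(series, m.time, cfg.baseline_window_h)
                    base48 = rolling_min(series, m.time, cfg.delta_window_h)
                    fires = (
                        base48 is not None
                        and m.scr - base48 >= cfg.delta_threshold
                    ) or (
                        base7 is not None
                        and m.scr >= cfg.ratio_threshold * base7
                    )
                    if not fires:
                        continue
                    msg = emit_alert(
                        assignment, episode, n_sent,
                        context={
                            "bed": adm.patient_id,
                            "ward": f"{adm.ward_type} {'ICU' if adm.icu else 'ward'}",
                            "admit_date": adm.admit_time.date().isoformat(),
                            "scr": m.scr,
                            "test_date": (
                                adm.admit_time + pd.Timedelta(hours=m.time)
                            ).isoformat(),
                            "consult_phone": "000-0000",
                        },
                        patient_ref=adm.patient_id,
                    )
                    if msg is None:
                        break
                    n_sent += 1
                    messages.append(
                        f"{adm.patient_id}\t{msg.sequence_number}\t{msg.rendered_text}"
                    )
        episodes[adm.patient_id] = (episode, assignment)
        rows.append({
            "patient_id": adm.patient_id,
            "stratum": stratum_of(adm.ward_type, adm.icu),
            "arm": assignment.arm if assignment else "",
            "seed_used": assignment.seed_used if assignment else "",
            "draw_index": assignment.draw_index if assignment else "",
            "exclusion_reason": elig.exclusion_reason or "",
            "onset_h": round(episode.onset_time, 3),
            "baseline_scr": round(episode.baseline_scr, 4),
            "scr_at_aki": round(episode.scr_at_aki, 4),
            "egfr_at_aki": round(episode.egfr_at_aki, 2)
            if episode.egfr_at_aki is not None else "",
            "stage_at_onset": episode.stage_at_onset,
        })
    return pd.DataFrame(rows), episodes, messages


def compute_outcomes(
    cohort: Cohort, episodes: dict, config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Per-randomized-patient outcome table; missing values stay empty."""
    cfg = config or PipelineConfig()
    rows = []
    for adm in cohort.admissions:
        entry = episodes.get(adm.patient_id)
        if entry is None or entry[1] is None:
            continue
        episode, assignment = entry
        series = cohort.labs[adm.patient_id]
        events = cohort.events.get(adm.patient_id, [])
        t_rand = episode.onset_time
        death_times = [e.time for e in events if e.kind == "death"]
        death_t = min(death_times) if death_times else None

        prim = primary_outcome(series, adm.demographics, t_rand, death_t)
        sec = secondary_outcomes(series, episode, events, t_rand,
                                 adm.stay_hours)
        care = care_outcomes(events, t_rand, discharge_record=adm)

        row = {
            "patient_id": adm.patient_id,
            "stratum": assignment.stratum,
            "arm": assignment.arm,
            "max_abs_egfr_change": round(prim.max_abs_egfr_change, 3)
            if prim else None,
            "max_rel_egfr_change_pct": round(100 * prim.max_rel_egfr_change, 2)
            if prim else None,
            "died_within_7d": prim.died_within_7d if prim else None,
            "death_7d": sec.death_7d,
            "death_28d": sec.death_28d,
            "death_90d": sec.death_90d,
            "in_hospital_death": sec.in_hospital_death,
            "dialysis_7d": sec.dialysis_7d,
            "in_hospital_dialysis": sec.in_hospital_dialysis,
            "aki_progression_any": sec.aki_progression is not None,
            "progression_from": sec.aki_progression[0] if sec.aki_progression else None,
            "progression_to": sec.aki_progression[1] if sec.aki_progression else None,
            "highest_stage": sec.highest_stage,
            "recovery_at_discharge": sec.recovery_at_discharge,
            "alive_dialysis_dependent_90d": sec.alive_dialysis_dependent_90d,
            "iv_fluids_2d": care.iv_fluids_2d,
            "urinalysis_2d": care.urinalysis_2d,
            "fluid_io_2d": care.fluid_io_2d,
            "scr_measured_2d": care.scr_measured_2d,
            "ultrasound_2d": care.ultrasound_2d,
            "anemia_corrected_2d": care.anemia_corrected_2d,
            "nephrology_consult_2d": care.nephrology_consult_2d,
            "aki_documented": care.aki_documented,
            "los_days": round(care.los_days, 3) if care.los_days else None,
            "total_cost": round(care.total_cost, 2) if care.total_cost else None,
        }
        for k in NEPHROTOXINS:
            row[f"{k}_3d"] = care.nephrotoxin_3d[k]
            row[f"{k}_7d"] = care.nephrotoxin_7d[k]
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt_median_iqr(v: pd.Series) -> str:
    if v.empty:
        return ""
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    return f"{q2:.1f} ({q1:.1f} to {q3:.1f})"


def analyze_outcomes(
    outcomes: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Arm comparison table mirroring the trial's outcome tables.

    Binary outcomes get per-arm counts/percentages, the risk difference in
    percentage points with its Wald CI, and the chi-square p-value;
    continuous outcomes get per-arm median (IQR), the Hodges-Lehmann
    difference with rank-sum-inverted CI, and the Mann-Whitney p-value.
    """
    cfg = config or PipelineConfig()
    if outcomes.empty:
        raise ValueError("no randomized patients: empty outcomes table")
    rows = []
    usual = outcomes[outcomes["arm"] == al.USUAL_CARE]
    alert = outcomes[outcomes["arm"] == al.ALERT]
    for col in BINARY_OUTCOMES:
        if col not in outcomes.columns:
            continue
        u = usual[col].dropna()
        a = alert[col].dropna()
        if u.empty or a.empty:
            continue
        c = ContingencyCounts(
            events_a=int(a.sum()), n_a=len(a),
            events_b=int(u.sum()), n_b=len(u),
        )
        est = risk_difference_ci(c, level=cfg.ci_level)
        rows.append({
            "outcome": col, "type": "binary",
            "usual_care": f"{c.events_b} ({100 * c.events_b / c.n_b:.1f})",
            "alert": f"{c.events_a} ({100 * c.events_a / c.n_a:.1f})",
            "difference": round(est.difference, 1),
            "ci_low": round(est.ci_low, 1),
            "ci_high": round(est.ci_high, 1),
            "p_value": round(est.p_value, 4),
        })
    for col in CONTINUOUS_OUTCOMES:
        if col not in outcomes.columns:
            continue
        u = pd.to_numeric(usual[col], errors="coerce").dropna()
        a = pd.to_numeric(alert[col], errors="coerce").dropna()
        if u.empty or a.empty:
            continue
        est, lo, hi = hodges_lehmann(u.to_numpy(), a.to_numpy(),
                                     level=cfg.ci_level)
        _, p = mann_whitney(a.to_numpy(), u.to_numpy(), method="asymptotic")
        rows.append({
            "outcome": col, "type": "continuous",
            "usual_care": _fmt_median_iqr(u),
            "alert": _fmt_median_iqr(a),
            "difference": round(est, 2),
            "ci_low": round(lo, 2),
            "ci_high": round(hi, 2),
            "p_value": round(p, 4),
        })
    return pd.DataFrame(rows)


def run_pipeline(
    cohort: Cohort,
    outdir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> dict[str, Path]:
    """Run the full trial pipeline on a cohort and write the report bundle.

    Deterministic given the cohort and config.  Writes assignments.csv,
    outcomes.csv, analysis.csv, messages.log and run_log.json (config
    hash, seed scheme, and Figure-1-style stage accounting).
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not cohort.admissions:
        raise ValueError("empty cohort: nothing to analyze")

    assignments, episodes, messages = screen_cohort(cohort, cfg)
    outcomes = compute_outcomes(cohort, episodes, cfg)
    analysis = analyze_outcomes(outcomes, cfg) if not outcomes.empty else pd.DataFrame()

    paths = {}
    paths["assignments"] = outdir / "assignments.csv"
    assignments.to_csv(paths["assignments"], index=False)
    paths["outcomes"] = outdir / "outcomes.csv"
    outcomes.to_csv(paths["outcomes"], index=False)
    paths["analysis"] = outdir / "analysis.csv"
    analysis.to_csv(paths["analysis"], index=False)
    paths["messages"] = outdir / "messages.log"
    paths["messages"].write_text("\n".join(messages) + ("\n" if messages else ""))

    cfg_yaml = yaml.safe_dump(asdict(cfg), sort_keys=True)
    n_detected = len(assignments)
    n_eligible = int((assignments["exclusion_reason"] == "").sum()) if n_detected else 0
    log = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "universal_seed": cfg.universal_seed,
        "stratum_seeds": {s: cfg.universal_seed + k
                          for k, s in enumerate(al.STRATA)},
        "admissions_in": len(cohort.admissions),
        "aki_detected": n_detected,
        "excluded": n_detected - n_eligible,
        "exclusion_tally": (
            assignments.loc[assignments["exclusion_reason"] != "",
                            "exclusion_reason"].value_counts().to_dict()
            if n_detected else {}
        ),
        "randomized": n_eligible,
        "per_arm": (
            assignments.loc[assignments["arm"] != "", "arm"]
            .value_counts().to_dict() if n_detected else {}
        ),
        "alert_messages_sent": len(messages),
    }
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2) + "\n")
    return paths
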