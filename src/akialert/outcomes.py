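"""Trial outcome definitions: primary eGFR change, secondary, care-centered.

The primary outcome is the maximum change in eGFR within 7 days of
randomization: eGFR at AKI minus the lowest eGFR observed in the 7-day
follow-up window, with eGFR set to 0 when the patient dies in that window.
The relative form divides by the eGFR at randomization (here identical to
the eGFR at AKI, since randomization is triggered by the AKI alert).

All windowed flags use half-open intervals (t_rand, t_rand + horizon] on the
hour axis; "within 2/3/7 days" means 48/72/168 hours from the randomization
timestamp.  Missing inputs propagate as None (no imputation); denominators
shrink accordingly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .kdigo import AkiEpisode, Demographics, LabSeries, egfr, highest_stage, stage_at

__all__ = [
    "PrimaryOutcome",
    "SecondaryOutcomes",
    "CareOutcomes",
    "primary_outcome",
    "secondary_outcomes",
    "care_outcomes",
    "recovery_at_discharge",
    "NEPHROTOXINS",
]

H7D = 168.0
H2D = 48.0
H3D = 72.0
H28D = 672.0
H90D = 2160.0

NEPHROTOXINS = ("contrast", "aminoglycoside", "vancomycin", "chemotherapy",
                "nsaid", "acei_arb")

RECOVERY_RATIO = 1.5  # last SCr < 1.5x episode baseline counts as recovered
ANEMIA_HB = 9.0       # g/dL; corrected means strictly above this


def _in_window(t: float, start: float, horizon: float) -> bool:
    return start < t <= start + horizon


@dataclass
class PrimaryOutcome:
    max_abs_egfr_change: float    # mL/min/1.73m2
    max_rel_egfr_change: float    # fraction of eGFR at randomization
    died_within_7d: bool
    egfr_at_aki: float
    lowest_egfr_7d: float


@dataclass
class SecondaryOutcomes:
    death_7d: bool
    death_28d: Optional[bool]
    death_90d: Optional[bool]
    in_hospital_death: bool
    dialysis_7d: bool
    in_hospital_dialysis: bool
    aki_progression: Optional[tuple[int, int]]  # (from, to), strictly higher
    highest_stage: int
    recovery_at_discharge: Optional[bool]
    alive_dialysis_dependent_90d: Optional[bool]


@dataclass
class CareOutcomes:
    iv_fluids_2d: bool
    urinalysis_2d: bool
    fluid_io_2d: bool
    scr_measured_2d: bool
    ultrasound_2d: bool
    anemia_corrected_2d: bool
    nephrology_consult_2d: bool
    nephrotoxin_3d: dict[str, bool]
    nephrotoxin_7d: dict[str, bool]
    aki_documented: bool
    los_days: Optional[float] = None
    total_cost: Optional[float] = None


def primary_outcome(
    series: LabSeries,
    demo: Demographics,
    randomization_time: float,
    death_time: Optional[float] = None,
    egfr_at_randomization: Optional[float] = None,
) -> Optional[PrimaryOutcome]:
    """Maximum absolute and relative eGFR change within 7 days.

    lowest_egfr_7d is the minimum eGFR over measurement times in
    (t_rand, t_rand + 168 h], forced to 0 when death falls in that window.
    Returns None (missing; no imputation) when there is neither a follow-up
    measurement nor an in-window death.
    """
    scr_rand = series.scr_at(randomization_time)
    if scr_rand is None:
        raise ValueError("randomization-time SCr unavailable")
    e_rand = (
        egfr_at_randomization
        if egfr_at_randomization is not None
        else egfr(scr_rand, demo)
    )
    died = death_time is not None and _in_window(death_time, randomization_time, H7D)
    follow = [
        egfr(m.scr, demo)
        for m in series.measurements
        if _in_window(m.time, randomization_time, H7D)
    ]
    if not follow and not died:
        return None
    lowest = 0.0 if died else min(follow)
    max_abs = e_rand - lowest
    return PrimaryOutcome(
        max_abs_egfr_change=max_abs,
        max_rel_egfr_change=max_abs / e_rand,
        died_within_7d=died,
        egfr_at_aki=e_rand,
        lowest_egfr_7d=lowest,
    )


def _first_event_time(events: Iterable, kind: str) -> Optional[float]:
    times = [e.time for e in events if e.kind == kind]
    return min(times) if times else None


def secondary_outcomes(
    series: LabSeries,
    episode: AkiEpisode,
    events: Iterable,
    randomization_time: float,
    discharge_time: float,
    has_90d_status: bool = True,
) -> SecondaryOutcomes:
    """Windowed mortality/dialysis flags, progression, stage, recovery.

    Events are records with .kind and .time (hours since admission); death
    and dialysis_start are the kinds consulted here.  Progression compares
    the stage at randomization with the highest subsequent in-hospital
    stage and is recorded only when strictly higher.  When has_90d_status
    is False the 90-day fields are None (missing), other fields unaffected.
    """
    events = list(events)
    death_time = _first_event_time(events, "death")
    dialysis_time = _first_event_time(events, "dialysis_start")

    def death_within(h: float) -> bool:
        return death_time is not None and _in_window(death_time, randomization_time, h)

    # sub-millisecond slack absorbs timestamp round-tripping
    eps = 1e-6
    in_hosp_death = death_time is not None and death_time <= discharge_time + eps
    in_hosp_dialysis = (
        dialysis_time is not None and dialysis_time <= discharge_time + eps
    )

    stage_rand = stage_at(
        series, episode, randomization_time,
        krt_started=dialysis_time is not None and dialysis_time <= randomization_time,
    )
    top = highest_stage(
        series, episode, discharge_time,
        krt_start_time=dialysis_time if in_hosp_dialysis else None,
    )
    # highest stage strictly after randomization, for progression
    post = stage_rand
    for m in series.measurements:
        if randomization_time < m.time <= discharge_time:
            krt = dialysis_time is not None and dialysis_time <= m.time
            post = max(post, stage_at(series, episode, m.time, krt))
    if in_hosp_dialysis and dialysis_time > randomization_time:
        post = 3
    progression = (stage_rand, post) if post > stage_rand else None

    recovery = recovery_at_discharge(series, episode, discharge_time, events)

    death_90 = death_within(H90D) if has_90d_status else None
    alive_dep = None
    if has_90d_status:
        alive_90 = not (death_time is not None and
                        death_time <= randomization_time + H90D)
        dial_in_90 = dialysis_time is not None and _in_window(
            dialysis_time, randomization_time, H90D
        )
        alive_dep = alive_90 and dial_in_90 and recovery is not True

    return SecondaryOutcomes(
        death_7d=death_within(H7D),
        death_28d=death_within(H28D),
        death_90d=death_90,
        in_hospital_death=in_hosp_death,
        dialysis_7d=dialysis_time is not None
        and _in_window(dialysis_time, randomization_time, H7D),
        in_hospital_dialysis=in_hosp_dialysis,
        aki_progression=progression,
        highest_stage=top,
        recovery_at_discharge=recovery,
        alive_dialysis_dependent_90d=alive_dep,
    )


def recovery_at_discharge(
    series: LabSeries,
    episode: AkiEpisode,
    discharge_time: float,
    events: Iterable,
    *,
    ratio: float = RECOVERY_RATIO,
) -> Optional[bool]:
    """AKI recovery at discharge under the package's default rule.

    Recovered means: alive at discharge, no dialysis during the admission,
    and the last SCr before discharge below `ratio` times the episode
    baseline.  The threshold is configurable; the trial does not print its
    ascertainment rule, so this is a documented convention.  None when no
    discharge SCr exists.
    """
    events = list(events)
    death_time = _first_event_time(events, "death")
    if death_time is not None and death_time <= discharge_time:
        return False
    dialysis_time = _first_event_time(events, "dialysis_start")
    if dialysis_time is not None and dialysis_time <= discharge_time:
        return False
    last = series.scr_at(discharge_time)
    if last is None:
        return None
    return last < ratio * episode.baseline_scr


def care_outcomes(
    intervention_log: Iterable,
    randomization_time: float,
    discharge_record=None,
    series: Optional[LabSeries] = None,
) -> CareOutcomes:
    """Care-process flags over 2/3/7-day windows after randomization.

    The intervention log holds typed, timestamped entries (kinds: iv_fluids,
    urinalysis, fluid_io, ultrasound, hemoglobin with g/dL value,
    nephrology_consult, the six nephrotoxins, aki_documented).  Unknown
    kinds are ignored.  Anemia counts as corrected only for hemoglobin
    strictly above 9.0 g/dL in the 2-day window.  Subsequent-creatinine is
    read off the lab series when given, else off scr_measured events.
    """
    events = list(intervention_log)

    def any_in(kind: str, horizon: float) -> bool:
        return any(
            e.kind == kind and _in_window(e.time, randomization_time, horizon)
            for e in events
        )

    anemia = any(
        e.kind == "hemoglobin"
        and e.value is not None
        and e.value > ANEMIA_HB
        and _in_window(e.time, randomization_time, H2D)
        for e in events
    )
    if series is not None:
        scr2d = any(
            _in_window(m.time, randomization_time, H2D) for m in series.measurements
        )
    else:
        scr2d = any_in("scr_measured", H2D)

    los = cost = None
    if discharge_record is not None:
        stay_h = getattr(discharge_record, "stay_hours", None)
        if stay_h is None:
            stay_h = discharge_record.discharge_time - discharge_record.admit_time
        los = stay_h / 24.0
        cost = getattr(discharge_record, "total_cost", None)

    return CareOutcomes(
        iv_fluids_2d=any_in("iv_fluids", H2D),
        urinalysis_2d=any_in("urinalysis", H2D),
        fluid_io_2d=any_in("fluid_io", H2D),
        scr_measured_2d=scr2d,
        ultrasound_2d=any_in("ultrasound", H2D),
        anemia_corrected_2d=anemia,
        nephrology_consult_2d=any_in("nephrology_consult", H2D),
        nephrotoxin_3d={k: any_in(k, H3D) for k in NEPHROTOXINS},
        nephrotoxin_7d={k: any_in(k, H7D) for k in NEPHROTOXINS},
        aki_documented=any(e.kind == "aki_documented" for e in events),
        los_days=los,
        total_cost=cost,
    )
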