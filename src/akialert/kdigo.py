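"""KDIGO creatinine-criteria AKI detection, staging, and CKD-EPI eGFR.

Acute kidney injury (AKI) is detected from a longitudinal serum-creatinine
(SCr) series using the two KDIGO creatinine criteria:

* an absolute rise of at least 0.3 mg/dL above the lowest SCr measured in the
  preceding 48 hours, or
* a rise to at least 1.5 times the lowest SCr measured in the preceding
  7 days (the *rolling baseline*).

Severity is staged against the baseline frozen at onset: stage 1 for a
1.5-1.9x rise (or the 0.3 mg/dL rule), stage 2 for 2.0-2.9x, stage 3 for a
3.0x or greater rise, an SCr of 4.0 mg/dL or higher, or initiation of kidney
replacement therapy (KRT).

Glomerular filtration rate is estimated with the CKD-EPI creatinine equation
(2009 two-level form, no race coefficient by default) from SCr, age and sex.

All creatinine values are mg/dL internally (multiply by 88.4 for umol/L);
times are hours relative to admission.  Negative times represent historic
pre-admission measurements, which participate in rolling baselines.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

__all__ = [
    "Measurement",
    "LabSeries",
    "AkiEpisode",
    "Demographics",
    "rolling_min",
    "detect_aki",
    "stage_at",
    "highest_stage",
    "egfr",
    "MGDL_PER_UMOLL",
]

#: conversion factor: SCr in umol/L = SCr in mg/dL * 88.4
MGDL_PER_UMOLL = 88.4

DELTA_048 = "delta048"  # >=0.3 mg/dL rise within 48 h
RATIO_7D = "ratio7d"    # >=1.5x lowest SCr within 7 d

# default criterion thresholds (mg/dL and ratios)
DELTA_THRESHOLD = 0.3
DELTA_WINDOW_H = 48.0
RATIO_THRESHOLD = 1.5
BASELINE_WINDOW_H = 168.0
STAGE2_RATIO = 2.0
STAGE3_RATIO = 3.0
STAGE3_SCR = 4.0

# threshold comparisons tolerate float rounding so printed boundaries
# (e.g. 1.2 vs 1.5 x 0.8) behave as exact arithmetic would
_EPS = 1e-9


@dataclass(frozen=True)
class Measurement:
    """One timestamped serum-creatinine result.

    time is in hours relative to admission (negative = pre-admission
    historic value); scr is mg/dL and must be positive.
    """

    time: float
    scr: float

    def __post_init__(self) -> None:
        if not self.scr > 0:
            raise ValueError(f"scr must be positive, got {self.scr}")


@dataclass
class LabSeries:
    """Time-ordered creatinine measurements for one admission."""

    measurements: list[Measurement]

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("LabSeries requires at least one measurement")
        times = [m.time for m in self.measurements]
        if any(b < a for a, b in zip(times, times[1:])):
            self.measurements = sorted(self.measurements, key=lambda m: m.time)

    @property
    def times(self) -> list[float]:
        return [m.time for m in self.measurements]

    @property
    def values(self) -> list[float]:
        return [m.scr for m in self.measurements]

    def scr_at(self, t: float) -> Optional[float]:
        """Most recent SCr at or before t (last observation carried forward)."""
        i = bisect.bisect_right(self.times, t)
        return self.measurements[i - 1].scr if i else None

    @classmethod
    def from_arrays(cls, times: Sequence[float], scrs: Sequence[float]) -> "LabSeries":
        return cls([Measurement(float(t), float(s)) for t, s in zip(times, scrs)])


@dataclass(frozen=True)
class Demographics:
    """Inputs to the CKD-EPI equation; trial enrolled adults only."""

    age: float
    sex: Literal["male", "female"]

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("age must be >= 18 (adult inclusion criterion)")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass
class AkiEpisode:
    """A detected AKI episode.

    baseline_scr is the lowest SCr in the 7 days preceding (and including)
    onset; it is frozen for the episode and anchors all staging ratios.
    """

    onset_time: float
    criterion: str  # DELTA_048 or RATIO_7D
    baseline_scr: float
    scr_at_aki: float
    stage_at_onset: int = 1
    egfr_at_aki: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scr_at_aki < self.baseline_scr:
            raise ValueError("scr_at_aki must be >= baseline_scr")


def rolling_min(series: LabSeries, t: float, window: float) -> Optional[float]:
    """Lowest SCr among measurements in the half-open window (t - window, t].

    The measurement at t itself is included; one exactly `window` hours
    earlier is excluded.  Returns None when the window holds no measurement.
    """
    lo, hi = t - window, t
    vals = [m.scr for m in series.measurements if lo < m.time <= hi]
    return min(vals) if vals else None


def detect_aki(
    series: LabSeries,
    demo: Optional[Demographics] = None,
    *,
    delta_threshold: float = DELTA_THRESHOLD,
    delta_window: float = DELTA_WINDOW_H,
    ratio_threshold: float = RATIO_THRESHOLD,
    baseline_window: float = BASELINE_WINDOW_H,
) -> Optional[AkiEpisode]:
    """Scan the series and return the earliest AKI episode, or None.

    Both criteria are evaluated at every measurement time t:

    * delta048:  scr(t) - min SCr in (t-48h, t]  >= 0.3 mg/dL
    * ratio7d:   scr(t) >= 1.5 * min SCr in (t-7d, t]

    The episode's baseline is the 7-day rolling minimum at onset.  When both
    criteria fire at the same timestamp the recorded criterion is delta048
    (a reporting convention only; the onset time is unaffected).  When
    demographics are supplied, eGFR at onset is filled in.
    """
    for m in series.measurements:
        base48 = rolling_min(series, m.time, delta_window)
        base7d = rolling_min(series, m.time, baseline_window)
        hit_delta = base48 is not None and m.scr - base48 >= delta_threshold - _EPS
        hit_ratio = (
            base7d is not None and m.scr >= (ratio_threshold - _EPS) * base7d
        )
        if hit_delta or hit_ratio:
            baseline = base7d if base7d is not None else base48
            ep = AkiEpisode(
                onset_time=m.time,
                criterion=DELTA_048 if hit_delta else RATIO_7D,
                baseline_scr=baseline,
                scr_at_aki=m.scr,
            )
            ep.stage_at_onset = stage_at(series, ep, m.time, krt_started=False)
            if demo is not None:
                ep.egfr_at_aki = egfr(m.scr, demo)
            return ep
    return None


def stage_at(
    series: LabSeries,
    episode: AkiEpisode,
    t: float,
    krt_started: bool = False,
    *,
    stage3_scr_rule: Literal["value", "delta"] = "value",
) -> int:
    """KDIGO stage at time t (>= onset) for a detected episode.

    Stage 3 when KRT has started, the SCr/baseline ratio reaches 3.0, or the
    4.0 mg/dL rule holds; stage 2 for a ratio in [2.0, 3.0); stage 1
    otherwise (the episode already satisfies a stage-1 criterion).

    stage3_scr_rule selects the reading of the 4.0 mg/dL rule: "value"
    (default, standard KDIGO semantics: SCr itself >= 4.0 in a patient
    meeting AKI criteria) or "delta" (rise above baseline >= 4.0).
    """
    if t < episode.onset_time:
        raise ValueError(f"t={t} precedes episode onset {episode.onset_time}")
    if krt_started:
        return 3
    scr = series.scr_at(t)
    if scr is None:
        raise ValueError("no measurement at or before t")
    ratio = scr / episode.baseline_scr
    if stage3_scr_rule == "value":
        scr4 = scr >= STAGE3_SCR - _EPS
    else:
        scr4 = scr - episode.baseline_scr >= STAGE3_SCR - _EPS
    if ratio >= STAGE3_RATIO - _EPS or scr4:
        return 3
    if ratio >= STAGE2_RATIO - _EPS:
        return 2
    return 1


def highest_stage(
    series: LabSeries,
    episode: AkiEpisode,
    horizon: float,
    krt_start_time: Optional[float] = None,
    *,
    stage3_scr_rule: Literal["value", "delta"] = "value",
) -> int:
    """Maximum stage over all measurement times in [onset, horizon].

    krt_start_time is the dialysis start, if any; KRT inside the window
    forces stage 3 regardless of creatinine.
    """
    if krt_start_time is not None and episode.onset_time <= krt_start_time <= horizon:
        return 3
    best = 0
    for m in series.measurements:
        if episode.onset_time <= m.time <= horizon:
            krt = krt_start_time is not None and krt_start_time <= m.time
            best = max(
                best,
                stage_at(series, episode, m.time, krt, stage3_scr_rule=stage3_scr_rule),
            )
    return best if best else episode.stage_at_onset


# CKD-EPI creatinine equation constants
_CKDEPI_2009 = {"female": (0.7, -0.329, 1.018), "male": (0.9, -0.411, 1.0)}
_CKDEPI_2021 = {"female": (0.7, -0.241, 1.012), "male": (0.9, -0.302, 1.0)}


def egfr(
    scr: float,
    demo: Demographics,
    *,
    variant: Literal["2009", "2009_race", "2021"] = "2009",
    black: bool = False,
) -> float:
    """Estimated GFR (mL/min/1.73 m2) from the CKD-EPI creatinine equation.

    Default is the 2009 two-level equation with the race coefficient omitted
    (the study cohort is entirely Han Chinese); "2009_race" applies the 1.159
    coefficient when black=True, "2021" uses the race-free refit.
    Strictly decreasing in SCr, and in age at fixed SCr and sex.
    """
    if not scr > 0:
        raise ValueError(f"scr must be positive, got {scr}")
    if variant in ("2009", "2009_race"):
        kappa, alpha, sexf = _CKDEPI_2009[demo.sex]
        val = (
            141.0
            * min(scr / kappa, 1.0) ** alpha
            * max(scr / kappa, 1.0) ** -1.209
            * 0.993 ** demo.age
            * sexf
        )
        if variant == "2009_race" and black:
            val *= 1.159
        return val
    if variant == "2021":
        kappa, alpha, sexf = _CKDEPI_2021[demo.sex]
        return (
            142.0
            * min(scr / kappa, 1.0) ** alpha
            * max(scr / kappa, 1.0) ** -1.200
            * 0.9938 ** demo.age
            * sexf
        )
    raise ValueError(f"unknown CKD-EPI variant {variant!r}")
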