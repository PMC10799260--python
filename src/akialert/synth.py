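"""Synthetic inpatient cohorts with controllable AKI trajectories.

The generator emulates the study conditions of a single-centre inpatient
AKI-alert trial: admissions with longitudinal serum-creatinine series,
an AKI incidence of about 1.4 episodes per 100 admissions with a roughly
50/25/25% stage-1/2/3 mix, stage-dependent 7-day mortality and dialysis,
and arm-dependent care-process event rates matching the trial's observed
per-arm proportions.

Trajectory model
----------------
Non-AKI series are flat on the log scale with multiplicative noise whose
relative amplitude is clipped to min(2.5*CV, 0.13/baseline), which
guarantees (not merely makes unlikely) that neither KDIGO criterion can
fire: the within-series range stays below both 0.3 mg/dL and a 1.5x ratio.
Injected AKI replaces post-onset values with an analytically controlled
ramp-plateau-recovery profile whose peak ratio is drawn inside the
requested stage's band (1.55-1.85, 2.1-2.8, or >=3.2 times the observed
pre-onset minimum, capped below the 4.0 mg/dL stage-3 value rule for
stages 1-2), so the highest KDIGO stage equals the requested stage by
construction.  Dialysis (which forces stage 3) is injected only for
stage-3 patients.

Reproducibility: one global seed; admission i draws from the independent
substream seeded with (seed, i), so cohorts are identical across runs and
insensitive to iteration order.  Arm-dependent events are drawn after
screening and randomizing each detected episode with the package's own
randomizer, so the pipeline re-derives identical assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import alerts
from .alerts import Randomizer, screen_eligibility, stratum_of
from .io import Admission, Cohort, EventRecord
from .kdigo import Demographics, LabSeries, Measurement, detect_aki, highest_stage

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "inject_aki",
           "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised for invalid generator settings."""


# Table-3-like per-arm probabilities (usual care, alert) for 2-day care
# outcomes and discharge documentation
DEFAULT_ARM_EFFECTS = {
    "iv_fluids": (0.618, 0.826),
    "urinalysis": (0.130, 0.362),
    "fluid_io": (0.685, 0.886),
    "scr_measured": (0.750, 0.925),
    "ultrasound": (0.006, 0.053),
    "anemia_corrected": (0.232, 0.460),
    "nephrology_consult": (0.205, 0.234),
    "aki_documented": (0.273, 0.499),
}

# nephrotoxin exposure: kind -> ((usual_3d, alert_3d), (usual_7d, alert_7d))
DEFAULT_NEPHROTOXIN_EFFECTS = {
    "contrast": ((0.030, 0.028), (0.045, 0.047)),
    "aminoglycoside": ((0.005, 0.004), (0.007, 0.006)),
    "vancomycin": ((0.024, 0.023), (0.033, 0.028)),
    "chemotherapy": ((0.016, 0.015), (0.020, 0.021)),
    "nsaid": ((0.110, 0.050), (0.124, 0.064)),
    "acei_arb": ((0.043, 0.038), (0.051, 0.045)),
}

_STAGE_PEAK_BANDS = {1: (1.55, 1.85), 2: (2.10, 2.80), 3: (3.20, 4.00)}
_DEATH_WEIGHTS = {1: 0.6, 2: 1.0, 3: 1.8}  # relative 7-day hazard by stage


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate the trial's marginals: ~1.4 AKI episodes per 100
    admissions, stage mix 50/25/25%, baseline creatinine log-normal with
    median 0.87 mg/dL, ~11% 7-day mortality and ~12% 7-day dialysis among
    AKI patients, and the observed per-arm care-process rates.
    """

    n_admissions: int = 1000
    aki_incidence: float = 0.014
    stage_mix: tuple[float, float, float] = (0.50, 0.25, 0.25)
    baseline_scr_mu: float = math.log(0.87)  # log-mg/dL
    baseline_scr_sigma: float = 0.35
    noise_cv: float = 0.05
    ward_interval_h: tuple[float, float] = (20.0, 28.0)
    icu_interval_h: tuple[float, float] = (6.0, 12.0)
    mortality_7d: float = 0.11
    mortality_28d: float = 0.35
    mortality_90d: float = 0.38
    dialysis_7d: float = 0.12
    arm_effects: dict = field(default_factory=lambda: dict(DEFAULT_ARM_EFFECTS))
    nephrotoxin_effects: dict = field(
        default_factory=lambda: {
            k: tuple(map(tuple, v)) for k, v in DEFAULT_NEPHROTOXIN_EFFECTS.items()
        }
    )
    icu_fraction: float = 0.606
    medical_fraction: float = 0.50
    male_fraction: float = 0.707
    age_mean: float = 64.0
    age_sd: float = 13.0
    los_median_d: float = 6.0
    los_sigma: float = 0.7
    onset_median_d: float = 6.0
    p_eskd: float = 0.004
    p_transplant: float = 0.003
    seed: int = 0
    study_start: str = "2019-08-01"

    def __post_init__(self) -> None:
        # normalize containers so YAML round-trips compare equal
        self.stage_mix = tuple(self.stage_mix)
        self.ward_interval_h = tuple(self.ward_interval_h)
        self.icu_interval_h = tuple(self.icu_interval_h)
        self.arm_effects = {k: tuple(v) for k, v in self.arm_effects.items()}
        self.nephrotoxin_effects = {
            k: tuple(tuple(p) for p in v)
            for k, v in self.nephrotoxin_effects.items()
        }
        if self.n_admissions < 1:
            raise ConfigurationError("n_admissions must be >= 1")
        probs = [
            self.aki_incidence, self.mortality_7d, self.mortality_28d,
            self.mortality_90d, self.dialysis_7d, self.icu_fraction,
            self.medical_fraction, self.male_fraction, self.p_eskd,
            self.p_transplant, *self.stage_mix,
        ]
        for kind, pair in self.arm_effects.items():
            probs.extend(pair)
        for kind, (p3, p7) in self.nephrotoxin_effects.items():
            probs.extend(p3)
            probs.extend(p7)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise ConfigurationError("stage_mix must sum to 1")
        if self.noise_cv < 0 or self.noise_cv > 0.2:
            raise ConfigurationError("noise_cv must be in [0, 0.2]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the injected ground truth.

    ground_truth has one row per admission: injected AKI flag and stage,
    onset, death/dialysis times (hours since admission), arm, eligibility,
    and the injected care-outcome truth flags.
    """

    cohort: Cohort
    ground_truth: pd.DataFrame

    @property
    def admissions(self) -> list[Admission]:
        return self.cohort.admissions


def _noise_band(baseline: float, cv: float) -> float:
    # relative amplitude that can neither reach a 0.3 mg/dL rise nor 1.5x
    return min(2.5 * cv, 0.13 / baseline)


def _flat_series(rng, baseline: float, times: np.ndarray, cv: float) -> np.ndarray:
    d = _noise_band(baseline, cv)
    eps = np.clip(rng.normal(0.0, cv, size=len(times)), -d, d) if cv else 0.0
    return baseline * (1.0 + eps)


def _measurement_times(rng, los_h: float, icu: bool, cfg: GeneratorConfig) -> np.ndarray:
    lo, hi = cfg.icu_interval_h if icu else cfg.ward_interval_h
    times = [rng.uniform(1.0, 4.0)]
    while times[-1] < los_h:
        times.append(times[-1] + rng.uniform(lo, hi))
    times = [t for t in times if t <= los_h]
    return np.asarray(times if times else [min(1.0, los_h)])


def inject_aki(
    series: LabSeries,
    stage: int,
    onset: float,
    rng: Optional[np.random.Generator] = None,
    peak_ratio: Optional[float] = None,
) -> LabSeries:
    """Overwrite the series from `onset` onward with a stage-targeted rise.

    The observed pre-onset minimum is the effective baseline; post-onset
    values ramp to a peak drawn in the requested stage's ratio band (or
    `peak_ratio` if given), hold it, then partially recover, never dipping
    below baseline.  The returned series is guaranteed to trigger KDIGO
    detection at or after `onset` with highest stage equal to `stage`
    (absent kidney replacement therapy, which the caller controls).
    """
    if stage not in (1, 2, 3):
        raise ValueError(f"stage must be 1, 2 or 3, got {stage}")
    first, last = series.measurements[0].time, series.measurements[-1].time
    if not first < onset <= last:
        raise ValueError(
            f"onset {onset} outside the measured admission ({first}, {last}]"
        )
    rng = rng or np.random.default_rng()
    pre = [m for m in series.measurements if m.time < onset]
    post_times = [m.time for m in series.measurements if m.time >= onset]
    if not post_times or post_times[0] > onset:
        post_times = [onset] + post_times
    if len(post_times) < 3:  # guarantee room for ramp and plateau
        step = max((last - first) / max(len(series.measurements) - 1, 1), 6.0)
        while len(post_times) < 3:
            post_times.append(post_times[-1] + step)
    # reference baseline = what the detector's 7-day rolling minimum sees
    # at onset: the lowest pre-onset value within the trailing window
    window = [m.scr for m in pre if onset - 168.0 < m.time]
    base_ref = min(window) if window else min(m.scr for m in pre)

    lo, hi = _STAGE_PEAK_BANDS[stage]
    r_peak = float(rng.uniform(lo, hi)) if peak_ratio is None else float(peak_ratio)
    peak = r_peak * base_ref
    if stage < 3:
        # stay under the 4.0 mg/dL stage-3 value rule
        peak = min(peak, 3.95)
        if peak < lo * base_ref:  # high baseline: band unreachable below 4.0
            raise ValueError(
                f"baseline {base_ref:.2f} mg/dL too high to inject stage {stage}"
            )
    n = len(post_times)
    r_peak = peak / base_ref
    # the first post-onset value already exceeds 1.5x, so detection fires
    # exactly at `onset` and freezes base_ref as the episode baseline
    r_start = min(1.55, r_peak)
    ramp_len = min(max(1, n // 3), 4)
    r_end = float(rng.uniform(1.05, 1.35))
    ratios = []
    for j in range(n):
        if j < ramp_len:
            frac = j / ramp_len if ramp_len > 1 else 1.0
            r = r_start + frac * (r_peak - r_start)
            if j == ramp_len - 1:
                r = r_peak
        elif j < ramp_len + 2:
            r = r_peak
        else:
            decay = (j - ramp_len - 1) / max(n - ramp_len - 2, 1)
            r = r_peak + decay * (r_end - r_peak)
        ratios.append(min(max(r, 1.0), r_peak))
    post = [Measurement(t, base_ref * r) for t, r in zip(post_times, ratios)]
    return LabSeries(pre + post)


def _draw_death_time(rng, cfg: GeneratorConfig, stage: int, t_rand: float,
                     scale: dict) -> Optional[float]:
    u = rng.uniform()
    p7 = min(scale["death7"] * _DEATH_WEIGHTS[stage], 0.95)
    extra28 = max(cfg.mortality_28d - cfg.mortality_7d, 0.0)
    extra90 = max(cfg.mortality_90d - cfg.mortality_28d, 0.0)
    if u < p7:
        return t_rand + rng.uniform(2.0, 166.0)
    if u < p7 + extra28:
        return t_rand + rng.uniform(169.0, 671.0)
    if u < p7 + extra28 + extra90:
        return t_rand + rng.uniform(673.0, 2159.0)
    return None


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort under `config`.

    Deterministic given the seed.  Each admission uses the substream
    seeded with (seed, admission index).  Detected episodes are screened
    and randomized with the package's alert-system machinery, and
    arm-dependent care events are then drawn at the configured per-arm
    probabilities, giving exact per-patient ground truth.
    """
    cfg = config
    start = pd.Timestamp(cfg.study_start)
    randomizer = Randomizer()
    admissions: list[Admission] = []
    labs: dict[str, LabSeries] = {}
    events: dict[str, list[EventRecord]] = {}
    truth_rows = []

    death7_scale = cfg.mortality_7d / sum(
        w * m for w, m in zip(
            (_DEATH_WEIGHTS[1], _DEATH_WEIGHTS[2], _DEATH_WEIGHTS[3]),
            cfg.stage_mix,
        )
    ) if cfg.mortality_7d else 0.0
    scale = {"death7": death7_scale}

    for i in range(cfg.n_admissions):
        rng = np.random.default_rng([cfg.seed, i])
        pid = f"P{i:06d}"
        demo = Demographics(
            age=round(float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18.0, 95.0)), 1),
            sex="male" if rng.uniform() < cfg.male_fraction else "female",
        )
        ward = "medical" if rng.uniform() < cfg.medical_fraction else "surgical"
        icu = rng.uniform() < cfg.icu_fraction
        eskd = rng.uniform() < cfg.p_eskd
        transplant = rng.uniform() < cfg.p_transplant
        baseline = float(rng.lognormal(cfg.baseline_scr_mu, cfg.baseline_scr_sigma))
        is_aki = rng.uniform() < cfg.aki_incidence
        stage = 0
        onset = death_t = dial_t = None
        t_rand = None

        if is_aki:
            stage = int(rng.choice([1, 2, 3], p=list(cfg.stage_mix)))
            # truncate high baselines so the requested stage's ratio band
            # stays below the 4.0 mg/dL stage-3 value rule
            cap = {1: 2.0, 2: 1.7, 3: math.inf}[stage]
            while baseline > cap:
                baseline = float(
                    rng.lognormal(cfg.baseline_scr_mu, cfg.baseline_scr_sigma)
                )
            onset = float(rng.exponential(cfg.onset_median_d / math.log(2)) * 24.0)
            onset = float(np.clip(onset, 30.0, 30.0 * 24.0))
            los_h = onset + rng.uniform(7.0, 21.0) * 24.0
        else:
            los_h = float(
                rng.lognormal(math.log(cfg.los_median_d * 24.0), cfg.los_sigma)
            )
            los_h = float(np.clip(los_h, 6.0, 90.0 * 24.0))

        times = _measurement_times(rng, los_h, icu, cfg)
        values = _flat_series(rng, baseline, times, cfg.noise_cv)
        series = LabSeries.from_arrays(times, values)
        ev: list[EventRecord] = []
        truth = {
            "patient_id": pid, "aki": is_aki, "stage": stage,
            "stage_injected": stage, "onset_h": np.nan,
            "baseline_scr": baseline,
            "death_h": np.nan, "dialysis_h": np.nan,
            "arm": "", "eligible": False, "exclusion_reason": "",
        }

        if is_aki:
            series = inject_aki(series, stage, onset, rng)
            episode = detect_aki(series, demo)
            assert episode is not None, "injected series must trigger detection"
            t_rand = episode.onset_time
            truth["onset_h"] = t_rand

            if stage == 3 and cfg.stage_mix[2] > 0:
                p_dial = min(cfg.dialysis_7d / cfg.stage_mix[2], 0.95)
                if rng.uniform() < p_dial:
                    dial_t = t_rand + rng.uniform(
                        2.0, max(min(166.0, los_h - t_rand - 1.0), 3.0)
                    )
            death_t = _draw_death_time(rng, cfg, stage, t_rand, scale)
            if death_t is not None and death_t <= los_h:
                los_h = death_t  # death truncates the admission

        admission = Admission(
            patient_id=pid,
            admit_time=start + pd.Timedelta(hours=float(i) * 1.7),
            discharge_time=start
            + pd.Timedelta(hours=float(i) * 1.7 + max(los_h, 0.5)),
            ward_type=ward,
            icu=icu,
            demographics=demo,
            eskd_admission=eskd,
            kidney_transplant_history=transplant,
            total_cost=float(rng.lognormal(math.log(20000.0), 0.8)),
        )
        # drop measurements after (possibly truncated) discharge
        kept = [m for m in series.measurements if m.time <= los_h]
        if kept:
            series = LabSeries(kept)
        labs[pid] = series

        if is_aki:
            episode = detect_aki(series, demo)
            if episode is not None:
                # achieved stage can fall below the injected one when death
                # truncates the series before the planned peak
                truth["stage"] = highest_stage(
                    series, episode, los_h,
                    krt_start_time=dial_t if dial_t and dial_t <= los_h else None,
                )
                elig = screen_eligibility(admission, episode, series)
                truth["eligible"] = elig.eligible
                truth["exclusion_reason"] = elig.exclusion_reason or ""
                if elig.eligible:
                    assignment = randomizer.assign(stratum_of(ward, icu))
                    arm = assignment.arm
                    truth["arm"] = arm
                    ai = 1 if arm == alerts.ALERT else 0
                    horizon = los_h - t_rand
                    for kind, pair in cfg.arm_effects.items():
                        if rng.uniform() >= pair[ai]:
                            if kind == "anemia_corrected":
                                # hemoglobin measured but below threshold
                                ev.append(EventRecord(
                                    pid, t_rand + rng.uniform(0.5, 47.5),
                                    "hemoglobin", float(rng.uniform(6.5, 9.0)),
                                ))
                            truth[f"{kind}_2d"] = False
                            continue
                        truth[f"{kind}_2d"] = True
                        if kind == "aki_documented":
                            ev.append(EventRecord(
                                pid, max(los_h - 0.5, t_rand + 0.5),
                                "aki_documented", None,
                            ))
                        elif kind == "anemia_corrected":
                            ev.append(EventRecord(
                                pid, t_rand + rng.uniform(0.5, 47.5),
                                "hemoglobin", float(rng.uniform(9.1, 14.0)),
                            ))
                        else:
                            ev.append(EventRecord(
                                pid, t_rand + rng.uniform(0.5, 47.5), kind, None,
                            ))
                    for kind, (p3, p7) in cfg.nephrotoxin_effects.items():
                        hit3 = rng.uniform() < p3[ai]
                        extra = max(p7[ai] - p3[ai], 0.0) / max(1.0 - p3[ai], 1e-12)
                        hit7only = (not hit3) and rng.uniform() < extra
                        truth[f"{kind}_3d"] = hit3
                        truth[f"{kind}_7d"] = hit3 or hit7only
                        if hit3:
                            ev.append(EventRecord(
                                pid, t_rand + rng.uniform(0.5, 71.5), kind, None,
                            ))
                        elif hit7only:
                            ev.append(EventRecord(
                                pid, t_rand + rng.uniform(72.5, 167.5), kind, None,
                            ))
            if death_t is not None:
                ev.append(EventRecord(pid, death_t, "death", None))
                truth["death_h"] = death_t
            if dial_t is not None and dial_t <= los_h:
                ev.append(EventRecord(pid, dial_t, "dialysis_start", None))
                truth["dialysis_h"] = dial_t

        # events cannot postdate death
        if death_t is not None:
            ev = [e for e in ev if e.kind == "death" or e.time <= death_t]
        ev = sorted(ev, key=lambda e: e.time)
        events[pid] = ev
        if truth["arm"]:
            # truth flags must reflect the surviving events exactly
            def _hit(kind, horizon, hb=False):
                return any(
                    e.kind == kind
                    and t_rand < e.time <= t_rand + horizon
                    and (not hb or (e.value is not None and e.value > 9.0))
                    for e in ev
                )

            for kind in cfg.arm_effects:
                if kind == "aki_documented":
                    truth["aki_documented_2d"] = any(
                        e.kind == "aki_documented" for e in ev
                    )
                elif kind == "anemia_corrected":
                    truth["anemia_corrected_2d"] = _hit("hemoglobin", 48.0, hb=True)
                else:
                    truth[f"{kind}_2d"] = _hit(kind, 48.0)
            for kind in cfg.nephrotoxin_effects:
                truth[f"{kind}_3d"] = _hit(kind, 72.0)
                truth[f"{kind}_7d"] = _hit(kind, 168.0)
        admissions.append(admission)
        truth_rows.append(truth)

    gt = pd.DataFrame(truth_rows)
    cohort = Cohort(admissions=admissions, labs=labs, events=events,
                    ground_truth=gt)
    return SyntheticCohort(cohort=cohort, ground_truth=gt)
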