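"""Trial-eligibility screening, stratified seeded randomization, and alerts.

Detected AKI episodes are screened against the trial's exclusion list, and
eligible patients are randomized 1:1 to an alert arm or a usual-care arm
within four strata defined by ward type (medical vs surgical) crossed with
ICU status.  Randomization is seeded: stratum k draws from a generator
seeded with 20180101 + k (consecutive increments of the universal seed), so
every assignment is reproducible from (stratum, draw index) alone.

Alert-arm patients receive a templated message with the triggering
creatinine; at most three messages are sent per admission to limit alert
fatigue.  Usual-care patients never receive messages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .kdigo import AkiEpisode, LabSeries, egfr

__all__ = [
    "EligibilityResult",
    "ArmAssignment",
    "AlertMessage",
    "Randomizer",
    "STRATA",
    "UNIVERSAL_SEED",
    "screen_eligibility",
    "randomize",
    "emit_alert",
    "render_message",
    "MESSAGE_TEMPLATE",
]

UNIVERSAL_SEED = 20180101

#: stratum order fixes the seed offsets: stratum k uses UNIVERSAL_SEED + k
STRATA = ("medical_icu", "medical_ward", "surgical_icu", "surgical_ward")

ALERT = "alert"
USUAL_CARE = "usual_care"
MAX_ALERTS_PER_ADMISSION = 3

# exclusion reasons, in the order the trial lists them; the first failing
# check is the one reported
EXCLUSION_ORDER = (
    "baseline_egfr_lt_15",
    "eskd_admission",
    "kidney_transplant",
    "community_acquired",
    "stay_lt_24h",
    "baseline_scr_lt_0.5",
    "repeat_admission",
)

EGFR_FLOOR = 15.0     # mL/min/1.73m2: below this, exclude
SCR_FLOOR = 0.5       # mg/dL: baseline below this, exclude
MIN_STAY_H = 24.0


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.eligible == (self.exclusion_reason is not None):
            raise ValueError("eligible XOR exclusion_reason must hold")


@dataclass(frozen=True)
class ArmAssignment:
    """Provenance-carrying arm assignment for one randomized patient."""

    stratum: str
    arm: str
    seed_used: int
    draw_index: int


@dataclass(frozen=True)
class AlertMessage:
    patient_ref: str
    scr_value: float
    test_time: str
    rendered_text: str
    sequence_number: int


def stratum_of(ward_type: str, icu: bool) -> str:
    """Map ward type x ICU status onto the four randomization strata."""
    if ward_type not in ("medical", "surgical"):
        raise ValueError(f"ward_type must be medical|surgical, got {ward_type!r}")
    return f"{ward_type}_{'icu' if icu else 'ward'}"


def screen_eligibility(
    admission,
    episode: AkiEpisode,
    series: LabSeries,
    prior_patient_ids: Iterable[str] = (),
) -> EligibilityResult:
    """Apply the trial's seven exclusions to a detected episode.

    Checks, in the trial's listed order: baseline eGFR < 15, end-stage
    kidney disease at admission, kidney-transplant history,
    community-acquired AKI, stay under 24 h, baseline SCr < 0.5 mg/dL, and
    repeat admission within the study period.  The decision is
    order-independent; only the reported reason follows the listed order.

    Community-acquired is operationalized as: the episode's 7-day baseline
    minimum was measured before admission, or detection fired at the first
    in-admission measurement (the rise predates the admission's lab stream).
    """
    demo = admission.demographics
    if demo is None:
        raise ValueError("demographics required to evaluate the eGFR exclusion")

    reasons = []
    if egfr(episode.baseline_scr, demo) < EGFR_FLOOR:
        reasons.append("baseline_egfr_lt_15")
    if getattr(admission, "eskd_admission", False):
        reasons.append("eskd_admission")
    if getattr(admission, "kidney_transplant_history", False):
        reasons.append("kidney_transplant")
    if _community_acquired(series, episode):
        reasons.append("community_acquired")
    stay_h = getattr(admission, "stay_hours", None)
    if stay_h is None:
        stay_h = admission.discharge_time - admission.admit_time
    if stay_h < MIN_STAY_H:
        reasons.append("stay_lt_24h")
    if episode.baseline_scr < SCR_FLOOR:
        reasons.append("baseline_scr_lt_0.5")
    if admission.patient_id in set(prior_patient_ids):
        reasons.append("repeat_admission")

    if reasons:
        first = min(reasons, key=EXCLUSION_ORDER.index)
        return EligibilityResult(eligible=False, exclusion_reason=first)
    return EligibilityResult(eligible=True)


def _community_acquired(series: LabSeries, episode: AkiEpisode) -> bool:
    in_admission = [m for m in series.measurements if m.time >= 0]
    if not in_admission:
        return True
    # baseline minimum achieved only pre-admission?
    lo = episode.onset_time - 168.0
    window = [m for m in series.measurements if lo < m.time <= episode.onset_time]
    min_times = [m.time for m in window if m.scr == episode.baseline_scr]
    if min_times and all(t < 0 for t in min_times):
        return True
    # criteria already met at the first in-admission measurement
    return episode.onset_time <= in_admission[0].time


class Randomizer:
    """Stateful per-stratum 1:1 randomizer with the trial's seed scheme.

    Each stratum k in STRATA order owns an independent PCG64 stream seeded
    with 20180101 + k; successive eligible patients in a stratum consume
    successive Bernoulli(1/2) draws.  Assignments are therefore a pure
    function of (stratum, draw_index), reproducible across runs and
    platforms.  blocked=m switches to permuted blocks of size m.
    """

    def __init__(self, universal_seed: int = UNIVERSAL_SEED, blocked: int = 0):
        self.universal_seed = universal_seed
        self.blocked = blocked
        self._counters = {s: 0 for s in STRATA}

    def assign(self, stratum: str) -> ArmAssignment:
        idx = self._counters[stratum]
        self._counters[stratum] += 1
        return randomize(
            stratum, idx, universal_seed=self.universal_seed, blocked=self.blocked
        )


def randomize(
    stratum: str,
    draw_index: int,
    *,
    universal_seed: int = UNIVERSAL_SEED,
    blocked: int = 0,
) -> ArmAssignment:
    """Arm for the draw_index-th eligible patient of a stratum (0-based).

    Deterministic: the stratum's full draw stream is regenerated from its
    seed on every call.  Simple Bernoulli 1:1 by default; with blocked=m,
    permuted blocks of size m (m even) guarantee exact balance per block.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    if draw_index < 0:
        raise ValueError("draw_index must be >= 0")
    seed = universal_seed + STRATA.index(stratum)
    rng = np.random.default_rng(seed)
    if blocked:
        if blocked % 2:
            raise ValueError("block size must be even for 1:1 allocation")
        block_no, pos = divmod(draw_index, blocked)
        block = None
        for _ in range(block_no + 1):
            block = rng.permutation([ALERT, USUAL_CARE] * (blocked // 2))
        arm = str(block[pos])
    else:
        draws = rng.integers(0, 2, size=draw_index + 1)
        arm = ALERT if draws[-1] == 1 else USUAL_CARE
    return ArmAssignment(stratum=stratum, arm=arm, seed_used=seed, draw_index=draw_index)


MESSAGE_TEMPLATE = (
    "Greetings, the patient in bed [bed], in the [ward] ward, admitted on "
    "[admit_date], has a serum creatinine result of [scr] from the "
    "[test_date] test time. Based on the creatinine result, acute kidney "
    "injury is probable to occur. Acute kidney injury requires optimization "
    "of hemodynamics, discontinuation of unnecessary nephrotoxic drugs, and "
    "adjustment of antimicrobial drug dosage and dialysis if necessary. "
    "Please be vigilant and handle it accordingly. Thank you! For diagnosis "
    "and treatment inquiries, please contact the nephrology consultation "
    "service at the kidney consultation phone number [consult_phone]."
)

_PLACEHOLDERS = ("bed", "ward", "admit_date", "scr", "test_date", "consult_phone")


def render_message(context: Mapping[str, object]) -> str:
    """Fill the alert/care-bundle message template.

    context must supply bed, ward, admit_date, scr (mg/dL, rendered with two
    decimals when numeric), test_date and consult_phone.  Missing fields
    raise with their names; the output contains no residual bracket tokens.
    """
    missing = [p for p in _PLACEHOLDERS if p not in context or context[p] in (None, "")]
    if missing:
        raise KeyError(f"missing message fields: {', '.join(missing)}")
    text = MESSAGE_TEMPLATE
    for key in _PLACEHOLDERS:
        val = context[key]
        if key == "scr" and isinstance(val, (int, float)):
            val = f"{val:.2f}"
        text = text.replace(f"[{key}]", str(val))
    return text


def emit_alert(
    assignment: ArmAssignment,
    episode: AkiEpisode,
    prior_alert_count: int,
    context: Optional[Mapping[str, object]] = None,
    patient_ref: str = "",
) -> Optional[AlertMessage]:
    """Next alert message for a trigger, or None.

    Usual-care patients never receive messages; alert-arm patients receive
    at most three per admission (any emitted message counts against the
    cap, regardless of day or episode).
    """
    if assignment.arm != ALERT:
        return None
    if prior_alert_count >= MAX_ALERTS_PER_ADMISSION:
        return None
    ctx = dict(context) if context else {
        "bed": "?", "ward": assignment.stratum, "admit_date": "?",
        "scr": episode.scr_at_aki, "test_date": "?", "consult_phone": "?",
    }
    ctx.setdefault("scr", episode.scr_at_aki)
    return AlertMessage(
        patient_ref=patient_ref,
        scr_value=episode.scr_at_aki,
        test_time=str(ctx.get("test_date", "")),
        rendered_text=render_message(ctx),
        sequence_number=prior_alert_count + 1,
    )
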