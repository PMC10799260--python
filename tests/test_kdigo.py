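"""Detection, staging and eGFR against hand-built series and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akialert.kdigo import (AkiEpisode, Demographics, LabSeries, Measurement,
                            MGDL_PER_UMOLL, detect_aki, egfr, highest_stage,
                            rolling_min, stage_at)
from conftest import random_series


def brute_force_detect(series: LabSeries):
    """Independent oracle: check every ordered measurement pair (and the
    single-point degenerate pair) against both criteria; earliest hit wins."""
    ms = series.measurements
    for j, mj in enumerate(ms):
        for i in range(j + 1):
            mi = ms[i]
            if mi.time <= mj.time - 168.0:
                continue
            in48 = mi.time > mj.time - 48.0
            if in48 and mj.scr - mi.scr >= 0.3:
                return mj.time
            if mj.scr >= 1.5 * mi.scr:
                return mj.time
    return None


class TestRollingMin:
    def test_minimum_over_window(self):
        s = LabSeries.from_arrays([0, 24, 60], [1.0, 0.8, 1.3])
        assert rolling_min(s, 60, 168) == 0.8

    def test_single_measurement_at_t_is_included(self):
        s = LabSeries.from_arrays([10], [1.1])
        assert rolling_min(s, 10, 48) == 1.1

    def test_half_open_lower_bound_excludes_exact_window_edge(self):
        s = LabSeries.from_arrays([0, 48], [0.5, 1.0])
        # the 0.5 at exactly 48 h before t falls outside (t-48, t]
        assert rolling_min(s, 48, 48) == 1.0

    def test_empty_window_returns_none(self):
        s = LabSeries.from_arrays([0], [1.0])
        assert rolling_min(s, 300, 48) is None


class TestDetect:
    def test_delta_boundary_fires(self):
        s = LabSeries.from_arrays([0, 36], [0.8, 1.1])
        ep = detect_aki(s)
        assert ep is not None
        assert ep.onset_time == 36
        assert ep.criterion == "delta048"
        assert ep.baseline_scr == 0.8

    def test_ratio_boundary_fires_beyond_48h(self):
        s = LabSeries.from_arrays([0, 144], [0.8, 1.2])
        ep = detect_aki(s)
        assert ep is not None
        assert ep.criterion == "ratio7d"
        assert ep.baseline_scr == 0.8

    def test_below_both_thresholds_is_none(self):
        s = LabSeries.from_arrays([0, 36], [0.8, 1.05])
        assert detect_aki(s) is None

    def test_tie_reports_delta_criterion(self):
        # at +36 h both 0.3-delta and 1.5x fire simultaneously
        s = LabSeries.from_arrays([0, 36], [0.6, 0.9])
        ep = detect_aki(s)
        assert ep.criterion == "delta048"

    def test_baseline_is_seven_day_minimum(self):
        # at t=100 neither criterion fires (0.85 < 1.5*0.6, 48h window empty
        # of the 0.6); at t=130 both fire and the baseline is the 7-day min
        s = LabSeries.from_arrays([0, 100, 130], [0.6, 0.85, 1.35])
        ep = detect_aki(s)
        assert ep.onset_time == 130
        assert ep.baseline_scr == 0.6

    def test_agrees_with_pairwise_oracle_on_random_series(self):
        rng = np.random.default_rng(20180101)
        for _ in range(400):
            s = random_series(rng)
            ep = detect_aki(s)
            oracle = brute_force_detect(s)
            if oracle is None:
                assert ep is None
            else:
                assert ep is not None and ep.onset_time == pytest.approx(oracle)

    def test_detection_is_prefix_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            s = random_series(rng)
            ep = detect_aki(s)
            if ep is None:
                continue
            extended = LabSeries(
                s.measurements
                + [Measurement(s.measurements[-1].time + 24.0, 1.0)]
            )
            ep2 = detect_aki(extended)
            assert ep2 is not None and ep2.onset_time == ep.onset_time

    def test_unit_round_trip_preserves_decisions(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            s = random_series(rng)
            umol = [m.scr * MGDL_PER_UMOLL for m in s.measurements]
            back = LabSeries.from_arrays(s.times, [v / MGDL_PER_UMOLL for v in umol])
            assert (detect_aki(s) is None) == (detect_aki(back) is None)


class TestStaging:
    def _episode(self, baseline=0.8):
        return AkiEpisode(onset_time=24, criterion="delta048",
                          baseline_scr=baseline, scr_at_aki=1.5 * baseline)

    @pytest.mark.parametrize(
        "ratio,expected", [(1.5, 1), (1.9, 1), (1.99, 1), (2.0, 2),
                           (2.9, 2), (2.99, 2), (3.0, 3), (3.5, 3)]
    )
    def test_ratio_bands(self, ratio, expected):
        ep = self._episode()
        s = LabSeries.from_arrays([0, 24, 48], [0.8, 1.2, 0.8 * ratio])
        assert stage_at(s, ep, 48) == expected

    def test_krt_forces_stage_3(self):
        ep = self._episode()
        s = LabSeries.from_arrays([0, 24, 48], [0.8, 1.2, 0.8 * 1.6])
        assert stage_at(s, ep, 48, krt_started=True) == 3

    def test_scr_4_value_rule(self):
        # 4.1 mg/dL on a 1.5 baseline: ratio 2.73 (stage 2) but value >= 4.0
        ep = self._episode(baseline=1.5)
        s = LabSeries.from_arrays([0, 24, 48], [1.5, 2.0, 4.1])
        assert stage_at(s, ep, 48) == 3
        # literal delta reading: rise 2.6 < 4.0 -> stays stage 2
        assert stage_at(s, ep, 48, stage3_scr_rule="delta") == 2

    def test_before_onset_raises(self):
        ep = self._episode()
        s = LabSeries.from_arrays([0, 24], [0.8, 1.2])
        with pytest.raises(ValueError):
            stage_at(s, ep, 10)

    def test_highest_stage_is_running_maximum(self):
        ep = self._episode()
        # ratios 1.5, 2.1, 1.6 -> stages 1, 2, 1 -> highest 2
        s = LabSeries.from_arrays([0, 24, 48, 72], [0.8, 1.2, 1.68, 1.28])
        assert highest_stage(s, ep, 72) == 2

    def test_highest_stage_single_point(self):
        ep = self._episode()
        s = LabSeries.from_arrays([0, 24], [0.8, 1.2])
        assert highest_stage(s, ep, 24) == stage_at(s, ep, 24)

    def test_dialysis_in_window_gives_3(self):
        ep = self._episode()
        s = LabSeries.from_arrays([0, 24, 48], [0.8, 1.2, 1.3])
        assert highest_stage(s, ep, 48, krt_start_time=30.0) == 3

    def test_stage_nondecreasing_in_scr(self):
        ep = self._episode()
        stages = []
        for scr in np.linspace(0.8, 4.5, 40):
            s = LabSeries.from_arrays([0, 24, 48], [0.8, 1.2, scr])
            stages.append(stage_at(s, ep, 48))
        assert stages == sorted(stages)


class TestEgfr:
    # frozen from an independent evaluation of the published 2009 equation:
    # 141 * min(S/k,1)^a * max(S/k,1)^-1.209 * 0.993^age * (1.018 if female)
    @pytest.mark.parametrize(
        "scr,age,sex,expected",
        [
            (1.0, 60, "male", 81.4429),
            (1.0, 60, "female", 61.1851),
            (0.6, 40, "female", 114.0151),
            (2.5, 75, "male", 24.2093),
        ],
    )
    def test_hand_computed_values(self, scr, age, sex, expected):
        assert egfr(scr, Demographics(age=age, sex=sex)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_sex_factor_above_kappa(self):
        # same scr above both kappas: ratio of female/male involves the
        # published 1.018 factor and the kappa/alpha pair
        d_m = Demographics(age=60, sex="male")
        d_f = Demographics(age=60, sex="female")
        ratio = egfr(2.0, d_f) / egfr(2.0, d_m)
        expected = 1.018 * (0.7 / 0.9) ** 1.209
        assert ratio == pytest.approx(expected, rel=1e-9)

    @given(
        scr=st.floats(0.2, 8.0),
        age=st.floats(18, 95),
        sex=st.sampled_from(["male", "female"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_scr_and_age(self, scr, age, sex):
        d = Demographics(age=age, sex=sex)
        assert egfr(scr * 2, d) < egfr(scr, d)
        if age + 5 <= 95:
            assert egfr(scr, Demographics(age=age + 5, sex=sex)) < egfr(scr, d)

    def test_nonpositive_scr_raises(self):
        with pytest.raises(ValueError):
            egfr(0.0, Demographics(age=50, sex="male"))

    def test_2021_variant_differs_and_is_race_free(self):
        d = Demographics(age=60, sex="male")
        assert egfr(1.0, d, variant="2021") != pytest.approx(egfr(1.0, d))
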