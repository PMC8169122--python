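"""Phase calling, event detection and fate classification."""

import numpy as np
import pandas as pd
import pytest

from pulsefate.errors import ConfigurationError, FormatError
from pulsefate.fates import (
    aggregate_cohort,
    call_phase_track,
    classify_fate,
    detect_division_events,
    interphase_length,
    label_exposure_phase,
    mitotic_length,
    phase_fractions,
)
from pulsefate.synthetic.fucci import (
    CellCycleParams,
    FateAllocation,
    make_fucci_cohort,
)


def frames_from(red, green, area=None, alive=None, dt=30.0):
    n = len(red)
    return pd.DataFrame(
        {
            "time_min": np.arange(n) * dt,
            "red": red,
            "green": green,
            "area_um2": area if area is not None else np.full(n, 140.0),
            "alive": alive if alive is not None else np.ones(n, bool),
        }
    )


class TestPhaseCalling:
    def test_pure_red_is_g1(self):
        f = frames_from([1.0] * 10, [0.0] * 10)
        assert (call_phase_track(f) == "G1").all()

    def test_colour_semantics(self):
        f = frames_from([1, 1, 1, 0.7, 0.0, 0.0, 0.0, 0.0],
                        [0, 0, 0, 0.6, 1.0, 1.0, 1.0, 1.0])
        called = call_phase_track(f, min_run=1)
        assert list(called) == ["G1"] * 3 + ["G1/S"] + ["S/G2/M"] * 4

    def test_hysteresis_merges_chatter(self):
        red = [1.0] * 6 + [0.1] + [1.0] * 6  # one-frame dropout
        f = frames_from(red, [0.0] * 13)
        assert (call_phase_track(f, min_run=2) == "G1").all()

    def test_dead_is_absorbing(self):
        alive = [True] * 5 + [False] * 5
        f = frames_from([1.0] * 10, [0.0] * 10, alive=alive)
        called = call_phase_track(f)
        assert list(called[5:]) == ["DEAD"] * 5

    def test_missing_columns_raise(self):
        with pytest.raises(FormatError, match="columns"):
            call_phase_track(pd.DataFrame({"time_min": [0, 30]}))

    def test_cohort_frame_agreement(self, mixed_cohorts):
        """At default trace noise, frame-level phase agreement with the
        generator truth is at least 99%."""
        agree = total = 0
        for tracks in mixed_cohorts.values():
            for t in tracks:
                called = call_phase_track(t)
                agree += int((called == t.truth_phases).sum())
                total += len(called)
        assert agree / total >= 0.99


class TestDivisionEvents:
    def test_annotated_events_take_precedence(self):
        f = frames_from([1.0] * 20, [0.0] * 20)
        events = [("NEBD", 600.0), ("ANAPHASE", 630.0),
                  ("NEBD", 1800.0), ("ANAPHASE", 1830.0)]
        pairs = detect_division_events((f, events))
        assert pairs == [(600.0, 630.0), (1800.0, 1830.0)]

    def test_orphan_anaphase_dropped(self):
        f = frames_from([1.0] * 5, [0.0] * 5)
        pairs = detect_division_events((f, [("ANAPHASE", 900.0)]))
        assert pairs == []

    def test_proxy_mode_recovers_divisions(self, allocations):
        """Without annotations the area-drop proxy finds division times
        within one frame of the truth."""
        tracks = make_fucci_cohort(
            allocations["palbo_G1S"], n=50, noise_sd=0.0, seed=7
        )
        for t in tracks:
            truth_anas = [tm for n, tm in t.events if n == "ANAPHASE"]
            pairs = detect_division_events((t.frames, []))
            assert len(pairs) == len(truth_anas)
            for (nebd, ana), tru in zip(pairs, truth_anas):
                assert abs(ana - tru) <= 30.0 + 1e-6

    def test_no_events(self):
        f = frames_from([1.0] * 5, [0.0] * 5)
        assert detect_division_events((f, [])) == []


class TestLengths:
    def test_mitotic_length(self):
        assert mitotic_length((600.0, 630.0)) == 30.0

    def test_interphase_length(self):
        assert interphase_length((600.0, 630.0), (1890.0, 1920.0)) == 1260.0

    def test_out_of_order_raises(self):
        with pytest.raises(ConfigurationError):
            mitotic_length((630.0, 600.0))

    def test_cohort_mean_mitotic_length(self):
        """A generator configured with 45 min mitoses yields a cohort mean
        within 2 min of 45."""
        params = CellCycleParams(mitotic_length_minutes=45.0)
        alloc = FateAllocation("untreated", {"PROLIF": 60})
        tracks = make_fucci_cohort(alloc, params=params, n=60, seed=13)
        lengths = []
        for t in tracks:
            for pair in detect_division_events(t):
                lengths.append(mitotic_length(pair))
        assert abs(np.mean(lengths) - 45.0) <= 2.0


class TestClassifyFate:
    def test_three_anaphases_is_prolif(self):
        f = frames_from([1.0] * 20, [0.0] * 20)
        events = []
        for k in range(3):
            events += [("NEBD", 300.0 + 400 * k), ("ANAPHASE", 330.0 + 400 * k)]
        call = classify_fate((f, events))
        assert call.fate == "PROLIF" and call.n_divisions == 3

    def test_long_green_then_red_is_g2_exit(self):
        n_green = 44  # 22 h of green
        red = [0.02] * n_green + [1.0] * 40
        green = [1.0] * n_green + [0.02] * 40
        call = classify_fate((frames_from(red, green), []))
        assert call.fate == "G2_EXIT"

    def test_short_green_then_red_is_g1_abm(self):
        red = [0.02] * 10 + [1.0] * 60
        green = [1.0] * 10 + [0.02] * 60
        call = classify_fate((frames_from(red, green), []))
        assert call.fate == "G1_ABM"

    def test_terminal_green_is_sg2_arrest(self):
        red = [1.0] * 20 + [0.02] * 80
        green = [0.02] * 20 + [1.0] * 80
        call = classify_fate((frames_from(red, green), []))
        assert call.fate == "SG2_ARREST"

    def test_death_outranks_divisions(self):
        alive = [True] * 50 + [False] * 30
        f = frames_from([1.0] * 80, [0.0] * 80, alive=alive)
        events = [("NEBD", 300.0), ("ANAPHASE", 330.0), ("DEATH", 1500.0)]
        assert classify_fate((f, events)).fate == "DAM"
        events0 = [("DEATH", 1500.0)]
        assert classify_fate((f, events0)).fate == "DBM"

    def test_all_gap_unclassifiable(self):
        f = frames_from([0.01] * 20, [0.01] * 20)
        assert classify_fate((f, [])).fate == "UNCLASSIFIABLE"

    def test_g2_exit_threshold_monotonicity(self, g1_cohort):
        """Lowering the G2-exit green-duration threshold never decreases
        the number of G2-exit calls."""
        counts = []
        for thr in (30.0, 20.0, 10.0):
            calls = [classify_fate(t, g2_exit_min_green_hours=thr)
                     for t in g1_cohort]
            counts.append(sum(c.fate == "G2_EXIT" for c in calls))
        assert counts == sorted(counts)

    def test_classifier_recovery_500_tracks(self, allocations):
        """On 500 synthetic tracks at default noise, fate labels are at
        least 98% accurate and division counts are exact."""
        total = correct = 0
        div_exact = True
        for name, alloc in allocations.items():
            for rep in range(2):
                tracks = make_fucci_cohort(alloc, n=50, seed=100 + rep)
                for t in tracks:
                    call = classify_fate(t)
                    correct += int(call.fate == t.truth_fate)
                    div_exact &= call.n_divisions == t.n_divisions_truth
                    total += 1
        extra = make_fucci_cohort(
            FateAllocation("untreated", {"PROLIF": 100}), n=100, seed=9
        )
        for t in extra:
            call = classify_fate(t)
            correct += int(call.fate == t.truth_fate)
            div_exact &= call.n_divisions == t.n_divisions_truth
            total += 1
        assert total == 500
        assert correct / total >= 0.98
        assert div_exact


class TestExposureLabels:
    @pytest.mark.parametrize(
        "protocol,offset,expected",
        [
            ("palbo_release", 0.0, "G1"),
            ("palbo_release", 6.0, "G1/S"),
            ("thy_release", -2.0, "G1/S"),
            ("thy_release", 4.0, "lateS"),
            ("thy_release", 10.0, "G2/M"),
        ],
    )
    def test_mapping(self, protocol, offset, expected):
        assert label_exposure_phase(protocol, offset) == expected

    def test_out_of_range_offset(self):
        with pytest.raises(ConfigurationError, match="range"):
            label_exposure_phase("palbo_release", 20.0)

    def test_unknown_protocol(self):
        with pytest.raises(ConfigurationError, match="protocol"):
            label_exposure_phase("nocodazole", 0.0)


class TestAggregation:
    def test_all_prolif_fraction_one(self):
        from pulsefate.fates import FateCall

        calls = [FateCall("PROLIF", 2) for _ in range(50)]
        table, div = aggregate_cohort(calls)
        assert table["fraction"].iloc[0] == 1.0
        assert div.set_index("divisions").loc["2", "count"] == 50

    def test_prolif_fraction_equals_multidivision_fraction(self, mixed_cohorts):
        """Definitional identity: the PROLIF fraction equals the fraction
        of tracks with two or more divisions."""
        for tracks in mixed_cohorts.values():
            calls = [classify_fate(t) for t in tracks]
            table, _ = aggregate_cohort(calls)
            prolif = table.loc[table["fate"] == "PROLIF", "fraction"].sum()
            multi = np.mean([c.n_divisions >= 2 for c in calls])
            assert prolif == pytest.approx(multi)

    def test_fractions_sum_to_one(self, mixed_cohorts):
        for tracks in mixed_cohorts.values():
            calls = [classify_fate(t) for t in tracks]
            table, _ = aggregate_cohort(calls)
            assert table["fraction"].sum() == pytest.approx(1.0)


class TestPhaseFractions:
    def test_all_g1_snapshot(self):
        df = phase_fractions({0.0: ["G1"] * 150})
        row = df.iloc[0]
        assert (row.frac_red, row.frac_yellow, row.frac_green) == (1.0, 0.0, 0.0)

    def test_gap_counts_as_red(self):
        labels = ["G1"] * 100 + ["GAP"] * 20 + ["S/G2/M"] * 80
        df = phase_fractions({0.0: labels})
        assert df.iloc[0].frac_red == pytest.approx(120 / 200)

    def test_small_snapshot_rejected(self):
        with pytest.raises(ConfigurationError):
            phase_fractions({0.0: ["G1"] * 10})
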