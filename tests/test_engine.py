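"""Re-execution engine: snapshots, interim decisions, full replay, patient
CSV round-trips and the model/results front."""

import numpy as np
import pandas as pd
import pytest

from seqtrial import (
    DesignSpec,
    Interim,
    ScenarioSpec,
    SequentialTrial,
    generate_stream,
    get_design,
    interim_decision,
    load_patients,
    reexecute,
    save_patients,
    snapshot_at,
)
from seqtrial.datasets import oscar_fixture, oscar_snapshots
from seqtrial.engine import PatientDataError, TruncatedStreamError

SCENARIO = ScenarioSpec(0.45, 0.36, label="unit test")


def _tiny_design(**kw):
    defaults = dict(
        name="tiny",
        n_max=60,
        interims=(Interim(20, None, 0.05), Interim(40, 0.99, 0.10)),
        final_threshold=0.9,
    )
    defaults.update(kw)
    return DesignSpec(**defaults)


class TestPatientCSV:
    def test_round_trip_is_lossless(self, tmp_path):
        df = generate_stream(SCENARIO, 200, seed=3)
        path = tmp_path / "patients.csv"
        save_patients(df, path)
        back = load_patients(path)
        pd.testing.assert_frame_equal(df, back)

    @pytest.mark.parametrize(
        "row, message",
        [
            ("P2,placebo,1.0,0", "line 3: arm"),
            ("P2,control,-1.0,0", "line 3: recruit_week"),
            ("P2,control,1.0,2", "line 3: outcome"),
        ],
    )
    def test_malformed_rows_name_their_line(self, tmp_path, row, message):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,arm,recruit_week,outcome\nP1,control,0.5,1\n" + row + "\n"
        )
        with pytest.raises(PatientDataError, match=message):
            load_patients(path)

    def test_unsorted_stream_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,arm,recruit_week,outcome\n"
            "P1,control,5.0,1\nP2,treatment,4.0,0\n"
        )
        with pytest.raises(PatientDataError, match="non-decreasing"):
            load_patients(path)


class TestSnapshot:
    def test_follow_up_lag_and_missingness(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3", "P4"],
                "arm": ["control", "treatment", "control", "treatment"],
                "recruit_week": [0.0, 1.0, 4.0, 9.0],
                "outcome": [1.0, np.nan, 0.0, 1.0],
            }
        )
        # trigger at the 4th patient (week 9): P1 and P3 have 30 days of
        # follow-up elapsed, P2 would have but is a dropout, P4 triggers
        snap = snapshot_at(df, 4)
        assert (snap.randomised_control, snap.randomised_treatment) == (2, 2)
        assert (snap.complete_control, snap.complete_treatment) == (2, 0)
        assert (snap.deaths_control, snap.deaths_treatment) == (1, 0)

    def test_trigger_beyond_stream_rejected(self):
        df = generate_stream(SCENARIO, 10, seed=0)
        with pytest.raises(ValueError):
            snapshot_at(df, 11)


class TestInterimDecision:
    def test_clear_futility_is_stopped(self):
        # second look of the two-look 335/670 design on its published
        # snapshot: P_max is far below the 0.1 boundary
        design = get_design("Design 3")
        snap = oscar_snapshots("Design 3")[1]
        dec = interim_decision(snap, design, 1, n_draws=4000, seed=1)
        assert dec.action == "stop_futility"
        assert dec.p_max < 0.05

    def test_clear_continue_at_first_look(self):
        design = get_design("Design 2")
        snap = oscar_snapshots("Design 2")[0]
        dec = interim_decision(snap, design, 0, n_draws=4000, seed=1)
        assert dec.action == "continue"
        assert dec.p_curr is None  # success stopping not allowed at this look
        assert dec.p_max > 0.1

    def test_unreachable_boundaries_always_continue(self):
        design = get_design("Design 5").with_thresholds(success=1.0, futility=0.0)
        snap = oscar_snapshots("Design 5")[0]
        dec = interim_decision(snap, design, 0, n_draws=1000, seed=1)
        assert dec.action == "continue"

    def test_snapshot_schedule_mismatch_rejected(self):
        design = get_design("Design 3")
        snap = oscar_snapshots("Design 3")[1]  # 670 randomised
        with pytest.raises(ValueError, match="trigger"):
            interim_decision(snap, design, 0, n_draws=100, seed=1)


class TestReexecute:
    def test_published_two_look_replay(self):
        fx = oscar_fixture("Design 3", seed=0)
        report = reexecute(fx, get_design("Design 3"), n_draws=4000, seed=7)
        assert report.stopped_at == 1
        assert report.stop_reason == "futility_stop"
        assert report.n_randomised == 670
        assert (report.counts_control.deaths, report.counts_control.analysed) == (138, 339)
        assert (report.counts_treatment.deaths, report.counts_treatment.analysed) == (134, 331)
        assert report.deaths_total == 272
        assert 0.52 <= report.final_prob_superior <= 0.53
        assert round(report.final_rr.rr, 2) == 0.99
        assert not report.successful
        assert report.savings_vs_n_max == 336

    def test_symmetric_stream_runs_to_n_max_with_even_posterior(self):
        design = _tiny_design(interims=(Interim(20, 1.0, 0.0), Interim(40, 1.0, 0.0)))
        n = design.n_max
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "arm": ["control", "treatment"] * (n // 2),
                # identical outcome pattern in both arms
                "recruit_week": np.arange(n) / 5.5,
                "outcome": [1.0, 1.0, 0.0, 0.0] * (n // 4),
            }
        )
        report = reexecute(df, design, n_draws=500, seed=0)
        assert all(d.action == "continue" for d in report.decisions)
        assert report.n_randomised == n
        assert report.final_prob_superior == pytest.approx(0.5, abs=1e-9)

    def test_unreachable_boundaries_reduce_to_fixed_design(self):
        stream = generate_stream(SCENARIO, 60, seed=9)
        fixed = _tiny_design(name="fixed", interims=())
        unreachable = _tiny_design(interims=(Interim(20, 1.0, 0.0), Interim(40, 1.0, 0.0)))
        rep_fixed = reexecute(stream, fixed, n_draws=500, seed=5)
        rep_seq = reexecute(stream, unreachable, n_draws=500, seed=5)
        assert rep_seq.counts_control == rep_fixed.counts_control
        assert rep_seq.counts_treatment == rep_fixed.counts_treatment
        assert rep_seq.final_prob_superior == rep_fixed.final_prob_superior
        assert rep_seq.n_randomised == rep_fixed.n_randomised
        assert rep_seq.accrual_duration_weeks == rep_fixed.accrual_duration_weeks

    def test_short_stream_without_stop_reports_truncation(self):
        stream = generate_stream(SCENARIO, 50, seed=2)
        design = _tiny_design(interims=(Interim(20, 1.0, 0.0),))
        with pytest.raises(TruncatedStreamError):
            reexecute(stream, design, n_draws=200, seed=0)
        report = reexecute(stream, design, n_draws=200, seed=0, allow_truncation=True)
        assert report.truncated
        assert report.n_randomised == 50

    def test_decision_trail_deterministic_given_seed(self):
        fx = oscar_fixture("Design 5", seed=1)
        design = get_design("Design 5")
        a = reexecute(fx, design, n_draws=2000, seed=3)
        b = reexecute(fx, design, n_draws=2000, seed=3)
        assert a == b


class TestModelFront:
    def test_fit_from_csv_and_summary(self, tmp_path):
        fx = oscar_fixture("Design 3", seed=0)
        path = tmp_path / "patients.csv"
        save_patients(fx, path)
        model = SequentialTrial.from_csv(path, get_design("Design 3"))
        results = model.fit(seed=7, n_draws=4000)
        text = results.summary()
        assert "Stop for futility" in text
        assert "138/339" in text and "134/331" in text
        assert "0.99" in text  # relative risk to 2 dp
        assert results.n_randomised == 670
        frame = results.interim_frame()
        assert list(frame["interim"]) == [1, 2]
        assert frame["decision"].iloc[-1] == "stop_futility"
        final = results.final_dict()
        assert final["deaths_total"] == 272
        assert final["savings_vs_n_max"] == 336

    def test_fixed_design_has_no_interim_rows(self):
        stream = generate_stream(SCENARIO, 60, seed=4)
        model = SequentialTrial(stream, _tiny_design(name="fixed", interims=()))
        results = model.fit(seed=0, n_draws=100)
        assert results.interim_frame().empty
        assert "fixed design" in results.summary()
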