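import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import emascale as e
from emascale.core import ResponseScale


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, scale, expected",
        [
            (1, ResponseScale.LIKERT7, 0.0),
            (7, ResponseScale.LIKERT7, 1.0),
            (4, ResponseScale.LIKERT7, 0.5),
            (0, ResponseScale.VAS101, 0.0),
            (50, ResponseScale.VAS101, 0.5),
            (100, ResponseScale.VAS101, 1.0),
        ],
    )
    def test_examples(self, raw, scale, expected):
        assert e.normalize_response(raw, scale) == pytest.approx(expected)

    @pytest.mark.parametrize("raw, scale", [(0, ResponseScale.LIKERT7), (8, ResponseScale.LIKERT7), (-1, ResponseScale.VAS101), (101, ResponseScale.VAS101)])
    def test_out_of_range_rejected(self, raw, scale):
        with pytest.raises(ValueError):
            e.normalize_response(raw, scale)

    @given(st.integers(1, 6))
    def test_strictly_increasing_likert(self, raw):
        assert e.normalize_response(raw + 1, ResponseScale.LIKERT7) > e.normalize_response(raw, ResponseScale.LIKERT7)

    @given(st.integers(0, 99))
    def test_strictly_increasing_vas(self, raw):
        assert e.normalize_response(raw + 1, ResponseScale.VAS101) > e.normalize_response(raw, ResponseScale.VAS101)


def _toy_study(beeps_per_participant):
    """Build a study where participant pX observes the given beep numbers."""
    rows = []
    for pid, beeps in beeps_per_participant.items():
        for b in beeps:
            for item in [it.name for it in e.DEFAULT_ITEMS]:
                rows.append((pid, "likert", item, b, 3, 2 / 6, np.nan))
    rec = pd.DataFrame(rows, columns=["participant_id", "group", "item", "beep", "value", "value_norm", "duration_s"])
    return e.StudyDataset(rec)


class TestInclusion:
    def test_threshold_is_at_least_20(self):
        ds = _toy_study({"p19": range(1, 20), "p20": range(1, 21)})
        out = e.apply_inclusion(ds)
        assert out.participants() == ["p20"]

    def test_idempotent(self, small_study):
        once = e.apply_inclusion(small_study)
        twice = e.apply_inclusion(once)
        assert once.participants() == twice.participants()
        assert once.lag_eligible == twice.lag_eligible

    def test_empty_input_gives_empty_output(self):
        ds = e.StudyDataset(pd.DataFrame(columns=["participant_id", "group", "item", "beep", "value", "value_norm", "duration_s"]))
        out = e.apply_inclusion(ds)
        assert out.records.empty

    def test_lag_eligibility_needs_consecutive_pairs_not_just_counts(self):
        # 20 observed beeps pass inclusion, but the (1,2), (5,6), ... layout
        # yields only 10 valid consecutive pairs -> lag statistics ineligible
        ds = _toy_study({"gappy": list(range(1, 41, 4)) + list(range(2, 42, 4))})
        out = e.apply_inclusion(ds)
        assert out.participants() == ["gappy"]
        assert out.lag_eligible["gappy"] is False

    def test_lag_ineligible_when_no_pairs(self):
        # every other beep: 42 observations but zero valid consecutive pairs
        ds = _toy_study({"alt": range(1, 84, 2)})
        out = e.apply_inclusion(ds)
        assert out.lag_eligible["alt"] is False


class TestCareless:
    def _study_with_rows(self, rows):
        rec = pd.DataFrame(rows, columns=["participant_id", "group", "item", "beep", "value", "value_norm", "duration_s"])
        return e.StudyDataset(rec)

    def test_constant_beeps_flagged(self):
        rows = [("p1", "vas", it.name, b, 40, 0.4, np.nan) for b in range(1, 30) for it in e.DEFAULT_ITEMS]
        flags = e.detect_careless(self._study_with_rows(rows))
        assert flags["p1"]

    def test_any_varying_beep_unflags_at_default_threshold(self):
        rows = [("p1", "vas", it.name, b, 40, 0.4, np.nan) for b in range(1, 30) for it in e.DEFAULT_ITEMS]
        rows[0] = ("p1", "vas", rows[0][2], 1, 80, 0.8, np.nan)
        flags = e.detect_careless(self._study_with_rows(rows))
        assert not flags["p1"]

    def test_single_completed_constant_beep_flagged(self):
        rows = [("p1", "vas", it.name, 1, 40, 0.4, np.nan) for it in e.DEFAULT_ITEMS]
        flags = e.detect_careless(self._study_with_rows(rows))
        assert flags["p1"]

    def test_no_completed_beeps_not_flagged(self):
        rows = [("p1", "vas", "Happy", 1, 40, 0.4, np.nan)]  # only 1 of 14 items
        flags = e.detect_careless(self._study_with_rows(rows))
        assert not flags["p1"]


class TestIO:
    def test_round_trip(self, small_study, tmp_path):
        path = tmp_path / "study.csv"
        crit = tmp_path / "criteria.csv"
        e.write_study(small_study, path, crit)
        back, errors = e.read_study(path, crit)
        assert errors.empty
        a = small_study.records.sort_values(["participant_id", "item", "beep"]).reset_index(drop=True)
        b = back.records.sort_values(["participant_id", "item", "beep"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
        pd.testing.assert_frame_equal(
            small_study.criteria.sort_index(), back.criteria.sort_index(), check_dtype=False
        )

    def test_malformed_rows_collected_not_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,group,item,beep,value\n"
            "p1,likert,Happy,1,3\n"
            "p1,likert,Happy,2,8\n"  # Likert out of range
            "p1,likert,Happy,90,3\n"  # beep out of range
            "p2,sometscale,Happy,1,3\n"  # unknown group
            "p1,likert,NotAnItem,3,3\n"
        )
        ds, errors = e.read_study(path)
        assert len(ds.records) == 1
        assert len(errors) == 4

    def test_values_normalized_on_load(self, tmp_path):
        path = tmp_path / "ok.csv"
        path.write_text("participant_id,group,item,beep,value\np1,vas,Happy,1,50\n")
        ds, _ = e.read_study(path)
        assert ds.records["value_norm"].iloc[0] == pytest.approx(0.5)


def test_default_item_catalogue_valence_split():
    vals = [it.valence for it in e.DEFAULT_ITEMS]
    assert len(e.DEFAULT_ITEMS) == 14
    assert vals.count("positive") == 5 and vals.count("negative") == 9
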