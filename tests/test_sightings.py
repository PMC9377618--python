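import numpy as np
import pandas as pd
import pytest

from socpod.sightings import (
    CaptureHistoryTable,
    SchemaError,
    build_capture_histories,
    build_sampling_periods,
    filter_usable,
    histories_from_session_counts,
    read_sightings,
    unique_by_inclusion_exclusion,
    write_sightings,
)

from conftest import make_sightings


CSV_HEADER = (
    "individual_id,date,group_id,session,habitat,stratum,"
    "mark_type,photo_quality,distinctiveness\n"
)


def write_csv(tmp_path, body, name="s.csv"):
    p = tmp_path / name
    p.write_text(CSV_HEADER + body)
    return p


class TestReadSightings:
    def test_well_formed_rows_become_records(self, tmp_path):
        p = write_csv(
            tmp_path,
            "A,2018-01-08,g1,1,estuary,SNCESS,LTM,good,distinctive\n"
            "B,2018-01-08,g1,1,coast,NNCESS,STM,fair,slightly\n"
            "A,2018-01-09,g2,1,estuary,mixed,LTM,excellent,very\n",
        )
        df = read_sightings(p)
        assert len(df) == 3
        assert df["date"].iloc[0].isoformat() == "2018-01-08"

    def test_duplicate_rows_collapse_with_warning(self, tmp_path):
        p = write_csv(
            tmp_path,
            "A,2018-01-08,g1,1,estuary,SNCESS,LTM,good,distinctive\n"
            "A,2018-01-08,g1,1,estuary,SNCESS,LTM,good,distinctive\n",
        )
        with pytest.warns(UserWarning, match="duplicate"):
            df = read_sightings(p)
        assert len(df) == 1

    def test_invalid_date_names_the_row(self, tmp_path):
        p = write_csv(
            tmp_path,
            "A,2018-01-08,g1,,,,,,\n"
            "B,13/45/2018,g1,,,,,,\n",
        )
        with pytest.raises(ValueError, match=r"13/45/2018.*row"):
            read_sightings(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("individual_id,date\nA,2018-01-08\n")
        with pytest.raises(SchemaError, match="group_id"):
            read_sightings(p)

    def test_enum_violation_is_schema_error(self, tmp_path):
        p = write_csv(tmp_path, "A,2018-01-08,g1,,swamp,,,,\n")
        with pytest.raises(SchemaError, match="habitat"):
            read_sightings(p)

    def test_round_trip_is_lossless(self, tmp_path):
        df = make_sightings(
            [
                {"individual_id": "A", "date": "2018-01-08", "group_id": "g1", "session": 1},
                {"individual_id": "B", "date": "2018-01-09", "group_id": "g2",
                 "mark_type": "STM", "photo_quality": "fair"},
            ]
        )
        out = tmp_path / "rt.csv"
        write_sightings(df, out)
        back = read_sightings(out)
        pd.testing.assert_frame_equal(back, df.astype(back.dtypes))


class TestFilterUsable:
    def test_poor_quality_excluded(self):
        df = make_sightings(
            [{"individual_id": c, "date": "2018-01-08", "group_id": "g1",
              "photo_quality": q}
             for c, q in zip("ABCDE", ["poor", "good", "fair", "poor", "excellent"])]
        )
        assert len(filter_usable(df)) == 3

    def test_ltm_only_restriction(self):
        df = make_sightings(
            [{"individual_id": c, "date": "2018-01-08", "group_id": "g1",
              "mark_type": m, "photo_quality": "fair"}
             for c, m in zip("ABCDE", ["LTM", "STM", "LTM", "STM", "LTM"])]
        )
        assert len(filter_usable(df, ltm_only=True)) == 3

    def test_idempotent(self):
        df = make_sightings(
            [{"individual_id": "A", "date": "2018-01-08", "group_id": "g1",
              "photo_quality": "poor"},
             {"individual_id": "B", "date": "2018-01-08", "group_id": "g1"}]
        )
        once = filter_usable(df)
        twice = filter_usable(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSamplingPeriods:
    def test_daily_group_membership(self):
        df = make_sightings(
            [("A", "2018-01-01", "g1"), ("B", "2018-01-01", "g1"),
             ("A", "2018-01-02", "g2")]
        )
        periods = build_sampling_periods(df)
        assert periods.n_periods == 2
        assert [periods.ids[i] for i in periods.groups[0][0]] == ["A", "B"]
        assert [periods.ids[i] for i in periods.groups[1][0]] == ["A"]

    def test_same_group_resight_counted_once(self):
        # two photos of A in g1 on one day appear as one membership
        df = make_sightings(
            [("A", "2018-01-01", "g1"), ("A", "2018-01-01", "g1"),
             ("B", "2018-01-01", "g1")]
        )
        periods = build_sampling_periods(df)
        assert len(periods.groups[0]) == 1
        assert periods.groups[0][0].tolist() == [0, 1]

    def test_two_groups_same_day_member_of_both(self):
        df = make_sightings(
            [("A", "2018-01-01", "g1"), ("B", "2018-01-01", "g1"),
             ("A", "2018-01-01", "g2"), ("C", "2018-01-01", "g2")]
        )
        periods = build_sampling_periods(df)
        memberships = [sorted(periods.ids[i] for i in g) for g in periods.groups[0]]
        assert ["A", "B"] in memberships and ["A", "C"] in memberships
        # both dyads score as associated in this period
        from socpod.association import dyad_tallies

        t = dyad_tallies(periods)
        a, b, c = (periods.ids.index(k) for k in "ABC")
        assert t.x[a, b] == 1 and t.x[a, c] == 1 and t.x[b, c] == 0
        assert t.yab[b, c] == 1


class TestCaptureHistories:
    def test_repeat_within_session_pools_to_one(self):
        df = make_sightings(
            [{"individual_id": "A", "date": "2018-01-08", "group_id": "g1", "session": 1},
             {"individual_id": "A", "date": "2018-01-09", "group_id": "g2", "session": 1},
             {"individual_id": "B", "date": "2018-01-16", "group_id": "g3", "session": 2},
             {"individual_id": "B", "date": "2018-01-23", "group_id": "g4", "session": 3}]
        )
        table = build_capture_histories(df)
        assert table.histories.tolist() == [[1, 0, 0], [0, 1, 1]]

    def test_session_assignment_from_date_ranges(self):
        df = make_sightings([("A", "2018-01-08", "g1"), ("B", "2018-01-16", "g2")])
        table = build_capture_histories(
            df, sessions={1: ("2018-01-08", "2018-01-11"), 2: ("2018-01-15", "2018-01-19")}
        )
        assert table.n_t.tolist() == [1, 1]

    def test_unassigned_record_raises(self):
        df = make_sightings([("A", "2018-02-01", "g1")])
        with pytest.raises(ValueError, match="no session"):
            build_capture_histories(df, sessions={1: ("2018-01-08", "2018-01-11")})

    def test_column_sums_and_total_match_inclusion_exclusion(self):
        table = histories_from_session_counts((269, 141, 174), (41, 42, 46), 21)
        assert table.n_t.tolist() == [269, 141, 174]
        assert table.n_individuals == unique_by_inclusion_exclusion(
            (269, 141, 174), (41, 42, 46), 21
        )
        assert table.frequencies == {
            "111": 21, "110": 20, "101": 25, "011": 21,
            "100": 203, "010": 79, "001": 107,
        }
        assert table.pairwise_overlaps() == {(0, 1): 41, (0, 2): 46, (1, 2): 42}
        assert table.triple_overlap() == 21

    def test_all_zero_history_rejected(self):
        with pytest.raises(ValueError, match="no detection"):
            CaptureHistoryTable(ids=["a"], histories=np.array([[0, 0, 0]]))


class TestInclusionExclusion:
    @pytest.mark.parametrize(
        "n_t,pairwise,triple,expected",
        [
            ((1, 0, 0), (0, 0, 0), 0, 1),
            ((187, 102, 126), (28, 30, 36), 16, 337),
            ((269, 141, 174), (41, 42, 46), 21, 476),
            ((316, 170, 190), (49, 52, 49), 21, 547),
        ],
    )
    def test_unique_totals(self, n_t, pairwise, triple, expected):
        assert unique_by_inclusion_exclusion(n_t, pairwise, triple) == expected

    def test_inconsistent_overlaps_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            unique_by_inclusion_exclusion((10, 10, 10), (12, 2, 2), 1)
        with pytest.raises(ValueError, match="inconsistent"):
            unique_by_inclusion_exclusion((10, 10, 10), (2, 2, 2), 5)

    def test_reconstruction_agrees_for_random_populations(self):
        # 3-session histories simulated directly, summarized, reconstructed
        rng = np.random.default_rng(7)
        for _ in range(20):
            hist = (rng.random((60, 3)) < 0.4).astype(int)
            hist = hist[hist.sum(axis=1) > 0]
            table = CaptureHistoryTable(
                ids=[str(i) for i in range(len(hist))], histories=hist
            )
            ov = table.pairwise_overlaps()
            rebuilt = histories_from_session_counts(
                table.n_t, (ov[(0, 1)], ov[(1, 2)], ov[(0, 2)]), table.triple_overlap()
            )
            assert rebuilt.frequencies == table.frequencies
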