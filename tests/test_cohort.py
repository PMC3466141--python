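import pytest

from matchqual.cohort import (
    CohortTable,
    build_matched_sets,
    derive_smoking_duration,
    read_cohort,
)
from matchqual.errors import DataError, LinkageError, RowValidationError, SchemaError
from matchqual.varspec import default_varspecs

from conftest import make_participant

HEADER = (
    "subject_id,group,survivor_link,sex,race,age,education,employment,"
    "days_smoked_30,age_first_cig,age_last_cig,is_current_smoker,"
    "alc_freq_month,alc_typical,alc_six_freq,cancer_history"
)


def write_csv(tmp_path, rows, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
    return path


ROW_S = "S1,survivor,S1,male,white,64,post-HS,retired,0,18,50,false,1.5,0.7,0.5,true"
ROW_P = "P1,peer,S1,male,white,60,post-HS,retired,0,,,false,1.0,0.5,0.2,false"
ROW_L = "L1,listed,S1,male,white,66,HS-grad,employed,0,,,false,2.0,1.0,0.8,false"


@pytest.mark.parametrize(
    "first,last,age,current,expected",
    [
        (18, 50, 64, False, 32),       # former smoker: last minus first
        (20, None, 60, True, 40),      # current smoker: current age stands in
        (None, None, 70, False, None), # never-smoker
        (25, None, 70, False, None),   # former smoker, quit age unknown
    ],
)
def test_smoking_duration_rule(first, last, age, current, expected):
    assert derive_smoking_duration(first, last, age, current) == expected


def test_smoking_duration_negative_is_data_error():
    with pytest.raises(DataError):
        derive_smoking_duration(30, 20, 64, False)


class TestReadCohort:
    def test_minimal_three_row_file(self, tmp_path):
        cohort = read_cohort(write_csv(tmp_path, [ROW_S, ROW_P, ROW_L]))
        assert len(cohort) == 3
        assert len(cohort.matched_sets) == 1
        mset = cohort.matched_sets[0]
        assert mset.peer_ids == ("P1",) and mset.listed_id == "L1"

    def test_ineligible_comparison_row_excluded_and_logged(self, tmp_path):
        bad_peer = ROW_P.replace("0.2,false", "0.2,true")
        cohort = read_cohort(write_csv(tmp_path, [ROW_S, bad_peer, ROW_L]))
        assert "P1" not in cohort.participants
        assert len(cohort.exclusions) == 1
        assert cohort.exclusions[0]["subject_id"] == "P1"
        assert "cancer" in cohort.exclusions[0]["reason"]

    def test_dangling_link_names_offender(self, tmp_path):
        orphan = ROW_L.replace("L1,listed,S1", "L1,listed,S999")
        with pytest.raises(LinkageError, match="L1"):
            read_cohort(write_csv(tmp_path, [ROW_S, orphan]))

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,group\nS1,survivor\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="survivor_link"):
            read_cohort(path)

    def test_unparseable_numeric_reports_row_index(self, tmp_path):
        bad = ROW_P.replace("60,post-HS", "sixty,post-HS")
        with pytest.raises(RowValidationError) as exc:
            read_cohort(write_csv(tmp_path, [ROW_S, bad]))
        assert exc.value.rows[0][0] == 1  # second row
        assert exc.value.rows[0][1] == "age"

    def test_round_trip_is_field_identical(self, tmp_path):
        cohort = read_cohort(write_csv(tmp_path, [ROW_S, ROW_P, ROW_L]))
        out = tmp_path / "again.csv"
        cohort.write_csv(out)
        again = read_cohort(out, default_varspecs())
        assert set(again.participants) == set(cohort.participants)
        for sid, p in cohort.participants.items():
            assert again.participants[sid] == p
        assert again.matched_sets == cohort.matched_sets


class TestBuildMatchedSets:
    def test_unequal_peer_allocation(self):
        parts = [
            make_participant("A", "survivor"),
            make_participant("B", "survivor"),
            make_participant("P", "peer", "A"),
        ]
        sets = {s.survivor_id: s for s in build_matched_sets(parts)}
        assert sets["A"].peer_ids == ("P",)
        assert sets["B"].peer_ids == ()

    def test_cardinality_violations_name_survivor(self):
        parts = [make_participant("A", "survivor")]
        parts += [make_participant(f"P{i}", "peer", "A") for i in range(3)]
        with pytest.raises(LinkageError, match="A"):
            build_matched_sets(parts)
        parts = [make_participant("A", "survivor")]
        parts += [make_participant(f"L{i}", "listed", "A") for i in range(2)]
        with pytest.raises(LinkageError, match="A"):
            build_matched_sets(parts)

    def test_empty_input_yields_empty_output(self):
        assert build_matched_sets([]) == []

    def test_order_independent(self):
        parts = [
            make_participant("S2", "survivor"),
            make_participant("S1", "survivor"),
            make_participant("P2", "peer", "S1"),
            make_participant("P1", "peer", "S1"),
            make_participant("L1", "listed", "S2"),
        ]
        forward = build_matched_sets(parts)
        backward = build_matched_sets(list(reversed(parts)))
        assert forward == backward
        assert forward[0].survivor_id == "S1"
        assert forward[0].peer_ids == ("P1", "P2")


def test_duplicate_subject_id_rejected():
    parts = [make_participant("A", "survivor"), make_participant("A", "survivor")]
    with pytest.raises(SchemaError, match="duplicate"):
        CohortTable.from_participants(parts)


def test_eligibility_invariant_after_read(tmp_path):
    rows = [ROW_S, ROW_P, ROW_L, ROW_L.replace("L1,listed,S1", "X,listed,S1").replace("0.8,false", "0.8,true")]
    cohort = read_cohort(write_csv(tmp_path, rows))
    assert all(
        p.cancer_history is not True
        for p in cohort.participants.values()
        if p.group != "survivor"
    )
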