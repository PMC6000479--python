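"""Domain types, battery definition, and serialization round-trips."""

import json

import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from acsnorms import (
    Demographics,
    Direction,
    MeasureSpec,
    NormModel,
    ParseError,
    SchemaVersionError,
    ScoreTable,
    Transform,
    ValidationError,
    default_acs_battery,
    default_acs_norm_models,
    education_from_verhage,
    read_norm_model,
    read_score_table,
    write_norm_model,
    write_score_table,
)


class TestBattery:
    def test_composition(self, battery):
        assert len(battery) == 12
        composite = {m.name for m in battery if m.in_composite}
        assert composite == {
            "ConnectTheDotsI", "ConnectTheDotsII", "WordlistLearning",
            "ReactionSpeed", "BoxTapping", "FillTheGrid",
            "WordlistDelayedRecall", "DigitSequencesI", "DigitSequencesII",
        }
        zero_invalid = {m.name for m in battery if m.zero_is_invalid}
        assert zero_invalid == {"WordlistLearning", "BoxTapping",
                               "DigitSequencesI", "DigitSequencesII"}

    @pytest.mark.parametrize("name, direction, transform", [
        ("ConnectTheDotsI", Direction.LOWER_IS_BETTER, Transform.INVERSE),
        ("ConnectTheDotsII", Direction.LOWER_IS_BETTER, Transform.LOG10),
        ("PlaceTheBeads", Direction.LOWER_IS_BETTER, Transform.SQRT),
        ("WordlistLearning", Direction.HIGHER_IS_BETTER, Transform.NONE),
    ])
    def test_directions_and_transforms(self, battery, name, direction, transform):
        spec = next(m for m in battery if m.name == name)
        assert spec.direction is direction
        assert spec.transform is transform

    def test_time_based_measures_are_mad_eligible(self, battery):
        eligible = {m.name for m in battery if m.mad_eligible}
        assert eligible == {"ConnectTheDotsI", "ConnectTheDotsII",
                            "ReactionSpeed", "FillTheGrid"}


class TestDemographics:
    @pytest.mark.parametrize("verhage, expected", [
        (1, 1), (3, 1), (5, 1), (6, 0), (7, 0)])
    def test_verhage_binary_mapping(self, verhage, expected):
        assert education_from_verhage(verhage) == expected
        d = Demographics("p", 50.0, 0, verhage=verhage)
        assert d.education_binary == expected

    def test_contradictory_education_rejected(self):
        with pytest.raises(ValidationError):
            Demographics("p", 50.0, 0, verhage=7, education_binary=1)

    @pytest.mark.parametrize("kwargs", [
        {"age": -3.0, "gender": 0},
        {"age": 50.0, "gender": 2},
        {"age": 50.0, "gender": 0, "verhage": 9},
    ])
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            Demographics("p", **kwargs)


class TestScoreTableIO:
    def test_wide_roundtrip(self, tmp_path, battery):
        csv = tmp_path / "wide.csv"
        csv.write_text(
            "participant_id,ConnectTheDotsI_1,ConnectTheDotsI_2,"
            "BoxTapping_1,BoxTapping_2\n"
            "P1,30,28,9,10\n"
            "P2,45,41,7,8\n")
        table = read_score_table(csv, battery, layout="wide")
        assert len(table) == 8
        assert table.scores("ConnectTheDotsI", 2).to_dict() == {
            "P1": 28.0, "P2": 41.0}

    def test_blank_cell_is_missing_not_zero(self, tmp_path, battery):
        csv = tmp_path / "wide.csv"
        csv.write_text("participant_id,BoxTapping_1,BoxTapping_2\nP1,,10\n")
        table = read_score_table(csv, battery, layout="wide")
        assert len(table) == 1
        assert not table.df["excluded"].any()

    def test_duplicate_rows_rejected(self, tmp_path, battery):
        csv = tmp_path / "long.csv"
        csv.write_text("participant_id,occasion,measure,raw_score\n"
                       "P1,1,ConnectTheDotsI,30\n"
                       "P1,1,ConnectTheDotsI,31\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_score_table(csv, battery, layout="long")

    def test_malformed_cell_names_location(self, tmp_path, battery):
        csv = tmp_path / "long.csv"
        csv.write_text("participant_id,occasion,measure,raw_score\n"
                       "P1,1,ConnectTheDotsI,fast\n")
        with pytest.raises(ParseError, match="raw_score"):
            read_score_table(csv, battery, layout="long")

    def test_long_roundtrip(self, tmp_path, battery, small_table):
        path = tmp_path / "scores.csv"
        write_score_table(small_table, path)
        again = read_score_table(path, battery, layout="long")
        assert again == small_table

    def test_excluded_requires_reason(self):
        df = pd.DataFrame([{"participant_id": "P1", "occasion": 1,
                            "measure": "BoxTapping", "raw_score": 5.0,
                            "excluded": True, "exclusion_reason": "none"}])
        with pytest.raises(ValidationError, match="inconsistent"):
            ScoreTable(df)

    def test_nan_scores_rejected(self):
        df = pd.DataFrame([{"participant_id": "P1", "occasion": 1,
                            "measure": "BoxTapping", "raw_score": float("nan")}])
        with pytest.raises(ValidationError, match="absent rows"):
            ScoreTable(df)


class TestNormModelIO:
    def test_published_model_roundtrip(self, tmp_path):
        model = default_acs_norm_models()["ConnectTheDotsI"]
        path = tmp_path / "ctd1.json"
        write_norm_model(model, path)
        again = read_norm_model(path)
        assert again == model
        assert again.coefficients == {"constant": -0.149, "age": -0.042,
                                      "gender": 0.401}

    def test_invalid_model_refused_on_write(self, tmp_path):
        model = default_acs_norm_models()["ConnectTheDotsI"]
        model.sd_residual = 0.0
        with pytest.raises(ValidationError, match="sd_residual"):
            write_norm_model(model, tmp_path / "bad.json")

    def test_unknown_key_warns_and_is_ignored(self, tmp_path):
        model = default_acs_norm_models()["ConnectTheDotsI"]
        data = model.to_dict()
        data["future_field"] = 42
        path = tmp_path / "extra.json"
        path.write_text(json.dumps(data))
        with pytest.warns(UserWarning, match="future_field"):
            again = read_norm_model(path)
        assert again == model

    def test_schema_version_mismatch_is_explicit(self, tmp_path):
        data = default_acs_norm_models()["ConnectTheDotsI"].to_dict()
        data["schema_version"] = 99
        path = tmp_path / "v99.json"
        path.write_text(json.dumps(data))
        with pytest.raises(SchemaVersionError):
            read_norm_model(path)

    @settings(derandomize=True, max_examples=50, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        constant=st.floats(-5, 5, allow_nan=False),
        age=st.floats(-0.5, 0.5, allow_nan=False),
        sd_residual=st.floats(0.01, 5, exclude_min=True),
        r2=st.floats(0, 1),
        ref_sd=st.one_of(st.none(), st.floats(1e-6, 100, exclude_min=True)),
    )
    def test_serialization_lossless(self, tmp_path, constant, age,
                                    sd_residual, r2, ref_sd):
        model = NormModel(
            measure="M", direction=Direction.LOWER_IS_BETTER,
            transform=Transform.INVERSE, age_center=49.19,
            coefficients={"constant": constant, "age": age},
            sd_residual=sd_residual, r_squared=r2, n_reference=100,
            ref_mean_transformed=None if ref_sd is None else 0.0304,
            ref_sd_transformed=ref_sd)
        path = tmp_path / "m.json"
        write_norm_model(model, path)
        again = read_norm_model(path)
        # JSON floats round-trip exactly (repr-based), so equality is exact
        assert again == model


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.sampled_from(["P1", "P2", "P3"]),
              st.sampled_from([1, 2]),
              st.sampled_from(["A", "B"]),
              st.floats(0.1, 100, allow_nan=False)),
    min_size=1, max_size=12))
def test_score_table_uniqueness_property(rows):
    """Any table with a repeated (participant, occasion, measure) key is
    rejected; any table without one is accepted."""
    df = pd.DataFrame(rows, columns=["participant_id", "occasion",
                                     "measure", "raw_score"])
    has_dup = df[["participant_id", "occasion", "measure"]].duplicated().any()
    if has_dup:
        with pytest.raises(ValidationError):
            ScoreTable(df)
    else:
        assert len(ScoreTable(df)) == len(df)
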