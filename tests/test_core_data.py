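import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meltrisk.core_data import (
    Category,
    ConcentrationTable,
    aggregate_by_category,
    censor_below_mdl,
    estimate_mdl,
    read_concentration_table,
    resolve_category,
    write_concentration_table,
)
from meltrisk.errors import (
    ConfigError,
    InsufficientData,
    SchemaError,
    UnknownCompoundError,
    ValidationError,
)
from meltrisk.synth import SnowScenario, generate_compound_library, generate_snow_samples


class TestCategoryResolution:
    def test_traffic_always_wins(self):
        assert resolve_category([Category.HUMAN_CONSUMPTION, Category.TRAFFIC]) is Category.TRAFFIC

    def test_precedence_chain(self):
        assert (
            resolve_category([Category.OTHER, Category.HUMAN_CONSUMPTION, Category.PESTICIDE_BIOCIDE])
            is Category.PESTICIDE_BIOCIDE
        )
        assert resolve_category([]) is Category.OTHER


class TestReadWrite:
    def test_well_formed_file_round_trip(self, tmp_path):
        path = tmp_path / "conc.csv"
        path.write_text(
            "sample_id,compound_id,concentration_ng_L\n"
            "s1,c1,10.5\ns1,c2,3.0\ns2,c1,0.8\n"
        )
        table = read_concentration_table(path)
        assert len(table) == 3
        assert table.concentration("s1", "c1") == 10.5

    def test_negative_value_error_names_row(self, tmp_path):
        path = tmp_path / "conc.csv"
        path.write_text("sample_id,compound_id,concentration_ng_L\ns1,c1,5\ns1,c2,-1\n")
        with pytest.raises(ValidationError, match=r"\b3\b"):
            read_concentration_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "conc.csv"
        path.write_text("sample_id,concentration_ng_L\ns1,5\n")
        with pytest.raises(SchemaError):
            read_concentration_table(path)

    def test_unparseable_rows_are_dropped(self, tmp_path):
        path = tmp_path / "conc.csv"
        path.write_text("sample_id,compound_id,concentration_ng_L\ns1,c1,abc\ns1,c2,2\n")
        table = read_concentration_table(path)
        assert len(table) == 1

    def test_unit_conversion_to_ng_l(self, tmp_path):
        path = tmp_path / "conc.csv"
        path.write_text("sample_id,compound_id,concentration_ng_L\ns1,c1,2.5\n")
        table = read_concentration_table(path, schema={"unit": "ug_L"})
        assert table.concentration("s1", "c1") == 2500.0

    def test_write_read_identity_on_generated_tables(self, tmp_path):
        library, _ = generate_compound_library(30, seed=11)
        table, _, _ = generate_snow_samples(
            SnowScenario(seed=11, singleton_fraction=0.3, sub_mdl_fraction=0.0), library
        )
        path = tmp_path / "rt.csv"
        write_concentration_table(table, path)
        back = read_concentration_table(path)
        pd.testing.assert_frame_equal(
            back.data.sort_values(["sample_id", "compound_id"]).reset_index(drop=True),
            table.data.sort_values(["sample_id", "compound_id"]).reset_index(drop=True),
        )
        assert back.mdl_ng_l == table.mdl_ng_l


class TestCensoring:
    def make(self, conc, mdl):
        df = pd.DataFrame(
            {"sample_id": ["s"], "compound_id": ["c"], "concentration_ng_L": [conc]}
        )
        return ConcentrationTable(df, {"c": mdl})

    def test_value_at_mdl_counts_as_detected(self):
        table = censor_below_mdl(self.make(1.0, 1.0))
        assert not table.data["censored"].iloc[0]

    def test_half_mdl_is_censored_and_value_retained(self):
        table = censor_below_mdl(self.make(0.5, 1.0))
        assert table.data["censored"].iloc[0]
        assert table.data["concentration_ng_L"].iloc[0] == 0.5

    def test_idempotent(self):
        once = censor_below_mdl(self.make(0.5, 1.0))
        twice = censor_below_mdl(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_missing_mdl_without_default_is_config_error(self):
        df = pd.DataFrame(
            {"sample_id": ["s"], "compound_id": ["c"], "concentration_ng_L": [2.0]}
        )
        with pytest.raises(ConfigError):
            censor_below_mdl(ConcentrationTable(df, {}))
        ok = censor_below_mdl(ConcentrationTable(df, {}), default_mdl_ng_l=5.0)
        assert ok.data["censored"].iloc[0]

    def test_planted_sub_mdl_fraction_recovered_exactly(self):
        library, _ = generate_compound_library(40, seed=2)
        table, _, truth = generate_snow_samples(
            SnowScenario(seed=2, singleton_fraction=0.3, sub_mdl_fraction=0.15), library
        )
        censored = censor_below_mdl(table)
        assert int(censored.data["censored"].sum()) == truth["n_below_mdl"]
        assert truth["n_below_mdl"] >= truth["n_planted_below_mdl"]


class TestEstimateMdl:
    def test_zero_variance_gives_zero(self):
        assert estimate_mdl([3.0, 3.0, 3.0]) == 0.0

    def test_seven_replicates_match_t_table(self):
        rng = np.random.default_rng(0)
        reps = rng.normal(10.0, 2.0, size=7)
        s = reps.std(ddof=1)
        assert estimate_mdl(reps) == pytest.approx(3.143 * s, rel=1e-3)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None)
    def test_scale_equivariance(self, factor):
        reps = [1.0, 2.0, 4.0, 7.0]
        assert estimate_mdl([factor * r for r in reps]) == pytest.approx(
            factor * estimate_mdl(reps), rel=1e-12
        )

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(InsufficientData):
            estimate_mdl([1.0])


class TestAggregation:
    def test_empty_table_gives_zero_sums_and_counts(self, small_library):
        empty = ConcentrationTable(
            pd.DataFrame(columns=["sample_id", "compound_id", "concentration_ng_L"]), {}
        )
        out = aggregate_by_category(empty, small_library)
        assert out["category_sums"].to_numpy().sum() == 0
        assert len(out["compound_detections"]) == 0

    def test_traffic_additivity(self, small_table, small_library):
        out = aggregate_by_category(small_table, small_library)
        assert out["category_sums"].loc["s1", "traffic"] == 30.0
        assert out["category_sums"].loc["s1", "human_consumption"] == 5.0
        assert out["sample_detections"].loc["s1", "n_detected"] == 3

    def test_censored_entries_excluded(self, small_library):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "compound_id": ["tw-1", "tw-2"],
                "concentration_ng_L": [10.0, 0.2],
            }
        )
        table = censor_below_mdl(ConcentrationTable(df, {"tw-1": 1.0, "tw-2": 1.0}))
        out = aggregate_by_category(table, small_library)
        assert out["category_sums"].loc["s1", "traffic"] == 10.0

    def test_unknown_compound_listed(self, small_table, small_library):
        extra = small_table.data.copy()
        extra.loc[len(extra)] = ["s1", "mystery", 1.0, False]
        with pytest.raises(UnknownCompoundError, match="mystery"):
            aggregate_by_category(ConcentrationTable(extra, small_table.mdl_ng_l), small_library)

    def test_row_order_and_split_invariance(self, small_table, small_library):
        base = aggregate_by_category(small_table, small_library)["category_sums"]
        shuffled = ConcentrationTable(
            small_table.data.sample(frac=1.0, random_state=4), small_table.mdl_ng_l
        )
        pd.testing.assert_frame_equal(
            base, aggregate_by_category(shuffled, small_library)["category_sums"]
        )

    def test_recovers_generated_traffic_fingerprint(self):
        library, _ = generate_compound_library(40, seed=9)
        table, meta, truth = generate_snow_samples(
            SnowScenario(seed=9, singleton_fraction=0.3, sub_mdl_fraction=0.0), library
        )
        out = aggregate_by_category(censor_below_mdl(table), library, meta)
        for site, expected in truth["true_traffic_sum_ng_l"].items():
            assert out["category_sums"].loc[site, "traffic"] == pytest.approx(expected)
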