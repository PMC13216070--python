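"""Survey standardization rules: frequencies, quantities, AME, distances,
and table ingestion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildmeat.survey import (
    UnitConversionTable,
    aggregate_within_day,
    build_distance_matrix,
    compute_ame,
    compute_frequency,
    convert_local_units,
    ingest_tables,
    standardize_daily_quantity,
)


class TestComputeFrequency:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({"category": "monthly"}, 12 / 365),
            ({"category": "weekly"}, 52 / 365),
            ({"category": "daily"}, 1.0),
            ({"category": "yearly"}, 1 / 365),
            ({"events": 2, "monitored_days": 6}, 2 / 6),
            ({"events": 0, "monitored_days": 5}, 0.0),
        ],
    )
    def test_values(self, kwargs, expected):
        assert compute_frequency(**kwargs) == pytest.approx(expected)

    def test_printed_roundings(self):
        # categorical monthly prints as 0.033; 2 events in 6 days as 0.33
        assert round(compute_frequency(category="monthly"), 3) == 0.033
        assert round(compute_frequency(events=2, monitored_days=6), 2) == 0.33

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"events": 7, "monitored_days": 6},
            {"events": 1, "monitored_days": 0},
            {"events": 1, "monitored_days": 1},
            {"category": "fortnightly"},
            {},
        ],
    )
    def test_rejects(self, kwargs):
        with pytest.raises(ValueError):
            compute_frequency(**kwargs)

    @given(
        events=st.integers(0, 365),
        monitored=st.integers(2, 365),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_a_proportion(self, events, monitored):
        if events > monitored:
            return
        f = compute_frequency(events=events, monitored_days=monitored)
        assert 0.0 <= f <= 1.0


class TestQuantity:
    @pytest.mark.parametrize(
        "total, days, expected",
        [(12.0, 3, 4.0), (2.0, 1, 2.0), (0.0, 7, 0.0)],
    )
    def test_daily_standardization(self, total, days, expected):
        assert standardize_daily_quantity(total, days) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            standardize_daily_quantity(1.0, 0.5)
        with pytest.raises(ValueError):
            standardize_daily_quantity(-1.0, 2)


class TestAggregateWithinDay:
    def test_two_meals_one_event(self):
        meals = pd.DataFrame(
            {
                "household_id": ["h1", "h1", "h1"],
                "day": ["d1", "d1", "d2"],
                "consumed": [1, 1, 0],
                "quantity_kg": [0.5, 1.0, 0.0],
            }
        )
        out = aggregate_within_day(meals).set_index("day")
        assert out.loc["d1", "consumed"] == 1
        assert out.loc["d1", "quantity_kg"] == pytest.approx(1.5)
        assert out.loc["d2", "consumed"] == 0
        assert out.loc["d2", "quantity_kg"] == 0.0

    def test_idempotent_on_aggregated_data(self):
        meals = pd.DataFrame(
            {
                "household_id": ["h1", "h1", "h2"],
                "day": ["d1", "d1", "d1"],
                "consumed": [1, 0, 1],
                "quantity_kg": [0.25, 0.0, 2.0],
            }
        )
        once = aggregate_within_day(meals)
        twice = aggregate_within_day(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_rejects_negative_quantity(self):
        meals = pd.DataFrame(
            {"household_id": ["h1"], "day": ["d1"], "consumed": [1],
             "quantity_kg": [-0.5]}
        )
        with pytest.raises(ValueError, match="negative"):
            aggregate_within_day(meals)


class TestConvertLocalUnits:
    TABLE = UnitConversionTable(
        species_mass_kg={"blue_duiker": 10.0},
        unit_kg={"piece": 0.4},
    )

    def test_fraction_units(self):
        records = pd.DataFrame(
            {
                "species": ["blue_duiker"] * 3,
                "unit": ["entire", "half", "quarter"],
                "count": [1, 1, 2],
            }
        )
        kg, flagged = convert_local_units(records, self.TABLE)
        assert list(kg) == pytest.approx([10.0, 5.0, 5.0])
        assert flagged.empty

    def test_direct_units_and_flags(self):
        records = pd.DataFrame(
            {
                "species": [None, None],
                "unit": ["piece", "basket"],
                "count": [3, 1],
            }
        )
        kg, flagged = convert_local_units(records, self.TABLE)
        assert kg.iloc[0] == pytest.approx(1.2)
        assert math.isnan(kg.iloc[1])
        assert len(flagged) == 1 and "basket" in flagged.iloc[0]["reason"]

    def test_rejects_nonpositive_table(self):
        with pytest.raises(ValueError):
            UnitConversionTable(unit_kg={"piece": 0.0})


class TestComputeAME:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({"n_adult_male": 2}, 2.0),
            ({"n_adult_male": 1, "n_adult_female": 1, "n_child_6_10": 1}, 2.71),
            ({"n_child_unspecified": 3}, 2.34),
            ({"n_adult_unspecified": 2}, 1.86),
            (
                {
                    "n_adult_male": 1,
                    "n_adult_female": 1,
                    "n_child_10_15": 1,
                    "n_child_6_10": 1,
                    "n_child_0_5": 1,
                },
                1 + 0.86 + 0.96 + 0.85 + 0.52,
            ),
        ],
    )
    def test_multipliers(self, kwargs, expected):
        assert compute_ame(**kwargs) == pytest.approx(expected)

    def test_empty_household_is_missing_not_zero(self):
        assert math.isnan(compute_ame())

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            compute_ame(n_adult_male=-1)

    @given(
        a=st.tuples(*[st.integers(0, 6)] * 7),
        b=st.tuples(*[st.integers(0, 6)] * 7),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_counts(self, a, b):
        if sum(a) == 0 or sum(b) == 0:
            return
        total = compute_ame(*(x + y for x, y in zip(a, b)))
        assert total == pytest.approx(compute_ame(*a) + compute_ame(*b))


class TestDistanceMatrix:
    def test_one_degree_latitude(self):
        locs = pd.DataFrame({"lon": [15.0, 15.0], "lat": [0.0, 1.0]})
        D = build_distance_matrix(locs)
        assert D[0, 1] == pytest.approx(111.2, abs=0.2)

    def test_symmetric_hollow_triangle(self):
        rng = np.random.default_rng(7)
        locs = pd.DataFrame(
            {"lon": rng.uniform(8, 25, 15), "lat": rng.uniform(-8, 8, 15)}
        )
        D = build_distance_matrix(locs)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D[~np.eye(len(D), dtype=bool)] > 0).all()
        for i, j, k in [(0, 5, 9), (2, 7, 11), (1, 13, 4)]:
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-9

    def test_duplicate_coordinates_give_zero(self):
        locs = pd.DataFrame({"lon": [15.0, 15.0, 16.0], "lat": [1.0, 1.0, 1.0]})
        D = build_distance_matrix(locs)
        assert D[0, 1] == 0.0

    def test_planar_option_and_errors(self):
        locs = pd.DataFrame({"lon": [0.0, 3.0], "lat": [0.0, 4.0]})
        D = build_distance_matrix(locs, method="euclidean")
        assert D[0, 1] == pytest.approx(5.0)
        with pytest.raises(ValueError):
            build_distance_matrix(locs.iloc[:1])
        with pytest.raises(ValueError):
            build_distance_matrix(locs, method="mercator")


class TestIngestion:
    def _base_tables(self):
        studies = pd.DataFrame(
            {"study_id": ["s1"], "study_type": [1], "period": [2]}
        )
        locations = pd.DataFrame(
            {
                "location_id": ["L1"],
                "lon": [15.0],
                "lat": [1.0],
                "location_type": ["village"],
            }
        )
        households = pd.DataFrame(
            {
                "household_id": ["h1", "h2"],
                "location_id": ["L1", "L1"],
                "mdays": [10, 1],
                "frequency": [0.2, "-1"],
                "education": ["unknown", "primary_or_none"],
                "ame": [4.0, "-1"],
            }
        )
        recalls = pd.DataFrame(
            {
                "recall_id": ["r1", "r2", "r3"],
                "household_id": ["h1", "h1", "h2"],
                "days": [1.0, 2.0, 1.0],
                "consumed": [1, 0, 1],
                "quantity_kg": [0.5, 0.0, "-1"],
                "ame": [4.0, 4.0, "-1"],
            }
        )
        return studies, locations, households, recalls

    def test_missing_codes_translated(self):
        tables = ingest_tables(*self._base_tables())
        assert tables.households["ame"].isna().sum() == 1
        assert tables.recalls["quantity_kg"].isna().sum() == 1
        assert tables.report["counts"]["households_missing_ame"] == 1

    def test_duplicate_recall_ids_rejected(self):
        studies, locations, households, recalls = self._base_tables()
        dup = pd.concat([recalls, recalls.iloc[[0]]], ignore_index=True)
        tables = ingest_tables(studies, locations, households, dup)
        assert "r1" in tables.report["excluded"]["duplicate_recall_ids"]
        assert "r1" not in set(tables.recalls["recall_id"])

    def test_single_day_frequency_dropped_with_flag(self):
        studies, locations, households, recalls = self._base_tables()
        households.loc[1, "frequency"] = 0.4  # mdays = 1
        tables = ingest_tables(studies, locations, households, recalls)
        assert tables.households["frequency"].isna().sum() == 1
        assert any("mdays < 2" in f for f in tables.report["flags"])

    def test_inconsistent_quantity_excluded(self):
        studies, locations, households, recalls = self._base_tables()
        recalls.loc[1, "quantity_kg"] = 0.7  # consumed = 0
        tables = ingest_tables(studies, locations, households, recalls)
        assert tables.report["excluded"]["inconsistent_recalls"] == ["r2"]

    def test_model_ready_split(self):
        tables = ingest_tables(*self._base_tables())
        ready = tables.model_ready()
        assert len(ready["consumption"]) == 3
        assert len(ready["frequency"]) == 1  # h2's frequency is missing
        assert len(ready["quantity"]) == 1  # only consumed recalls with kg
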