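from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffqkit import (
    FoodGroupMap,
    FrequencyScale,
    Instrument,
    ScoringError,
    aggregate_food_groups,
    frequency_multiplier,
    percent_energy,
    score_response,
)
from ffqkit.derivation import NUTRIENTS, CompositionTable
from ffqkit.scoring import ENERGY_FACTORS_KCAL_PER_G, IntakeRecord

from conftest import constant_composition, make_instrument, make_item, make_response


class TestFrequencyMultiplier:
    @pytest.mark.parametrize(
        "index,expected",
        [
            (0, 0.0),            # never
            (5, 1.0),            # once a day
            (3, 3.0 / 7.0),      # 2-4 per week, midpoint convention
            (8, 6.0),            # 6+ per day scored as 6
        ],
    )
    def test_default_mapping(self, index, expected):
        assert frequency_multiplier(FrequencyScale(), index) == pytest.approx(expected)

    def test_out_of_range_errors(self):
        with pytest.raises(ScoringError):
            frequency_multiplier(FrequencyScale(), 9)


class TestScoreResponse:
    def test_all_never_scores_exactly_zero(self, toy_instrument, toy_composition):
        rec = score_response(
            toy_instrument, toy_composition, make_response(toy_instrument, freq_idx=0)
        )
        assert all(v == 0.0 for v in rec.nutrients.values())
        assert all(v == 0.0 for v in rec.food_groups.values())
        assert all(math.isnan(v) for v in rec.percent_te.values())

    def test_single_item_hand_arithmetic(self):
        # 1 item, once a day, 150 g portion, 200 kcal/100 g -> 300 kcal/day
        item = make_item("i0", p50=150.0)
        inst = Instrument("t1", (item,), ("staples",))
        comp = constant_composition(inst, energy=200.0)
        rec = score_response(inst, comp, make_response(inst, freq_idx=5, portion_idx=3))
        assert rec.nutrients["energy_kcal"] == pytest.approx(300.0)
        assert rec.per_item_grams["i0"] == pytest.approx(150.0)

    def test_matches_item_by_item_brute_force(self, toy_instrument, toy_composition):
        """Whole-instrument scoring equals summing single-item instruments."""
        resp = make_response(toy_instrument, freq_idx=6, portion_idx=5)
        rec = score_response(toy_instrument, toy_composition, resp)
        brute = np.zeros(len(NUTRIENTS))
        for item in toy_instrument.items:
            sub = Instrument(toy_instrument.name, (item,), toy_instrument.categories,
                             toy_instrument.frequency_scale)
            sub_resp = dataclasses.replace(
                resp, answers={item.item_id: resp.answers[item.item_id]}
            )
            sub_rec = score_response(sub, toy_composition, sub_resp)
            brute += np.array([sub_rec.nutrients[k] for k in NUTRIENTS])
        np.testing.assert_allclose(
            np.array([rec.nutrients[k] for k in NUTRIENTS]), brute, rtol=0, atol=1e-12
        )

    @given(freq=st.integers(0, 8), portion=st.integers(0, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_doubling_portion_doubles_intakes(self, freq, portion):
        inst = make_instrument(3)
        comp = constant_composition(inst)
        base = score_response(inst, comp, make_response(inst, freq, portion))
        doubled = score_response(inst, comp, make_response(inst, freq, portion + 1))
        series = inst.items[0].portion_series.options
        alpha = series[portion + 1] / series[portion]
        for k in NUTRIENTS:
            assert doubled.nutrients[k] == pytest.approx(alpha * base.nutrients[k])

    def test_missing_composition_names_item(self, toy_instrument, toy_composition):
        del toy_composition.values["i2"]
        with pytest.raises(ScoringError, match="i2"):
            score_response(toy_instrument, toy_composition, make_response(toy_instrument))

    def test_unscoreable_response_rejected(self, toy_instrument, toy_composition):
        resp = make_response(toy_instrument)
        bad = dataclasses.replace(
            resp, answers={k: v for k, v in list(resp.answers.items())[:-1]}
        )
        with pytest.raises(ScoringError, match="not scoreable"):
            score_response(toy_instrument, toy_composition, bad)


def record_with(energy=0.0, **grams) -> IntakeRecord:
    nutrients = {k: 0.0 for k in NUTRIENTS}
    nutrients["energy_kcal"] = energy
    nutrients.update(grams)
    return IntakeRecord("r", nutrients, {}, {}, {})


class TestPercentEnergy:
    def test_zero_fat_gives_zero_pct(self):
        rec = percent_energy(record_with(energy=1000.0, fat_g=0.0))
        assert rec.percent_te["fat_pct_te"] == 0.0

    def test_hand_oracle(self):
        rec = percent_energy(record_with(energy=900.0, fat_g=10.0))
        assert rec.percent_te["fat_pct_te"] == pytest.approx(10.0)  # 9*10*100/900

    def test_zero_energy_is_undefined_not_zero(self):
        rec = percent_energy(record_with(energy=0.0, fat_g=10.0))
        assert math.isnan(rec.percent_te["fat_pct_te"])

    def test_components_sum_to_100_when_energy_is_their_sum(self):
        grams = {"fat_g": 20.0, "protein_g": 30.0, "carbohydrate_g": 50.0,
                 "alcohol_g": 5.0}
        energy = sum(ENERGY_FACTORS_KCAL_PER_G[k] * v for k, v in grams.items())
        rec = percent_energy(record_with(energy=energy, **grams))
        total = (
            rec.percent_te["fat_pct_te"]
            + rec.percent_te["protein_pct_te"]
            + rec.percent_te["carbohydrate_pct_te"]
            + ENERGY_FACTORS_KCAL_PER_G["alcohol_g"] * grams["alcohol_g"] * 100 / energy
        )
        assert total == pytest.approx(100.0, abs=1e-12)


class TestIntakeTableIO:
    def test_round_trip_preserves_values_and_comma_columns(self, tmp_path, toy_instrument, toy_composition):
        from ffqkit.scoring import read_intakes, score_all, write_intakes

        # a group label containing commas must survive the units header row
        import dataclasses

        items = tuple(
            dataclasses.replace(it, food_group="Rice, pasta, and grains")
            for it in toy_instrument.items
        )
        inst = dataclasses.replace(toy_instrument, items=items)
        df = score_all(inst, toy_composition, [make_response(inst, 5, 3, rid="r9")])
        path = tmp_path / "intakes.csv"
        write_intakes(df, path)
        back = read_intakes(path)
        assert list(back.columns) == list(df.columns)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy())


class TestAggregateFoodGroups:
    def test_singleton_and_hand_sum(self):
        fg = FoodGroupMap({"a": "G1", "b": "G2", "c": "G2"})
        out = aggregate_food_groups({"a": 90.0, "b": 50.0, "c": 70.0}, fg)
        assert out == {"G1": 90.0, "G2": 120.0}

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        items = {f"i{k}": float(v) for k, v in enumerate(rng.uniform(0, 300, 40))}
        fg = FoodGroupMap({i: f"G{k % 5}" for k, i in enumerate(items)})
        out = aggregate_food_groups(items, fg)
        assert sum(out.values()) == pytest.approx(sum(items.values()), rel=1e-12)

    def test_unmapped_item_errors(self):
        fg = FoodGroupMap({"a": "G1"})
        with pytest.raises(Exception, match="b"):
            aggregate_food_groups({"a": 1.0, "b": 2.0}, fg)
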