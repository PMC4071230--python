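from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from ffqkit import (
    CompositionTable,
    FoodItem,
    FrequencyScale,
    Instrument,
    PortionSeries,
    ResponseSet,
)
from ffqkit.derivation import NUTRIENTS


def make_series(p50: float = 100.0) -> PortionSeries:
    p25, p75 = 0.7 * p50, 1.4 * p50
    return PortionSeries(
        (0.5 * p25, p25, (p25 + p50) / 2, p50, (p50 + p75) / 2, p75, 1.5 * p75),
        (p25, p50, p75),
    )


def make_item(item_id: str, group: str = "Grains", category: str = "staples",
              p50: float = 100.0) -> FoodItem:
    return FoodItem(
        item_id=item_id,
        name=item_id,
        category=category,
        portion_series=make_series(p50),
        composition_ref=item_id,
        food_group=group,
    )


def make_instrument(n_items: int = 3, name: str = "toy") -> Instrument:
    groups = ["Grains", "Dairy", "Fruit"]
    items = tuple(
        make_item(f"i{k}", group=groups[k % len(groups)], p50=50.0 + 25.0 * k)
        for k in range(n_items)
    )
    return Instrument(name=name, items=items, categories=("staples",),
                      frequency_scale=FrequencyScale())


def constant_composition(instrument: Instrument, energy: float = 200.0) -> CompositionTable:
    """Every item: energy kcal/100 g as given, fat 10 g, protein 5 g, carb 20 g."""
    table = CompositionTable()
    base = {k: 0.0 for k in NUTRIENTS}
    base.update(energy_kcal=energy, fat_g=10.0, protein_g=5.0,
                carbohydrate_g=20.0, total_sugars_g=5.0, calcium_mg=100.0)
    vec = np.array([base[k] for k in NUTRIENTS])
    for item in instrument.items:
        table.values[item.composition_ref] = vec.copy()
        table.provenance[item.composition_ref] = ("fixture",)
    return table


def make_response(instrument: Instrument, freq_idx: int = 5, portion_idx: int = 3,
                  rid: str = "r1", when: date = date(2012, 5, 1)) -> ResponseSet:
    return ResponseSet(
        respondent_id=rid,
        instrument_name=instrument.name,
        completion_date=when,
        answers={i: (freq_idx, portion_idx) for i in instrument.item_ids},
    )


@pytest.fixture
def toy_instrument() -> Instrument:
    return make_instrument(3)


@pytest.fixture
def toy_composition(toy_instrument) -> CompositionTable:
    return constant_composition(toy_instrument)
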