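"""Score questionnaire responses into daily nutrient and food-group intakes.

For each item, daily grams = (events/day for the chosen frequency category)
x (grams for the chosen portion option).  Nutrient intakes accumulate
grams/day x per-100 g composition / 100; food-group intakes sum member
items' grams/day.  Percent-of-total-energy (%TE) values use the UK
energy-conversion convention: fat 9, protein 4, carbohydrate 3.75
(monosaccharide equivalents), alcohol 7 kcal/g.

Energy is read from the composition table's energy field, as composition
databases are used in practice, not recomputed from the macronutrients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .derivation import NUTRIENT_PANEL, NUTRIENTS, CompositionTable
from .instrument import (
    FoodGroupMap,
    FrequencyScale,
    Instrument,
    ResponseSet,
    validate_response,
)

#: kcal per gram; carbohydrate is the UK monosaccharide-equivalent factor.
ENERGY_FACTORS_KCAL_PER_G: dict[str, float] = {
    "fat_g": 9.0,
    "protein_g": 4.0,
    "carbohydrate_g": 3.75,
    "alcohol_g": 7.0,
}

#: %TE output column per contributing nutrient column.
PERCENT_TE_COLUMNS: dict[str, str] = {
    "fat_g": "fat_pct_te",
    "sfa_g": "sfa_pct_te",
    "mufa_g": "mufa_pct_te",
    "pufa_g": "pufa_pct_te",
    "protein_g": "protein_pct_te",
    "carbohydrate_g": "carbohydrate_pct_te",
}

# fatty-acid subclasses burn at the fat factor
_TE_FACTOR_OF = {
    "fat_g": 9.0,
    "sfa_g": 9.0,
    "mufa_g": 9.0,
    "pufa_g": 9.0,
    "protein_g": 4.0,
    "carbohydrate_g": 3.75,
}


class ScoringError(ValueError):
    pass


@dataclass
class IntakeRecord:
    """One respondent's scored daily intakes."""

    respondent_id: str
    nutrients: dict[str, float]          # per NUTRIENTS, daily units
    percent_te: dict[str, float]         # %TE fields; NaN when energy == 0
    food_groups: dict[str, float]        # grams/day per group
    per_item_grams: dict[str, float]     # audit trail, grams/day per item

    @property
    def energy_kcal(self) -> float:
        return self.nutrients["energy_kcal"]


def frequency_multiplier(scale: FrequencyScale, category_index: int) -> float:
    """Events/day for one frequency category."""
    if not 0 <= category_index < len(scale):
        raise ScoringError(
            f"frequency index {category_index} not in [0, {len(scale) - 1}]"
        )
    return scale.multipliers[category_index]


def aggregate_food_groups(
    per_item_grams: Mapping[str, float], group_map: FoodGroupMap
) -> dict[str, float]:
    """Sum item grams/day into food-group grams/day (map must be total)."""
    out: dict[str, float] = {label: 0.0 for label in group_map.labels}
    for item_id, grams in per_item_grams.items():
        out[group_map.group_of(item_id)] += grams
    return out


def score_response(
    instrument: Instrument,
    composition: CompositionTable,
    response: ResponseSet,
) -> IntakeRecord:
    """Score one validated response set into an :class:`IntakeRecord`."""
    report = validate_response(instrument, response)
    if not report.ok:
        raise ScoringError(
            f"response {response.respondent_id!r} is not scoreable: "
            f"missing={list(report.missing_items)} "
            f"out_of_range={list(report.out_of_range)}"
        )
    scale = instrument.frequency_scale
    totals = np.zeros(len(NUTRIENTS))
    per_item: dict[str, float] = {}
    for item in instrument.items:
        if item.composition_ref not in composition:
            raise ScoringError(
                f"item {item.item_id!r} (composition_ref "
                f"{item.composition_ref!r}) missing from composition table"
            )
        f_idx, p_idx = response.answers[item.item_id]
        grams = frequency_multiplier(scale, f_idx) * item.portion_series.options[p_idx]
        per_item[item.item_id] = grams
        totals += grams * composition.values[item.composition_ref] / 100.0
    nutrients = dict(zip(NUTRIENTS, totals.tolist()))
    record = IntakeRecord(
        respondent_id=response.respondent_id,
        nutrients=nutrients,
        percent_te={},
        food_groups=aggregate_food_groups(per_item, instrument.food_group_map),
        per_item_grams=per_item,
    )
    return percent_energy(record)


def percent_energy(
    intake: IntakeRecord,
    factors: Mapping[str, float] | None = None,
) -> IntakeRecord:
    """Fill the %TE fields: factor x grams x 100 / energy (kcal).

    When energy is 0 the fields are NaN (undefined), never 0.
    """
    energy = intake.nutrients["energy_kcal"]
    table = dict(_TE_FACTOR_OF)
    if factors is not None:
        for nutrient, factor in factors.items():
            table[nutrient] = factor
    for nutrient, column in PERCENT_TE_COLUMNS.items():
        grams = intake.nutrients[nutrient]
        if energy > 0:
            intake.percent_te[column] = table[nutrient] * grams * 100.0 / energy
        else:
            intake.percent_te[column] = math.nan
    return intake


def score_all(
    instrument: Instrument,
    composition: CompositionTable,
    responses: Iterable[ResponseSet],
) -> pd.DataFrame:
    """Score many responses into one wide intake table.

    Columns: the nutrient panel, the %TE fields, then one column per food
    group prefixed ``group:``.  Index: respondent_id.
    """
    rows = {}
    for resp in responses:
        rec = score_response(instrument, composition, resp)
        row: dict[str, float] = dict(rec.nutrients)
        row.update(rec.percent_te)
        row.update({f"group:{g}": v for g, v in rec.food_groups.items()})
        rows[rec.respondent_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "respondent_id"
    return df


def intake_units_header(columns: Sequence[str]) -> list[str]:
    """Units row matching an intake table's columns."""
    units = []
    for col in columns:
        if col in NUTRIENT_PANEL:
            units.append(NUTRIENT_PANEL[col])
        elif col.endswith("_pct_te"):
            units.append("%TE")
        elif col.startswith("group:"):
            units.append("g/day")
        else:
            units.append("")
    return units


def write_intakes(df: pd.DataFrame, path: str | Path) -> None:
    """Write an intake table with a units header row below the column names."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["respondent_id", *df.columns])
        writer.writerow(["unit", *intake_units_header(list(df.columns))])
        df.to_csv(fh, header=False)


def read_intakes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="respondent_id")
    if len(df) and df.index[0] == "unit":
        df = df.iloc[1:].astype(float)
    return df.astype(float)
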