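"""Derive per-item composition and portion series from consumption surveys.

A national food-consumption survey records, per respondent, the foods eaten
and the grams consumed per day.  Survey food codes are mapped (recoded) onto
the questionnaire's food items.  From those records this module derives:

* a per-item nutrient composition: the unweighted mean of the per-100 g
  nutrient vectors of the *k* most frequently consumed mapped foods
  (default ``k=3``), and
* a per-item portion series: the 25th/50th/75th percentiles of daily intake
  become the small/medium/large portion anchors, padded to a 7-option
  series with half-way, half-of-smallest, and 1.5x-largest options.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import PortionSeries

#: Fixed nutrient panel (column name -> unit), per 100 g edible portion.
NUTRIENT_PANEL: dict[str, str] = {
    "energy_kcal": "kcal",
    "fat_g": "g",
    "sfa_g": "g",
    "mufa_g": "g",
    "pufa_g": "g",
    "protein_g": "g",
    "carbohydrate_g": "g",
    "total_sugars_g": "g",
    "alcohol_g": "g",
    "calcium_mg": "mg",
    "folate_ug": "ug",
    "iron_mg": "mg",
    "carotene_ug": "ug",
    "riboflavin_mg": "mg",
    "thiamin_mg": "mg",
    "vitamin_b6_mg": "mg",
    "vitamin_b12_ug": "ug",
    "vitamin_c_mg": "mg",
    "vitamin_a_re_ug": "ug",
    "retinol_ug": "ug",
    "vitamin_d_ug": "ug",
    "vitamin_e_mg": "mg",
    "sodium_mg": "mg",
    "salt_g": "g",
}

NUTRIENTS: tuple[str, ...] = tuple(NUTRIENT_PANEL)


class DerivationError(ValueError):
    pass


@dataclass(frozen=True)
class ConsumptionRecord:
    """One survey consumption event mapped onto a questionnaire item."""

    respondent_id: str
    food_code: str
    item_id: str
    amount: float  # grams/day

    def __post_init__(self) -> None:
        if not np.isfinite(self.amount) or self.amount <= 0:
            raise DerivationError(
                f"record for {self.food_code!r} has non-positive amount {self.amount}"
            )


@dataclass(frozen=True)
class FoodCompositionEntry:
    """Per-100 g nutrient vector for one survey food code."""

    food_code: str
    nutrients: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(NUTRIENTS) - set(self.nutrients)
        if missing:
            raise DerivationError(
                f"food {self.food_code!r} missing nutrients {sorted(missing)}"
            )
        for k in NUTRIENTS:
            if self.nutrients[k] < 0:
                raise DerivationError(
                    f"food {self.food_code!r} has negative {k}"
                )

    def vector(self) -> np.ndarray:
        return np.array([self.nutrients[k] for k in NUTRIENTS], dtype=float)


@dataclass
class CompositionTable:
    """item_id -> per-100 g nutrient vector, with contributing-food provenance."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.values

    def nutrient(self, item_id: str, name: str) -> float:
        return float(self.values[item_id][NUTRIENTS.index(name)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            {k: v for k, v in self.values.items()}, orient="index", columns=NUTRIENTS
        )
        df.index.name = "item_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionTable":
        missing = set(NUTRIENTS) - set(df.columns)
        if missing:
            raise DerivationError(f"composition table missing columns {sorted(missing)}")
        values = {
            str(idx): row[list(NUTRIENTS)].to_numpy(dtype=float)
            for idx, row in df.iterrows()
        }
        for item_id, vec in values.items():
            if (vec < 0).any():
                raise DerivationError(f"negative composition value for {item_id!r}")
        return cls(values=values, provenance={k: () for k in values})

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def load(cls, path: str | Path) -> "CompositionTable":
        return cls.from_frame(pd.read_csv(path, index_col="item_id"))


def derive_composition(
    records: Sequence[ConsumptionRecord],
    foods: Sequence[FoodCompositionEntry],
    k: int = 3,
) -> CompositionTable:
    """Mean per-100 g composition of each item's top-k most consumed foods.

    "Most frequently consumed" counts consumption records (occurrences);
    ties are broken lexicographically by food code.  An item mapped to fewer
    than *k* distinct foods averages all of them.
    """
    if k < 1:
        raise DerivationError("k must be >= 1")
    by_code = {f.food_code: f for f in foods}
    for rec in records:
        if rec.food_code not in by_code:
            raise DerivationError(
                f"no composition entry for food code {rec.food_code!r}"
            )
    counts: dict[str, Counter] = defaultdict(Counter)
    for rec in records:
        counts[rec.item_id][rec.food_code] += 1
    table = CompositionTable()
    for item_id in sorted(counts):
        ranked = sorted(counts[item_id].items(), key=lambda kv: (-kv[1], kv[0]))
        chosen = tuple(code for code, _ in ranked[:k])
        vectors = np.stack([by_code[c].vector() for c in chosen])
        table.values[item_id] = vectors.mean(axis=0)
        table.provenance[item_id] = chosen
    return table


_DEGENERATE_GRID = (0.5, 0.75, 0.9, 1.0, 1.1, 1.25, 1.5)


def derive_portion_series(
    records: Sequence[ConsumptionRecord],
    item_id: str,
    n_options: int = 7,
    basis: Literal["daily", "occasion"] = "daily",
    decimals: int = 1,
) -> PortionSeries:
    """Portion series for one item from its survey intake distribution.

    Anchors are the 25th/50th/75th percentiles (linear interpolation between
    order statistics) of either per-respondent daily totals (``basis="daily"``,
    the default) or raw per-record amounts (``basis="occasion"``).  The
    7-option series is ``[0.5*p25, p25, (p25+p50)/2, p50, (p50+p75)/2, p75,
    1.5*p75]``, each rounded to ``decimals``.  A degenerate distribution
    (all anchors equal, value c) falls back to the multiplicative grid
    ``{0.5, 0.75, 0.9, 1, 1.1, 1.25, 1.5} * c``.
    """
    if n_options != 7:
        raise DerivationError("only the documented 7-option series is supported")
    amounts = [r.amount for r in records if r.item_id == item_id]
    if not amounts:
        raise DerivationError(f"no consumption records for item {item_id!r}")
    if basis == "daily":
        totals: dict[str, float] = defaultdict(float)
        for r in records:
            if r.item_id == item_id:
                totals[r.respondent_id] += r.amount
        sample = np.array(sorted(totals.values()), dtype=float)
    elif basis == "occasion":
        sample = np.array(amounts, dtype=float)
    else:
        raise DerivationError(f"unknown basis {basis!r}")
    p25, p50, p75 = np.percentile(sample, [25, 50, 75], method="linear")
    r = lambda x: round(float(x), decimals)
    if r(p25) == r(p75):  # degenerate: collapse around the common value
        c = r(p50)
        options = tuple(r(g * c) for g in _DEGENERATE_GRID)
        return PortionSeries(options, (c, c, c))
    anchors = (r(p25), r(p50), r(p75))
    options = (
        r(0.5 * p25),
        anchors[0],
        r((p25 + p50) / 2),
        anchors[1],
        r((p50 + p75) / 2),
        anchors[2],
        r(1.5 * p75),
    )
    return PortionSeries(options, anchors)


# ---------------------------------------------------------------------------
# Delimited I/O
# ---------------------------------------------------------------------------

def read_consumption_records(path: str | Path) -> list[ConsumptionRecord]:
    df = pd.read_csv(path)
    required = {"respondent_id", "food_code", "item_id", "amount"}
    missing = required - set(df.columns)
    if missing:
        raise DerivationError(f"records table missing columns {sorted(missing)}")
    return [
        ConsumptionRecord(str(r.respondent_id), str(r.food_code), str(r.item_id),
                          float(r.amount))
        for r in df.itertuples()
    ]


def read_food_compositions(path: str | Path) -> list[FoodCompositionEntry]:
    df = pd.read_csv(path)
    if "food_code" not in df.columns:
        raise DerivationError("foods table missing column 'food_code'")
    return [
        FoodCompositionEntry(
            str(row["food_code"]),
            {k: float(row[k]) for k in NUTRIENTS},
        )
        for _, row in df.iterrows()
    ]
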