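"""Packaged questionnaire fixtures.

Two instruments are shipped:

* ``food4me_instrument()`` — the 157-item online questionnaire, 11 display
  categories, 9-level frequency scale, 7-option portion series per item.
* ``epic_norfolk_instrument()`` — the 130-item printed base list it extends;
  its items are a strict subset of the online instrument's, the online one
  adding 27 items.

The category structure, the shared 35-label food-group classification and
the item counts are documented instrument facts; individual item *names*
are deterministic placeholders (``fixture=True``) because no public
enumeration of the full food lists exists.
"""

from __future__ import annotations

from .instrument import FoodItem, FrequencyScale, Instrument, PortionSeries

#: The 11 display categories, in questionnaire order.
CATEGORIES: tuple[str, ...] = (
    "cereal",
    "bread and savory biscuits",
    "potatoes, rice, and pasta",
    "meat and fish",
    "dairy products",
    "fats and spreads",
    "sweets and snacks",
    "soups, sauces, and spreads",
    "drinks",
    "fruit",
    "vegetables",
)

#: Per-category item counts: (online 157-item count, printed 130-item count).
_CATEGORY_COUNTS: dict[str, tuple[int, int]] = {
    "cereal": (10, 8),
    "bread and savory biscuits": (12, 10),
    "potatoes, rice, and pasta": (12, 10),
    "meat and fish": (24, 19),
    "dairy products": (14, 12),
    "fats and spreads": (10, 9),
    "sweets and snacks": (16, 13),
    "soups, sauces, and spreads": (12, 10),
    "drinks": (17, 14),
    "fruit": (12, 10),
    "vegetables": (18, 15),
}

#: The 35 standard food groups used for group-level intake analysis.
FOOD_GROUPS: tuple[str, ...] = (
    "Rice, pasta, grains, and starches",
    "Savories (lasagna, pizza)",
    "White bread (rolls, tortillas, crackers)",
    "Wholemeal and brown breads and rolls",
    "Breakfast cereals and porridge",
    "Biscuits",
    "Cakes, pastries, and buns",
    "Milk",
    "Cheeses",
    "Yoghurts",
    "Ice cream, creams, and desserts",
    "Eggs and egg dishes",
    "Fats and oils",
    "Potatoes and potato dishes",
    "Chipped, fried, and roasted potatoes",
    "Peas, beans, and lentils and vegetable and pulse dishes",
    "Green vegetables",
    "Carrots",
    "Salad vegetables",
    "Other vegetables",
    "Tinned fruit or vegetables",
    "Bananas",
    "Other fruits",
    "Nuts and seeds, herbs and spices",
    "Fish and fish products/dishes",
    "Bacon and ham",
    "Red meat",
    "Poultry",
    "Meat products",
    "Alcoholic beverages",
    "Sugars, syrups, preserves, and sweeteners",
    "Confectionary and savory snacks",
    "Soups, sauces, and miscellaneous foods",
    "Teas and coffees",
    "Other beverages",
)

# Food groups reachable from each display category; items cycle through them
# so every group has members in both instruments.
_CATEGORY_GROUPS: dict[str, tuple[str, ...]] = {
    "cereal": (
        "Breakfast cereals and porridge",
        "Rice, pasta, grains, and starches",
    ),
    "bread and savory biscuits": (
        "White bread (rolls, tortillas, crackers)",
        "Wholemeal and brown breads and rolls",
        "Biscuits",
    ),
    "potatoes, rice, and pasta": (
        "Potatoes and potato dishes",
        "Chipped, fried, and roasted potatoes",
        "Rice, pasta, grains, and starches",
        "Savories (lasagna, pizza)",
    ),
    "meat and fish": (
        "Red meat",
        "Poultry",
        "Bacon and ham",
        "Meat products",
        "Fish and fish products/dishes",
        "Eggs and egg dishes",
    ),
    "dairy products": (
        "Milk",
        "Cheeses",
        "Yoghurts",
        "Ice cream, creams, and desserts",
    ),
    "fats and spreads": ("Fats and oils",),
    "sweets and snacks": (
        "Cakes, pastries, and buns",
        "Confectionary and savory snacks",
        "Sugars, syrups, preserves, and sweeteners",
        "Biscuits",
    ),
    "soups, sauces, and spreads": (
        "Soups, sauces, and miscellaneous foods",
        "Nuts and seeds, herbs and spices",
    ),
    "drinks": (
        "Teas and coffees",
        "Alcoholic beverages",
        "Other beverages",
    ),
    "fruit": (
        "Bananas",
        "Other fruits",
        "Tinned fruit or vegetables",
    ),
    "vegetables": (
        "Green vegetables",
        "Carrots",
        "Salad vegetables",
        "Other vegetables",
        "Peas, beans, and lentils and vegetable and pulse dishes",
        "Tinned fruit or vegetables",
    ),
}

# Typical medium-portion grams per category; item series are scaled around it.
_CATEGORY_P50: dict[str, float] = {
    "cereal": 45.0,
    "bread and savory biscuits": 35.0,
    "potatoes, rice, and pasta": 150.0,
    "meat and fish": 100.0,
    "dairy products": 120.0,
    "fats and spreads": 10.0,
    "sweets and snacks": 40.0,
    "soups, sauces, and spreads": 80.0,
    "drinks": 220.0,
    "fruit": 100.0,
    "vegetables": 80.0,
}


def _portion_series(p50: float) -> PortionSeries:
    """7-option series around fixed small/medium/large anchors."""
    p25 = round(0.7 * p50, 1)
    p75 = round(1.4 * p50, 1)
    options = (
        round(0.5 * p25, 1),
        p25,
        round((p25 + p50) / 2, 1),
        round(p50, 1),
        round((p50 + p75) / 2, 1),
        p75,
        round(1.5 * p75, 1),
    )
    return PortionSeries(options, (p25, round(p50, 1), p75))


def _build(name: str, online: bool) -> Instrument:
    items: list[FoodItem] = []
    for cat_idx, cat in enumerate(CATEGORIES):
        n_online, n_print = _CATEGORY_COUNTS[cat]
        n = n_online if online else n_print
        groups = _CATEGORY_GROUPS[cat]
        slug = f"c{cat_idx + 1:02d}"
        for j in range(n):
            item_id = f"{slug}_{j + 1:02d}"
            # mild deterministic size variation across a category's items
            p50 = _CATEGORY_P50[cat] * (1.0 + 0.1 * (j % 5 - 2))
            items.append(
                FoodItem(
                    item_id=item_id,
                    name=f"{cat} item {j + 1} (placeholder)",
                    category=cat,
                    portion_series=_portion_series(p50),
                    composition_ref=item_id,
                    food_group=groups[j % len(groups)],
                    fixture=True,
                )
            )
    return Instrument(
        name=name,
        items=tuple(items),
        categories=CATEGORIES,
        frequency_scale=FrequencyScale(),
    )


def food4me_instrument() -> Instrument:
    """The packaged 157-item online instrument."""
    return _build("food4me", online=True)


def epic_norfolk_instrument() -> Instrument:
    """The packaged 130-item printed base instrument (item-subset of online)."""
    return _build("epic-norfolk", online=False)
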