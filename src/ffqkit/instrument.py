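"""Food-frequency questionnaire (FFQ) instrument structures.

An *instrument* is the questionnaire itself: an ordered list of food items,
each belonging to one display category, sharing one frequency scale
("never (<1 per month)" ... "6+ per day") and carrying its own series of
selectable portion sizes in grams.  A *response set* holds one respondent's
answers: for every item, the index of the chosen frequency category and the
index of the chosen portion option.

The online delivery of such questionnaires enforces completeness — a
frequency must be reported for every item before submission — and
:func:`validate_response` mirrors that rule offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

SCHEMA_VERSION = 1

#: Conventional 9-level frequency scale: midpoint-of-range events/day.
#: "1-3 per month" uses 2 occasions over a mean month of 30.44 days.
DEFAULT_FREQUENCY_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("never (<1 per month)", 0.0),
    ("1-3 per month", 2.0 / 30.44),
    ("once a week", 1.0 / 7.0),
    ("2-4 per week", 3.0 / 7.0),
    ("5-6 per week", 5.5 / 7.0),
    ("once a day", 1.0),
    ("2-3 per day", 2.5),
    ("4-5 per day", 4.5),
    ("6+ per day", 6.0),
)


class InstrumentError(ValueError):
    """Structural problem in an instrument definition or response file."""


class ResponseValidationError(InstrumentError):
    """A response set cannot be scored against the claimed instrument."""


@dataclass(frozen=True)
class FrequencyScale:
    """Ordered consumption-frequency categories with events/day multipliers."""

    categories: tuple[tuple[str, float], ...] = DEFAULT_FREQUENCY_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise InstrumentError("frequency scale needs at least 2 categories")
        mults = [m for _, m in self.categories]
        if mults[0] != 0.0:
            raise InstrumentError(
                "first frequency category must be 'never' with multiplier 0"
            )
        if any(m < 0 for m in mults):
            raise InstrumentError("frequency multipliers must be >= 0")
        if any(b < a for a, b in zip(mults, mults[1:])):
            raise InstrumentError("frequency multipliers must be nondecreasing")

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.categories)

    @property
    def multipliers(self) -> tuple[float, ...]:
        return tuple(m for _, m in self.categories)


@dataclass(frozen=True)
class PortionSeries:
    """Selectable grams-per-occasion options anchored at intake percentiles.

    ``anchors`` are the (p25, p50, p75) gram amounts — small, medium and
    large portions — and must appear among ``options``.
    """

    options: tuple[float, ...]
    anchors: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.options:
            raise InstrumentError("portion series has no options")
        if any(o <= 0 for o in self.options):
            raise InstrumentError("portion options must be > 0 g")
        if any(b < a for a, b in zip(self.options, self.options[1:])):
            raise InstrumentError("portion options must be nondecreasing")
        p25, p50, p75 = self.anchors
        if not (p25 <= p50 <= p75):
            raise InstrumentError("portion anchors must satisfy p25 <= p50 <= p75")
        for a in self.anchors:
            if not any(abs(a - o) < 1e-9 for o in self.options):
                raise InstrumentError(
                    f"anchor {a} g is not among the portion options"
                )

    def __len__(self) -> int:
        return len(self.options)


@dataclass(frozen=True)
class FoodItem:
    item_id: str
    name: str
    category: str
    portion_series: PortionSeries
    composition_ref: str
    food_group: str
    fixture: bool = False  # placeholder name, not enumerated by a source list


@dataclass(frozen=True)
class FoodGroupMap:
    """Total mapping item_id -> food-group label (35 standard groups)."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        for item_id, label in self.groups.items():
            if not label:
                raise InstrumentError(f"empty food-group label for item {item_id!r}")

    def group_of(self, item_id: str) -> str:
        try:
            return self.groups[item_id]
        except KeyError:
            raise InstrumentError(f"item {item_id!r} has no food-group mapping")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.groups.values())))


@dataclass(frozen=True)
class Instrument:
    name: str
    items: tuple[FoodItem, ...]
    categories: tuple[str, ...]
    frequency_scale: FrequencyScale = field(default_factory=FrequencyScale)

    def __post_init__(self) -> None:
        if not self.items:
            raise InstrumentError("empty item list")
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise InstrumentError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)
            if it.category not in self.categories:
                raise InstrumentError(
                    f"item {it.item_id!r} has unknown category {it.category!r}"
                )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> FoodItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def food_group_map(self) -> FoodGroupMap:
        return FoodGroupMap({it.item_id: it.food_group for it in self.items})


@dataclass(frozen=True)
class ResponseSet:
    """One respondent's (frequency index, portion index) answer per item."""

    respondent_id: str
    instrument_name: str
    completion_date: date | None
    answers: Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a response set against its instrument."""

    missing_items: tuple[str, ...] = ()
    out_of_range: tuple[tuple[str, str], ...] = ()  # (item_id, description)
    unknown_items: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not (self.missing_items or self.out_of_range or self.unknown_items)


# ---------------------------------------------------------------------------
# Serialization: one documented YAML dialect with a schema-version field
# ---------------------------------------------------------------------------

def instrument_to_dict(instrument: Instrument) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "name": instrument.name,
        "categories": list(instrument.categories),
        "frequency_scale": [
            {"label": lbl, "per_day": mult}
            for lbl, mult in instrument.frequency_scale.categories
        ],
        "items": [
            {
                "item_id": it.item_id,
                "name": it.name,
                "category": it.category,
                "portion_options": list(it.portion_series.options),
                "portion_anchors": list(it.portion_series.anchors),
                "composition_ref": it.composition_ref,
                "food_group": it.food_group,
                "fixture": it.fixture,
            }
            for it in instrument.items
        ],
    }


def instrument_from_dict(data: Mapping) -> Instrument:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise InstrumentError(f"unsupported schema_version {version!r}")
    required = {"name", "categories", "frequency_scale", "items"}
    missing = required - set(data)
    if missing:
        raise InstrumentError(f"missing fields: {sorted(missing)}")
    scale = FrequencyScale(
        tuple((c["label"], float(c["per_day"])) for c in data["frequency_scale"])
    )
    items = []
    for raw in data["items"]:
        for key in ("item_id", "name", "category", "portion_options",
                    "portion_anchors", "composition_ref", "food_group"):
            if key not in raw:
                raise InstrumentError(
                    f"item {raw.get('item_id', '<unnamed>')!r} missing field {key!r}"
                )
        try:
            series = PortionSeries(
                tuple(float(o) for o in raw["portion_options"]),
                tuple(float(a) for a in raw["portion_anchors"]),  # type: ignore[arg-type]
            )
        except InstrumentError as exc:
            raise InstrumentError(f"item {raw['item_id']!r}: {exc}") from exc
        items.append(
            FoodItem(
                item_id=str(raw["item_id"]),
                name=str(raw["name"]),
                category=str(raw["category"]),
                portion_series=series,
                composition_ref=str(raw["composition_ref"]),
                food_group=str(raw["food_group"]),
                fixture=bool(raw.get("fixture", False)),
            )
        )
    return Instrument(
        name=str(data["name"]),
        items=tuple(items),
        categories=tuple(str(c) for c in data["categories"]),
        frequency_scale=scale,
    )


def save_instrument(instrument: Instrument, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(instrument_to_dict(instrument), sort_keys=False)
    )


def load_instrument(path: str | Path) -> Instrument:
    """Load and fully validate an instrument definition file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, Mapping):
        raise InstrumentError(f"{path} does not contain an instrument mapping")
    return instrument_from_dict(data)


# ---------------------------------------------------------------------------
# Response validation
# ---------------------------------------------------------------------------

def validate_response(instrument: Instrument, response: ResponseSet) -> ValidationReport:
    """Check a response set for completeness and index bounds.

    An empty report (``report.ok``) means the response is scoreable.
    Scoring a response against a different instrument than the one it was
    collected with is refused outright rather than reported.
    """
    if response.instrument_name != instrument.name:
        raise ResponseValidationError(
            f"response claims instrument {response.instrument_name!r}, "
            f"got {instrument.name!r}"
        )
    known = set(instrument.item_ids)
    missing = tuple(i for i in instrument.item_ids if i not in response.answers)
    unknown = tuple(sorted(set(response.answers) - known))
    out_of_range: list[tuple[str, str]] = []
    n_freq = len(instrument.frequency_scale)
    for item_id, (freq_idx, portion_idx) in response.answers.items():
        if item_id not in known:
            continue
        series = instrument.item(item_id).portion_series
        if not 0 <= freq_idx < n_freq:
            out_of_range.append(
                (item_id, f"frequency index {freq_idx} not in [0, {n_freq - 1}]")
            )
        if not 0 <= portion_idx < len(series):
            out_of_range.append(
                (item_id, f"portion index {portion_idx} not in [0, {len(series) - 1}]")
            )
    return ValidationReport(
        missing_items=missing,
        out_of_range=tuple(out_of_range),
        unknown_items=unknown,
    )


# ---------------------------------------------------------------------------
# Delimited-file I/O for responses and demographics
# ---------------------------------------------------------------------------

def read_responses(path: str | Path, instrument_name: str) -> list[ResponseSet]:
    """Read a long-format response table.

    Columns: respondent_id, item_id, frequency_category, portion_option
    (0-based indices) and optionally completion_date (ISO-8601).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"respondent_id", "item_id", "frequency_category", "portion_option"}
    missing = required - set(df.columns)
    if missing:
        raise InstrumentError(f"response table missing columns {sorted(missing)}")
    out = []
    for rid, grp in df.groupby("respondent_id", sort=True):
        answers = {
            str(r.item_id): (int(r.frequency_category), int(r.portion_option))
            for r in grp.itertuples()
        }
        cdate = None
        if "completion_date" in grp.columns:
            cdate = date.fromisoformat(str(grp["completion_date"].iloc[0]))
        out.append(ResponseSet(str(rid), instrument_name, cdate, answers))
    return out


def write_responses(responses: Iterable[ResponseSet], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for resp in responses:
        for item_id, (f_idx, p_idx) in resp.answers.items():
            rows.append(
                {
                    "respondent_id": resp.respondent_id,
                    "item_id": item_id,
                    "frequency_category": f_idx,
                    "portion_option": p_idx,
                    "completion_date": (
                        resp.completion_date.isoformat()
                        if resp.completion_date
                        else ""
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
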