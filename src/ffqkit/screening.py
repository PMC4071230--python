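"""Energy-plausibility screening and participant-flow exclusion filters.

Basal metabolic rate (BMR) is predicted from sex, age, weight and height
with the published Henry (Oxford) weight-and-height equations, shipped as a
versioned, checksummed coefficient file in MJ/day and converted to kcal at
239.005736 kcal/MJ.  The lowest plausible estimated energy requirement
(EER floor) is 1.1 x BMR; a respondent reporting energy intake strictly
below the floor is an under-reporter.

Cohort-level exclusions: a gap of strictly more than 28 days between the
two questionnaire administrations, or an online-instrument energy intake
strictly above a threshold (default 4500 kcal/day).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

KCAL_PER_MJ = 239.005736
EER_FLOOR_FACTOR = 1.1
DEFAULT_MAX_GAP_DAYS = 28
DEFAULT_ENERGY_MAX_KCAL = 4500.0

_HENRY_FILE = "henry_weight_height.csv"
_HENRY_SHA256 = "73ee2e8ebf78903a936de071e582a235249d589f2cfafe7e38c4cb68479eb05c"


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class Demographics:
    respondent_id: str
    sex: str                      # "male" | "female"
    age: float                    # years, >= 18 (study eligibility)
    weight: float                 # kg
    height: float                 # cm
    completion_dates: Mapping[str, date | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ScreeningError(f"unknown sex {self.sex!r}")
        if self.weight <= 0 or self.height <= 0:
            raise ScreeningError(
                f"respondent {self.respondent_id!r}: weight and height must be positive"
            )


@dataclass
class ScreeningResult:
    respondent_id: str
    bmr: float                       # kcal/day
    eer_floor: float                 # kcal/day, 1.1 x bmr
    under_reporter: dict[str, bool]  # per instrument
    exclusion_reasons: list[str]


def _load_henry_table() -> pd.DataFrame:
    ref = resources.files("ffqkit.data").joinpath(_HENRY_FILE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _HENRY_SHA256:
        raise ScreeningError(
            f"Henry coefficient file checksum mismatch ({digest})"
        )
    from io import StringIO

    return pd.read_csv(StringIO(raw.decode()), comment="#")


_HENRY_CACHE: pd.DataFrame | None = None


def henry_coefficients() -> pd.DataFrame:
    global _HENRY_CACHE
    if _HENRY_CACHE is None:
        _HENRY_CACHE = _load_henry_table()
    return _HENRY_CACHE


def bmr_henry(sex: str, age: float, weight_kg: float, height_cm: float) -> float:
    """Predicted BMR in kcal/day from the packaged coefficient table.

    Age bands are lower-inclusive; an age below the table's lowest band
    raises rather than extrapolating.
    """
    table = henry_coefficients()
    rows = table[table["sex"] == sex]
    if rows.empty:
        raise ScreeningError(f"unknown sex {sex!r}")
    band = rows[(rows["age_min"] <= age) & (age < rows["age_max"])]
    if band.empty:
        raise ScreeningError(
            f"age {age} outside the coefficient table's bands for {sex}"
        )
    row = band.iloc[0]
    mj = (
        row["w_coef"] * weight_kg
        + row["h_coef"] * (height_cm / 100.0)
        + row["intercept"]
    )
    return float(mj * KCAL_PER_MJ)


def classify_under_reporter(energy_intake_kcal: float, bmr_kcal: float) -> bool:
    """True iff reported energy is strictly below the EER floor (1.1 x BMR)."""
    if bmr_kcal <= 0:
        raise ScreeningError("BMR must be positive")
    if energy_intake_kcal <= 0:
        raise ScreeningError("energy intake must be positive")
    floor = EER_FLOOR_FACTOR * bmr_kcal
    # intake exactly at the floor is plausible; guard the strict inequality
    # against binary representation error in 1.1 * bmr
    import math

    if math.isclose(energy_intake_kcal, floor, rel_tol=1e-12):
        return False
    return energy_intake_kcal < floor


def screen_cohort(
    energy_by_instrument: Mapping[str, Mapping[str, float]],
    demographics: Iterable[Demographics],
) -> dict[str, ScreeningResult]:
    """Per-respondent BMR, EER floor and under-reporter flags per instrument."""
    out: dict[str, ScreeningResult] = {}
    for demo in demographics:
        bmr = bmr_henry(demo.sex, demo.age, demo.weight, demo.height)
        flags = {}
        for instrument_name, energies in energy_by_instrument.items():
            if demo.respondent_id in energies:
                flags[instrument_name] = classify_under_reporter(
                    energies[demo.respondent_id], bmr
                )
        out[demo.respondent_id] = ScreeningResult(
            respondent_id=demo.respondent_id,
            bmr=bmr,
            eer_floor=EER_FLOOR_FACTOR * bmr,
            under_reporter=flags,
            exclusion_reasons=[],
        )
    return out


def under_reporter_concordance(
    results: Mapping[str, ScreeningResult], online: str, printed: str
) -> float:
    """Fraction of online under-reporters also flagged by the printed FFQ."""
    flagged = [
        r for r in results.values() if r.under_reporter.get(online, False)
    ]
    if not flagged:
        return float("nan")
    both = sum(1 for r in flagged if r.under_reporter.get(printed, False))
    return both / len(flagged)


@dataclass
class ExclusionConfig:
    max_gap_days: int | float = DEFAULT_MAX_GAP_DAYS
    energy_max_kcal: float = DEFAULT_ENERGY_MAX_KCAL
    energy_filter_instruments: tuple[str, ...] = ("online",)  # which intakes screened


def apply_exclusions(
    completion_dates: Mapping[str, Mapping[str, date | None]],
    energy_by_instrument: Mapping[str, Mapping[str, float]],
    config: ExclusionConfig | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Participant-flow filters; returns (retained ids, exclusion log).

    * ``gap_gt_4_weeks``: strictly more than ``max_gap_days`` (default 28)
      days between the two administrations; a gap of exactly 28 days is
      retained.
    * ``energy_gt_threshold``: energy strictly above ``energy_max_kcal`` on
      any instrument listed in ``energy_filter_instruments``.
    * ``incomplete``: a missing completion date — excluded with an explicit
      reason, never silently dropped.

    The retained list preserves the input iteration order; the filter is
    idempotent.
    """
    cfg = config or ExclusionConfig()
    retained: list[str] = []
    log: dict[str, list[str]] = {}
    for rid, dates in completion_dates.items():
        reasons: list[str] = []
        ds = list(dates.values())
        if len(ds) < 2 or any(d is None for d in ds):
            reasons.append("incomplete")
        else:
            gap = abs((ds[0] - ds[1]).days)
            if gap > cfg.max_gap_days:
                reasons.append("gap_gt_4_weeks")
        for instrument_name in cfg.energy_filter_instruments:
            energy = energy_by_instrument.get(instrument_name, {}).get(rid)
            if energy is not None and energy > cfg.energy_max_kcal:
                reasons.append("energy_gt_threshold")
                break
        if reasons:
            log[rid] = reasons
        else:
            retained.append(rid)
    return retained, log
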