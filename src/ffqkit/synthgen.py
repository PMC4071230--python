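"""Synthetic inputs for the whole pipeline, with known ground truth.

Two generators cover everything the other modules consume:

* :func:`generate_consumption_survey` emulates a national-survey extract —
  per-respondent consumption records (grams/day, lognormal) mapped onto
  questionnaire items, each item backed by several candidate survey foods
  with distinct occurrence counts and per-100 g composition vectors.
* :func:`generate_paired_responses` emulates the paired study design: each
  respondent holds latent true daily gram intakes per item; each instrument
  observes ``bias x truth x lognormal noise`` and the response is the
  (frequency, portion) pair whose product is nearest the observation in log
  space (ties to the lower option).  A configurable fraction of respondents
  is scaled below their estimated-energy-requirement floor to act as
  under-reporters.

Everything is driven by one :class:`numpy.random.Generator` seed: identical
spec + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .derivation import (
    NUTRIENTS,
    CompositionTable,
    ConsumptionRecord,
    FoodCompositionEntry,
)
from .instrument import Instrument, ResponseSet
from .screening import EER_FLOOR_FACTOR, Demographics, bmr_henry


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a paired synthetic cohort.

    Defaults emulate a plausible adult convenience cohort: every item is a
    candidate for consumption with probability ``consumption_prob``; a
    consumed item's true daily grams are lognormal with median
    ``portion_rate x medium portion`` (``portion_rate`` = 0.15 events/day,
    i.e. roughly once a week at the medium portion) and log-scale spread
    ``latent_sigma``.  Reporting error is multiplicative lognormal with
    log-scale ``noise_sd`` per instrument on top of a method-level
    multiplicative ``bias``.
    """

    n_respondents: int
    bias_a: float = 1.0
    bias_b: float = 1.0
    noise_sd: float = 0.2
    under_reporter_fraction: float = 0.0
    consumption_prob: float = 0.5
    portion_rate: float = 0.15
    latent_sigma: float = 0.6
    max_gap_days: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_a <= 0 or self.bias_b <= 0:
            raise SynthError("method biases must be > 0")
        for frac in (self.under_reporter_fraction, self.consumption_prob):
            if not 0.0 <= frac <= 1.0:
                raise SynthError("fractions must lie in [0, 1]")
        if self.n_respondents < 0:
            raise SynthError("n_respondents must be >= 0")


# ---------------------------------------------------------------------------
# Plausible per-100 g nutrient vectors
# ---------------------------------------------------------------------------

def _nutrient_vector(rng: np.random.Generator, allow_alcohol: bool = True) -> dict:
    """One plausible per-100 g composition; energy 80-300 kcal/100 g."""
    energy = float(rng.uniform(80.0, 300.0))
    alcohol_share = float(rng.uniform(0.05, 0.3)) if (
        allow_alcohol and rng.random() < 0.08
    ) else 0.0
    shares = rng.dirichlet([2.0, 3.5, 1.5])  # fat, carbohydrate, protein
    shares = shares * (1.0 - alcohol_share)
    fat_g = shares[0] * energy / 9.0
    carb_g = shares[1] * energy / 3.75
    protein_g = shares[2] * energy / 4.0
    alcohol_g = alcohol_share * energy / 7.0
    fa = rng.dirichlet([2.0, 2.0, 1.0])  # SFA/MUFA/PUFA split of total fat
    retinol = float(rng.uniform(0.0, 150.0))
    carotene = float(rng.uniform(0.0, 1500.0))
    sodium = float(rng.uniform(10.0, 600.0))
    return {
        "energy_kcal": energy,
        "fat_g": fat_g,
        "sfa_g": fat_g * fa[0],
        "mufa_g": fat_g * fa[1],
        "pufa_g": fat_g * fa[2],
        "protein_g": protein_g,
        "carbohydrate_g": carb_g,
        "total_sugars_g": carb_g * float(rng.uniform(0.1, 0.8)),
        "alcohol_g": alcohol_g,
        "calcium_mg": float(rng.uniform(5.0, 300.0)),
        "folate_ug": float(rng.uniform(2.0, 80.0)),
        "iron_mg": float(rng.uniform(0.1, 4.0)),
        "carotene_ug": carotene,
        "riboflavin_mg": float(rng.uniform(0.01, 0.5)),
        "thiamin_mg": float(rng.uniform(0.01, 0.5)),
        "vitamin_b6_mg": float(rng.uniform(0.01, 0.6)),
        "vitamin_b12_ug": float(rng.uniform(0.0, 2.0)),
        "vitamin_c_mg": float(rng.uniform(0.0, 60.0)),
        "vitamin_a_re_ug": retinol + carotene / 6.0,
        "retinol_ug": retinol,
        "vitamin_d_ug": float(rng.uniform(0.0, 3.0)),
        "vitamin_e_mg": float(rng.uniform(0.0, 3.0)),
        "sodium_mg": sodium,
        "salt_g": sodium * 2.5 / 1000.0,
    }


def generate_composition_table(
    instrument: Instrument, seed: int = 0
) -> CompositionTable:
    """Plausible per-item composition table for a (fixture) instrument."""
    rng = np.random.default_rng(seed)
    table = CompositionTable()
    for item in instrument.items:
        vec = _nutrient_vector(rng, allow_alcohol=item.category == "drinks")
        table.values[item.composition_ref] = np.array(
            [vec[k] for k in NUTRIENTS], dtype=float
        )
        table.provenance[item.composition_ref] = (f"synthetic:{item.item_id}",)
    return table


# ---------------------------------------------------------------------------
# Consumption-survey emulation
# ---------------------------------------------------------------------------

def generate_consumption_survey(
    instrument: Instrument,
    n_respondents: int = 500,
    foods_per_item: int = 5,
    amount_median: float = 80.0,
    amount_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[list[ConsumptionRecord], list[FoodCompositionEntry]]:
    """Survey records + survey-food compositions for every instrument item.

    Each item gets ``foods_per_item`` candidate foods with pairwise-distinct
    occurrence counts; record amounts are lognormal with the configured
    median.  ``n_respondents = 0`` yields empty tables.
    """
    rng = np.random.default_rng(seed)
    records: list[ConsumptionRecord] = []
    foods: list[FoodCompositionEntry] = []
    if n_respondents == 0:
        return records, foods
    for item in instrument.items:
        counts = rng.choice(
            np.arange(3, 3 + 10 * foods_per_item), size=foods_per_item, replace=False
        )
        counts = np.sort(counts)[::-1]
        for j, count in enumerate(counts):
            code = f"{item.item_id}_f{j + 1}"
            foods.append(FoodCompositionEntry(code, _nutrient_vector(rng)))
            respondents = rng.integers(0, n_respondents, size=int(count))
            amounts = rng.lognormal(np.log(amount_median), amount_sigma, int(count))
            for rid, amount in zip(respondents, amounts):
                records.append(
                    ConsumptionRecord(
                        respondent_id=f"r{rid:05d}",
                        food_code=code,
                        item_id=item.item_id,
                        amount=float(amount),
                    )
                )
    return records, foods


# ---------------------------------------------------------------------------
# Paired questionnaire administrations
# ---------------------------------------------------------------------------

def _quantization_grid(instrument: Instrument, item_id: str):
    """Nonzero (frequency x portion) products sorted ascending, with indices."""
    item = instrument.item(item_id)
    mults = np.asarray(instrument.frequency_scale.multipliers[1:])
    opts = np.asarray(item.portion_series.options)
    prods = np.outer(mults, opts).ravel()
    f_idx = np.repeat(np.arange(1, len(mults) + 1), len(opts))
    p_idx = np.tile(np.arange(len(opts)), len(mults))
    order = np.argsort(prods, kind="stable")
    return prods[order], f_idx[order], p_idx[order]


def _quantize(observed: np.ndarray, grid) -> tuple[np.ndarray, np.ndarray]:
    """Nearest representable intake in log space; ties to the lower option.

    Observations below half the smallest representable intake map to
    "never" (frequency index 0, portion index 0), as do exact zeros.
    """
    products, f_idx, p_idx = grid
    f_out = np.zeros(len(observed), dtype=int)
    p_out = np.zeros(len(observed), dtype=int)
    mask = observed >= products[0] / 2.0
    if mask.any():
        dist = np.abs(
            np.log(observed[mask])[:, None] - np.log(products)[None, :]
        )
        best = np.argmin(dist, axis=1)  # first minimum = smallest product on ties
        f_out[mask] = f_idx[best]
        p_out[mask] = p_idx[best]
    return f_out, p_out


@dataclass
class SimulatedCohort:
    """Everything :func:`generate_paired_responses` produced."""

    responses_a: list[ResponseSet]
    responses_b: list[ResponseSet]
    demographics: list[Demographics]
    composition_a: CompositionTable
    composition_b: CompositionTable
    truth: pd.DataFrame            # latent true grams/day, respondent x item
    under_reporter_ids: tuple[str, ...]


def generate_paired_responses(
    spec: CohortSpec,
    instrument_a: Instrument,
    instrument_b: Instrument,
    seed: int | None = None,
) -> SimulatedCohort:
    """Paired response sets + demographics under the cohort spec.

    Method A (printed reference) observes ``bias_a x truth x noise``;
    method B (online) likewise with ``bias_b``.  Designated under-reporters
    have each method's observations scaled to land well below their EER
    floor before quantization.
    """
    for inst in (instrument_a, instrument_b):
        if inst.frequency_scale.multipliers[0] != 0.0:
            raise SynthError(
                f"instrument {inst.name!r} lacks a 'never' category"
            )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_respondents
    ids = [f"r{i:05d}" for i in range(n)]

    # demographics: balanced sexes, plausible adult anthropometry
    sexes = np.array(["male", "female"])[rng.permutation(n) % 2]
    ages = rng.uniform(18.0, 60.0, n)
    weights = np.where(
        sexes == "male", rng.normal(77.0, 11.0, n), rng.normal(62.0, 9.0, n)
    ).clip(min=40.0)
    heights = np.where(
        sexes == "male", rng.normal(178.0, 7.0, n), rng.normal(165.0, 6.0, n)
    ).clip(min=140.0)
    base = date(2012, 5, 1)
    starts = rng.integers(0, 60, n)
    gaps = rng.integers(0, spec.max_gap_days + 1, n)

    # latent truth per union item
    union_ids = sorted(set(instrument_a.item_ids) | set(instrument_b.item_ids))
    ref = {
        i: (instrument_a if i in set(instrument_a.item_ids) else instrument_b)
        for i in union_ids
    }
    medians = np.array(
        [spec.portion_rate * ref[i].item(i).portion_series.anchors[1]
         for i in union_ids]
    )
    consumed = rng.random((n, len(union_ids))) < spec.consumption_prob
    truth = np.where(
        consumed,
        rng.lognormal(np.log(medians)[None, :], spec.latent_sigma, (n, len(union_ids))),
        0.0,
    )
    truth_df = pd.DataFrame(truth, index=ids, columns=union_ids)

    composition_a = generate_composition_table(instrument_a, seed=int(rng.integers(2**31)))
    seed_b = int(rng.integers(2**31))
    if set(instrument_b.item_ids) == set(instrument_a.item_ids):
        # identical food lists share one composition, so identical
        # instruments form an exact fixed point under zero noise/bias
        composition_b = composition_a
    else:
        composition_b = generate_composition_table(instrument_b, seed=seed_b)

    col_of = {item_id: j for j, item_id in enumerate(union_ids)}
    n_ur = int(round(spec.under_reporter_fraction * n))
    ur_rows = rng.choice(n, size=n_ur, replace=False) if n_ur else np.array([], dtype=int)
    ur_ids = tuple(ids[r] for r in sorted(ur_rows))
    eer_floor = np.array(
        [
            EER_FLOOR_FACTOR
            * bmr_henry(sexes[r], float(ages[r]), float(weights[r]), float(heights[r]))
            for r in range(n)
        ]
    ) if n else np.zeros(0)

    def administer(instrument, bias, composition):
        cols = [col_of[i] for i in instrument.item_ids]
        observed = truth[:, cols] * bias * np.exp(
            rng.normal(0.0, spec.noise_sd, (n, len(cols)))
        )
        observed[truth[:, cols] == 0.0] = 0.0
        grids = {i: _quantization_grid(instrument, i) for i in instrument.item_ids}
        energy_density = np.array(
            [
                composition.nutrient(instrument.item(i).composition_ref, "energy_kcal")
                for i in instrument.item_ids
            ]
        )

        def quantize_all(obs):
            f = np.zeros_like(obs, dtype=int)
            p = np.zeros_like(obs, dtype=int)
            for j, item_id in enumerate(instrument.item_ids):
                f[:, j], p[:, j] = _quantize(obs[:, j], grids[item_id])
            return f, p

        f, p = quantize_all(observed)
        if len(ur_rows):
            # scored energy from the quantized answers, then rescale and redo
            mults = np.asarray(instrument.frequency_scale.multipliers)
            grams = np.zeros_like(observed)
            for j, item_id in enumerate(instrument.item_ids):
                opts = np.asarray(instrument.item(item_id).portion_series.options)
                grams[:, j] = mults[f[:, j]] * opts[p[:, j]]
            energy = grams @ (energy_density / 100.0)
            for r in ur_rows:
                if energy[r] <= 0:
                    continue
                factor = 0.75 * eer_floor[r] / energy[r]
                if factor < 1.0:
                    scaled = observed[r][None, :] * factor
                    f[r], p[r] = (a[0] for a in quantize_all(scaled))
        return f, p

    f_a, p_a = administer(instrument_a, spec.bias_a, composition_a)
    f_b, p_b = administer(instrument_b, spec.bias_b, composition_b)

    responses_a, responses_b, demographics = [], [], []
    for r, rid in enumerate(ids):
        date_a = base + timedelta(days=int(starts[r]))
        date_b = date_a + timedelta(days=int(gaps[r]))
        responses_a.append(
            ResponseSet(
                rid, instrument_a.name, date_a,
                {
                    item_id: (int(f_a[r, j]), int(p_a[r, j]))
                    for j, item_id in enumerate(instrument_a.item_ids)
                },
            )
        )
        responses_b.append(
            ResponseSet(
                rid, instrument_b.name, date_b,
                {
                    item_id: (int(f_b[r, j]), int(p_b[r, j]))
                    for j, item_id in enumerate(instrument_b.item_ids)
                },
            )
        )
        demographics.append(
            Demographics(
                respondent_id=rid,
                sex=str(sexes[r]),
                age=float(ages[r]),
                weight=float(weights[r]),
                height=float(heights[r]),
                completion_dates={
                    instrument_a.name: date_a,
                    instrument_b.name: date_b,
                },
            )
        )
    return SimulatedCohort(
        responses_a=responses_a,
        responses_b=responses_b,
        demographics=demographics,
        composition_a=composition_a,
        composition_b=composition_b,
        truth=truth_df,
        under_reporter_ids=ur_ids,
    )
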