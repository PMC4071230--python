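# Methods

## Instrument model

An instrument is a fixed list of food items in display categories, one
shared frequency scale, and a per-item portion series. The packaged online
instrument has 157 items in 11 categories; the packaged printed reference
has 130 items forming a strict subset (the online instrument adds 27
items). Item *names* in these fixtures are placeholders (`fixture=True`):
no public enumeration of the food lists exists, so the fixtures carry the
documented structure — counts, categories, scale, series, 35-label food
group map — rather than real food names. The per-category item counts
(summing to 157/130) are a one-time plausible allocation.

The 9-level frequency scale maps each category to events/day by the
midpoint-of-range convention: never = 0; 1–3/month = 2/30.44 ≈ 0.0657;
1/week = 1/7; 2–4/week = 3/7; 5–6/week = 5.5/7; 1/day = 1; 2–3/day = 2.5;
4–5/day = 4.5; 6+/day = 6. The open-ended top category is scored as exactly
6 events/day; the whole scale is overridable in the instrument file, which
is YAML with an explicit `schema_version` so that load → save → load
round-trips field-for-field.

Response sets must be complete (one frequency and one portion per item),
mirroring the online delivery that refuses submission otherwise;
`validate_response` returns the offending items and is empty exactly when
`score_response` succeeds.

## Derivation from consumption surveys

"Most frequently consumed" is interpreted as the number of consumption
records (eating occurrences), not total grams; ties break lexicographically
by food code so the selection is deterministic. The per-item composition is
the unweighted arithmetic mean of the top-3 foods' per-100 g vectors (all
foods when fewer than 3 exist); provenance records the codes used. The
nutrient panel is fixed: energy plus 23 nutrients (macronutrients, sugars,
alcohol, and the standard micronutrient set including retinol equivalents
and salt).

Portion anchors use linear interpolation between order statistics (the
numpy default quantile rule), computed by default on per-respondent daily
totals with a per-occasion switch. The 7-option series is
`[0.5·p25, p25, (p25+p50)/2, p50, (p50+p75)/2, p75, 1.5·p75]`, rounded to
0.1 g. When the anchors coincide (constant intake c) the series falls back
to the multiplicative grid `{0.5, 0.75, 0.9, 1, 1.1, 1.25, 1.5}·c`, which
preserves 7 ordered options with the observed value as every anchor.

## Scoring

Scoring is a linear map from (frequency multiplier × portion grams) to
nutrients and food groups; energy is read from the composition table's
energy field rather than recomputed from macronutrients, matching how
composition databases are used. %TE factors are fat (and fatty-acid
subclasses) 9, protein 4, carbohydrate 3.75 (the UK
monosaccharide-equivalent convention), alcohol 7 kcal/g, overridable. When
energy is zero the %TE fields are NaN — undefined, never 0. Dietary-habit
add-ons (added salt, fried food, supplements) are out of scope and never
scored.

## Screening

BMR comes from the published Henry (Oxford) weight-and-height adult
equations, shipped as a versioned CSV (MJ/day per sex and age band,
sha256-checked at load) and converted at 239.005736 kcal/MJ. Age bands are
lower-inclusive; ages below the lowest band raise rather than extrapolate.
The under-reporter rule is strict: intake < 1.1 × BMR. The strictness is
guarded against binary representation error in `1.1 × BMR` (relative
tolerance 1e-12), so an intake exactly at the floor is never flagged.
Under-reporting is evaluated per instrument, and the concordance (fraction
of online under-reporters also flagged by the printed instrument) is a
built-in report.

Cohort filters: completion gap strictly greater than 28 days ("more than 4
weeks" read literally, so exactly 28 days is retained), and energy strictly
above 4500 kcal/day on the online instrument only by default (the filter's
instrument set is configurable). Missing dates yield an explicit
`incomplete` reason; the filter is idempotent and order-stable.

## Agreement statistics

* **Bland–Altman**: differences are printed − online, plotted against the
  pair mean; limits are mean ± k·SD with the literal k = 2 default (not
  1.96) and the n−1 sample SD. Zero-variance differences collapse the
  limits onto the mean with 100% within — documented, not an error.
  Comparability requires strictly more than 95% of pairs within the limits.
* **Cross-classification**: values are ranked with average ranks on ties
  and cut at ranks n/4, n/2, 3n/4 (upper-inclusive). Four mutually
  exclusive bins |Δq| ∈ {0,1,2,3} are reported along with the combined
  "≥ 2 apart" figure, because "disagreement" is used in the field both for
  exactly-2-apart and for 2-or-more-apart. Heavy ties that empty a stratum
  raise, naming the variable.
* **Correlations**: Spearman by default for food groups, with Pearson
  available; zero variance raises.
* **Adjusted comparison**: OLS of intake on a two-level method factor plus
  energy (and center/gender/randomization where present), rows treated as
  independent observations — no respondent random effect, matching a
  GLM-with-covariates analysis; the paired structure is therefore ignored
  and p-values are conservative about it. Covariates with zero variance
  are dropped before fitting, so with constant energy the estimate reduces
  exactly to the between-method mean difference; genuinely collinear
  columns raise, naming them. Method × covariate interaction p-values are
  reported on request.
* **Food-group t-test**: Welch by default (pooled-variance mode available).

`compare_instruments` orchestrates all of the above over aligned intake
tables: per-nutrient adjusted comparison (energy itself is excluded — it is
the adjustment variable), correlations and cross-classification; per-group
t-test, Spearman, cross-classification and Bland–Altman; a dedicated
Bland–Altman panel for energy and macronutrients in grams and %TE; and
under-reporter concordance. Variables whose statistics are undefined (zero
variance, undefined %TE) appear with empty cells rather than aborting the
report.

## Synthetic cohorts

The generator emulates the paired validation design. Each respondent holds
latent true daily grams per item: consumed with probability 0.5, and, when
consumed, lognormal with median 0.15 × the item's medium portion
(≈ weekly consumption at the pictured medium serving) and log-SD 0.6.
Each instrument observes bias × truth × lognormal noise (log-SD 0.2 by
default) and answers with the (frequency, portion) pair whose product is
nearest in log space, ties to the lower option; observations below half the
smallest representable nonzero intake map to "never". Demographics are
plausible, not fitted: balanced sexes, age uniform 18–60, weight/height
from sex-specific normals consistent with adult European cohorts.
Designated under-reporters have their observations rescaled to 0.75 × their
EER floor before re-quantization, so they land clearly below the floor
despite grid granularity. With these defaults mean scored energy sits near
2400–2600 kcal/day, comfortably above typical EER floors (~1700–1900), so
false-positive under-reporting is rare and an injected under-reporter
fraction is recovered closely.

Identical instruments share one composition table, making
zero-noise/unit-bias simulation an exact fixed point (identical scored
intakes, 100% exact cross-classification). Distinct instruments get
independent composition tables, emulating two instruments backed by
different composition databases.

What the generator does not emulate: food-level dietary realism (items are
exchangeable), intra-individual day-to-day variation, correlated item
preferences, seasonal effects, or differential item-response behaviour
between modes. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic and statistics are correct under a known measurement
model, not that either instrument is valid on real diets.

## Problem sizes and numerics

Simulation-based tests use 400–2,000 respondents on the full 157-item
instrument and 10,000–100,000 pairs for the distributional checks on
Bland–Altman coverage (normal differences give ≈ 95.45% within ±2 SD) and
the cross-classification independence null (25% exact agreement); these
sizes give Monte-Carlo error well inside the asserted tolerances. All
randomness flows from single `numpy.random.default_rng` seeds; identical
seed and spec give byte-identical outputs. Oracle tests against hand
formulas assert to 1e-10.

## Known limitations

* Fixture instruments carry structure, not real food lists; scored outputs
  on them are synthetic by construction.
* The adjusted comparison ignores pairing (by design, see above); a
  mixed-model variant would be the natural extension.
* The Henry coefficient file ships adult bands only (18+); child bands are
  out of the instrument's eligibility range and deliberately absent.
* The 4500 kcal/day ceiling applies to the online instrument by default;
  whether a printed-instrument ceiling is wanted is study-specific and
  configurable.
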