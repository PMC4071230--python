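"""Paired-method agreement statistics for two dietary instruments.

The convention throughout is ``diff = x - y`` where *x* is the printed
reference instrument and *y* the online instrument, plotted against the
pair mean ``(x + y) / 2``.  Limits of agreement are ``mean(diff) +/- k *
SD(diff)`` with the literal ``k = 2`` default and the n-1 sample SD; the
two methods are called *comparable* when strictly more than 95% of pairs
lie within the limits.

Quartile cross-classification ranks each method's values (average ranks on
ties) and cuts at ranks n/4, n/2, 3n/4 (upper-inclusive); agreement is
binned by the absolute quartile difference 0/1/2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LOA_SD_FACTOR = 2.0
COMPARABLE_PCT_WITHIN = 95.0


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSeries:
    """Aligned per-respondent values from two instruments for one variable."""

    ids: tuple[str, ...]
    x: np.ndarray  # printed / reference method
    y: np.ndarray  # online method
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(self.ids) == len(x) == len(y)):
            raise AgreementError("ids, x, y must be aligned")
        if len(x) < 3:
            raise AgreementError("need at least 3 pairs")
        if np.isnan(x).any() or np.isnan(y).any():
            raise AgreementError(f"missing values in paired series {self.label!r}")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class BlandAltmanResult:
    mean_diff: float           # bias, x - y units
    sd_diff: float             # n-1 sample SD of the differences
    loa_low: float
    loa_high: float
    n: int
    n_outside: int             # strictly outside [loa_low, loa_high]
    pct_within: float
    comparable: bool           # pct_within > 95
    means: np.ndarray = field(repr=False, default=None)  # (x+y)/2, for plotting
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(pairs: PairedSeries, k_sd: float = DEFAULT_LOA_SD_FACTOR) -> BlandAltmanResult:
    """Limits-of-agreement analysis of ``x - y`` against ``(x + y) / 2``.

    Zero-variance differences collapse the limits onto the mean and give
    100% within (documented, not an error).
    """
    diffs = pairs.x - pairs.y
    means = (pairs.x + pairs.y) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    low, high = bias - k_sd * sd, bias + k_sd * sd
    outside = int(np.sum((diffs < low) | (diffs > high)))
    pct_within = 100.0 * (len(diffs) - outside) / len(diffs)
    return BlandAltmanResult(
        mean_diff=bias,
        sd_diff=sd,
        loa_low=low,
        loa_high=high,
        n=len(diffs),
        n_outside=outside,
        pct_within=pct_within,
        comparable=pct_within > COMPARABLE_PCT_WITHIN,
        means=means,
        diffs=diffs,
    )


@dataclass
class CrossClassResult:
    counts: np.ndarray            # n_strata x n_strata quartile pair counts
    pct_exact: float              # same stratum
    pct_adjacent_only: float      # exactly 1 apart
    pct_exact_plus_adjacent: float
    pct_two_apart: float          # "disagreement" in the 4x4 convention
    pct_extreme: float            # opposite extreme strata (3 apart)
    pct_disagreement_combined: float  # >= 2 apart


def _strata(values: np.ndarray, n_strata: int, label: str) -> np.ndarray:
    """Rank-based stratum index (1..n_strata), average ranks on ties,
    cuts at ranks n/4, n/2, 3n/4 ... upper-inclusive."""
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    edges = np.array([n * (i + 1) / n_strata for i in range(n_strata - 1)])
    idx = np.searchsorted(edges, ranks, side="left") + 1  # rank <= edge -> stratum
    counts = np.bincount(idx, minlength=n_strata + 1)[1:]
    if (counts == 0).any():
        raise AgreementError(
            f"ties too heavy to form {n_strata} strata for {label!r}"
        )
    return idx


def cross_classify(pairs: PairedSeries, n_strata: int = 4) -> CrossClassResult:
    """Quartile (or n-strata) cross-classification of the two methods."""
    if len(pairs) < n_strata:
        raise AgreementError("need at least n_strata pairs")
    qx = _strata(pairs.x, n_strata, pairs.label)
    qy = _strata(pairs.y, n_strata, pairs.label)
    counts = np.zeros((n_strata, n_strata), dtype=int)
    for a, b in zip(qx, qy):
        counts[a - 1, b - 1] += 1
    n = len(pairs)
    delta = np.abs(qx - qy)
    pct = lambda m: 100.0 * float(np.sum(m)) / n
    exact = pct(delta == 0)
    adjacent = pct(delta == 1)
    two = pct(delta == 2)
    extreme = pct(delta == n_strata - 1) if n_strata > 2 else 0.0
    return CrossClassResult(
        counts=counts,
        pct_exact=exact,
        pct_adjacent_only=adjacent,
        pct_exact_plus_adjacent=exact + adjacent,
        pct_two_apart=two,
        pct_extreme=extreme,
        pct_disagreement_combined=pct(delta >= 2),
    )


def correlations(
    pairs: PairedSeries, kind: Literal["pearson", "spearman"] = "spearman"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value between the methods."""
    if np.std(pairs.x) == 0 or np.std(pairs.y) == 0:
        raise AgreementError(f"zero variance in paired series {pairs.label!r}")
    if kind == "pearson":
        res = stats.pearsonr(pairs.x, pairs.y)
    elif kind == "spearman":
        res = stats.spearmanr(pairs.x, pairs.y)
    else:
        raise AgreementError(f"unknown correlation kind {kind!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class AdjustedComparisonResult:
    method_effect: float     # coefficient for method B relative to method A
    p_value: float
    interaction_p: dict[str, float]  # method x covariate interaction p-values
    model: object = field(repr=False, default=None)


def adjusted_comparison(
    long_table: pd.DataFrame,
    outcome: str = "intake",
    covariates: Sequence[str] = ("energy",),
    check_interactions: bool = True,
) -> AdjustedComparisonResult:
    """Energy-adjusted between-method comparison by ordinary least squares.

    ``long_table`` stacks both instruments' values with a two-level
    ``method`` factor and covariate columns (energy and, where present,
    center, gender, randomization).  Rows are treated as independent
    observations.  Covariates with zero variance are dropped before the
    fit; genuinely collinear columns raise, naming them.
    """
    import statsmodels.formula.api as smf

    if "method" not in long_table.columns:
        raise AgreementError("long table needs a 'method' column")
    levels = sorted(long_table["method"].unique())
    if len(levels) != 2:
        raise AgreementError(f"method must have exactly 2 levels, got {levels}")
    df = long_table.copy()
    df = df.rename(columns={outcome: "_y"})
    kept: list[str] = []
    for cov in covariates:
        if cov not in df.columns:
            raise AgreementError(f"missing covariate column {cov!r}")
        if df[cov].nunique() > 1:
            kept.append(cov)
    def term(c):
        numeric = pd.api.types.is_numeric_dtype(df[c]) and df[c].dtype != bool
        return c if numeric else f"C({c})"
    rhs = " + ".join(["C(method)"] + [term(c) for c in kept]) or "C(method)"
    model = smf.ols(f"_y ~ {rhs}", data=df).fit()
    design_rank = np.linalg.matrix_rank(model.model.exog)
    if design_rank < model.model.exog.shape[1]:
        exog = model.model.exog
        names = model.model.exog_names
        bad = [
            names[j]
            for j in range(exog.shape[1])
            if np.linalg.matrix_rank(np.delete(exog, j, axis=1)) == design_rank
        ]
        raise AgreementError(f"rank-deficient design; collinear columns: {bad}")
    coef_name = next(n for n in model.params.index if n.startswith("C(method)"))
    interaction_p: dict[str, float] = {}
    if check_interactions and kept:
        for cov in kept:
            rhs_i = rhs + f" + C(method):{term(cov)}"
            m_i = smf.ols(f"_y ~ {rhs_i}", data=df).fit()
            ip = [
                float(m_i.pvalues[n])
                for n in m_i.pvalues.index
                if n.startswith("C(method)") and ":" in n
            ]
            interaction_p[cov] = min(ip) if ip else float("nan")
    return AdjustedComparisonResult(
        method_effect=float(model.params[coef_name]),
        p_value=float(model.pvalues[coef_name]),
        interaction_p=interaction_p,
        model=model,
    )


def group_ttest(
    pairs: PairedSeries, equal_var: bool = False
) -> tuple[float, float, float]:
    """Independent two-sample t-test between the two methods' samples.

    Welch (unequal variances) by default; returns (t, df, p).
    """
    if len(pairs.x) < 2 or len(pairs.y) < 2:
        raise AgreementError("each side needs n >= 2")
    if np.var(pairs.x, ddof=1) == 0 and np.var(pairs.y, ddof=1) == 0:
        raise AgreementError("zero variance on both sides")
    res = stats.ttest_ind(pairs.x, pairs.y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Full two-instrument report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    nutrients: pd.DataFrame     # per nutrient: adjusted comparison, corr, cross-class
    food_groups: pd.DataFrame   # per group: t-test, corr, cross-class, Bland-Altman
    macronutrient_ba: pd.DataFrame  # Bland-Altman on grams and %TE
    bland_altman_points: dict[str, pd.DataFrame]  # plot-ready (mean, diff) per variable
    under_reporter_concordance: float = float("nan")


#: Macronutrient columns carried into the dedicated Bland-Altman panel.
MACRO_BA_COLUMNS: tuple[str, ...] = (
    "energy_kcal",
    "fat_g", "fat_pct_te",
    "protein_g", "protein_pct_te",
    "carbohydrate_g", "carbohydrate_pct_te",
)


def _paired(intakes_a: pd.DataFrame, intakes_b: pd.DataFrame, col: str) -> PairedSeries:
    return PairedSeries(
        ids=tuple(str(i) for i in intakes_a.index),
        x=intakes_a[col].to_numpy(dtype=float),
        y=intakes_b[col].to_numpy(dtype=float),
        label=col,
    )


def compare_instruments(
    intakes_a: pd.DataFrame,
    intakes_b: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    correlation_kind: Literal["pearson", "spearman"] = "spearman",
    under_reporter_flags: pd.DataFrame | None = None,
    k_sd: float = DEFAULT_LOA_SD_FACTOR,
) -> AgreementReport:
    """Run the full two-instrument comparison on screened, aligned intakes.

    ``intakes_a`` (printed reference) and ``intakes_b`` (online) are wide
    tables from :func:`ffqkit.scoring.score_all` indexed by respondent, with
    identical respondent sets and columns.
    """
    ids_a, ids_b = set(intakes_a.index), set(intakes_b.index)
    if ids_a != ids_b:
        raise AgreementError(
            f"misaligned respondent sets; symmetric difference: "
            f"{sorted(ids_a ^ ids_b)}"
        )
    intakes_b = intakes_b.loc[intakes_a.index]

    from .derivation import NUTRIENTS

    nutrient_cols = [c for c in intakes_a.columns
                     if c in NUTRIENTS or c.endswith("_pct_te")]
    group_cols = [c for c in intakes_a.columns if c.startswith("group:")]

    energy_long = np.concatenate(
        [intakes_a["energy_kcal"].to_numpy(), intakes_b["energy_kcal"].to_numpy()]
    )
    method_col = ["A"] * len(intakes_a) + ["B"] * len(intakes_b)

    def safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except AgreementError:
            return None

    nut_rows = []
    for col in nutrient_cols:
        try:
            pairs = _paired(intakes_a, intakes_b, col)
        except AgreementError:
            nut_rows.append({"variable": col})
            continue
        row: dict[str, float | str] = {"variable": col}
        if col != "energy_kcal":  # energy is the adjustment variable itself
            long = pd.DataFrame(
                {
                    "intake": np.concatenate([pairs.x, pairs.y]),
                    "method": method_col,
                    "energy": energy_long,
                }
            )
            adj = safe(adjusted_comparison, long, check_interactions=False)
            if adj is not None:
                row["method_effect"] = adj.method_effect
                row["p_adjusted"] = adj.p_value
        corr = safe(correlations, pairs, correlation_kind)
        if corr is not None:
            row["correlation"], row["corr_p"] = corr
        cc = safe(cross_classify, pairs)
        if cc is not None:
            row.update(
                pct_exact=cc.pct_exact,
                pct_exact_plus_adjacent=cc.pct_exact_plus_adjacent,
                pct_two_apart=cc.pct_two_apart,
                pct_extreme=cc.pct_extreme,
            )
        nut_rows.append(row)

    ba_points: dict[str, pd.DataFrame] = {}
    grp_rows = []
    for col in group_cols:
        pairs = _paired(intakes_a, intakes_b, col)
        row = {"variable": col.removeprefix("group:")}
        tt = safe(group_ttest, pairs)
        if tt is not None:
            row["t"], row["t_df"], row["t_p"] = tt
        corr = safe(correlations, pairs, "spearman")
        if corr is not None:
            row["scc"], row["scc_p"] = corr
        cc = safe(cross_classify, pairs)
        if cc is not None:
            row.update(
                pct_exact=cc.pct_exact,
                pct_exact_plus_adjacent=cc.pct_exact_plus_adjacent,
                pct_two_apart=cc.pct_two_apart,
            )
        ba = bland_altman(pairs, k_sd=k_sd)
        row.update(
            bias=ba.mean_diff, loa_low=ba.loa_low, loa_high=ba.loa_high,
            n_outside=ba.n_outside, pct_within=ba.pct_within,
            comparable=ba.comparable,
        )
        ba_points[col] = pd.DataFrame({"mean": ba.means, "diff": ba.diffs})
        grp_rows.append(row)

    macro_rows = []
    for col in MACRO_BA_COLUMNS:
        if col not in intakes_a.columns:
            continue
        try:
            pairs = _paired(intakes_a, intakes_b, col)
        except AgreementError:  # e.g. undefined %TE for a zero-energy respondent
            continue
        ba = bland_altman(pairs, k_sd=k_sd)
        macro_rows.append(
            {
                "variable": col,
                "bias": ba.mean_diff,
                "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "n_outside": ba.n_outside,
                "pct_within": ba.pct_within,
                "comparable": ba.comparable,
            }
        )
        ba_points[col] = pd.DataFrame({"mean": ba.means, "diff": ba.diffs})

    concordance = float("nan")
    if under_reporter_flags is not None and {"A", "B"} <= set(
        under_reporter_flags.columns
    ):
        online_flagged = under_reporter_flags[under_reporter_flags["B"]]
        if len(online_flagged):
            concordance = float(online_flagged["A"].mean())

    return AgreementReport(
        nutrients=pd.DataFrame(nut_rows).set_index("variable"),
        food_groups=pd.DataFrame(grp_rows).set_index("variable"),
        macronutrient_ba=pd.DataFrame(macro_rows).set_index("variable"),
        bland_altman_points=ba_points,
        under_reporter_concordance=concordance,
    )
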