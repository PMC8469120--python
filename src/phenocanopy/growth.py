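"""Growth, correlation, treatment and germination statistics.

This module turns per-(pot, day) pixel counts into the standard downstream
analyses of a pot experiment:

* assembly of per-pot growth series from biomass records;
* Pearson correlation of digital biomass (green pixels) against destructive
  fresh/dry weight, pooled over stages or per stage;
* one-way ANOVA across treatments with Tukey HSD post-hoc pairwise
  comparisons (studentized-range adjusted p-values);
* a dummy-coded linear model per sampling day (intercept = reference
  treatment mean, per-level two-sided t-test p-values, the ``Pr(>|t|)``
  column of an R ``lm`` summary);
* germination calling from early green-area series: a unit has emerged on
  the first day its green-pixel count reaches a configurable area threshold,
  and cumulative germinated fractions per treatment follow.

Statistical engines are the standard ones (scipy for Pearson/F, statsmodels
for Tukey HSD and OLS); this module owns the experiment-aware plumbing and
the result containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .classifier import BiomassRecord
from .layout import ExperimentLayout

__all__ = [
    "GrowthSeries",
    "CorrelationResult",
    "TreatmentComparison",
    "AnovaTukeyResult",
    "GerminationResult",
    "build_series",
    "pearson_correlation",
    "anova_tukey",
    "treatment_lm",
    "call_germination",
    "germination_fractions",
    "growth_summary",
    "plot_growth_curves",
]


@dataclass
class GrowthSeries:
    """Day-ordered green/yellow pixel counts for one pot or tray cell."""

    pot_id: str
    treatment: str
    replicate: int
    days: np.ndarray
    green_pixels: np.ndarray
    yellow_pixels: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.green_pixels = np.asarray(self.green_pixels, dtype=int)
        self.yellow_pixels = np.asarray(self.yellow_pixels, dtype=int)
        if not (len(self.days) == len(self.green_pixels) == len(self.yellow_pixels)):
            raise ValueError(f"series {self.pot_id!r}: unequal array lengths")
        if len(self.days) and np.any(np.diff(self.days) <= 0):
            raise ValueError(f"series {self.pot_id!r}: days must be strictly increasing")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TreatmentComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    alpha: float
    comparisons: list[TreatmentComparison]


@dataclass(frozen=True)
class GerminationResult:
    unit_id: str
    day_of_emergence: Optional[int]


def build_series(records, layout: ExperimentLayout) -> list[GrowthSeries]:
    """Group biomass records into one day-sorted series per pot.

    Every record's pot must exist in the layout (unknown ids are reported
    together); duplicate (pot, day) pairs are rejected.  Missing days are
    simply absent — no interpolation.
    """
    records = list(records)
    known = set(layout.pot_ids)
    unknown = sorted({r.pot_id for r in records} - known)
    if unknown:
        raise ValueError(f"records reference pot ids not in layout: {unknown}")
    by_pot: dict[str, list[BiomassRecord]] = {}
    for r in records:
        by_pot.setdefault(r.pot_id, []).append(r)
    out = []
    for pot_id in sorted(by_pot):
        recs = sorted(by_pot[pot_id], key=lambda r: r.day)
        days = [r.day for r in recs]
        if len(set(days)) != len(days):
            dup = sorted({d for d in days if days.count(d) > 1})
            raise ValueError(f"pot {pot_id!r}: duplicate days {dup}")
        pot = layout.pot(pot_id)
        out.append(
            GrowthSeries(
                pot_id=pot_id,
                treatment=pot.treatment,
                replicate=pot.replicate,
                days=np.array(days),
                green_pixels=np.array([r.green_pixels for r in recs]),
                yellow_pixels=np.array([r.yellow_pixels for r in recs]),
            )
        )
    return out


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p_value=float(res.pvalue), n=len(x))


def anova_tukey(groups: dict, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA plus all pairwise Tukey HSD comparisons.

    ``groups`` maps treatment name to a list of values.  Requires at least
    two groups with n >= 2 each and nonzero pooled within-group variance.
    """
    if len(groups) < 2:
        raise ValueError("need at least two treatment groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has n={len(vals)} (need >= 2)")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if all(np.var(v) == 0 for v in arrays.values()):
        raise ValueError("zero within-group variance in every group; ANOVA undefined")
    f_stat, p_value = stats.f_oneway(*arrays.values())

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    comparisons = []
    i1, i2 = tukey._multicomp.pairindices
    for a_idx, b_idx, diff, p in zip(i1, i2, tukey.meandiffs, tukey.pvalues):
        comparisons.append(
            TreatmentComparison(
                group_a=str(tukey.groupsunique[a_idx]),
                group_b=str(tukey.groupsunique[b_idx]),
                mean_diff=float(diff),
                p_adj=float(p),
                significant=bool(p < alpha),
            )
        )
    return AnovaTukeyResult(
        f_stat=float(f_stat), p_value=float(p_value), alpha=alpha, comparisons=comparisons
    )


def treatment_lm(values, reference: str) -> pd.DataFrame:
    """Dummy-coded OLS of value on treatment against a reference level.

    ``values`` is an iterable of (treatment, value) pairs.  Returns a tidy
    coefficient table — term, estimate, std_err, t, p_value — where the
    intercept is the reference-group mean and each other row tests that
    level's mean shift against the reference (two-sided t).
    """
    df = pd.DataFrame(list(values), columns=["treatment", "value"])
    levels = sorted(df["treatment"].unique())
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among treatments {levels}")
    if len(levels) < 2:
        raise ValueError("need at least two treatment levels")
    others = [l for l in levels if l != reference]
    X = np.column_stack(
        [np.ones(len(df))] + [(df["treatment"] == l).to_numpy(float) for l in others]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (an empty treatment level?)")
    fit = sm.OLS(df["value"].to_numpy(float), X).fit()
    terms = ["(Intercept)"] + list(others)
    return pd.DataFrame(
        {
            "term": terms,
            "estimate": fit.params,
            "std_err": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    ).reset_index(drop=True)


def call_germination(series: GrowthSeries, min_area_px: int = 50) -> GerminationResult:
    """First day the unit's green area reaches ``min_area_px`` pixels.

    Operationalizes the visual emergence call: a seedling counts as
    germinated once its projected green area crosses a small fixed area.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if len(series.days) == 0:
        raise ValueError(f"series {series.pot_id!r} is empty")
    hits = np.nonzero(series.green_pixels >= min_area_px)[0]
    day = int(series.days[hits[0]]) if hits.size else None
    return GerminationResult(unit_id=series.pot_id, day_of_emergence=day)


def germination_fractions(series_list, min_area_px: int = 50) -> pd.DataFrame:
    """Cumulative germinated fraction per treatment and day.

    For each treatment, the fraction of its units whose emergence day is on
    or before each observed sampling day; nondecreasing in day by
    construction.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no series given")
    all_days = np.unique(np.concatenate([s.days for s in series_list]))
    rows = []
    by_treatment: dict[str, list[GrowthSeries]] = {}
    for s in series_list:
        by_treatment.setdefault(s.treatment, []).append(s)
    for treatment in sorted(by_treatment):
        units = by_treatment[treatment]
        emerged = [call_germination(s, min_area_px).day_of_emergence for s in units]
        for day in all_days:
            frac = sum(1 for e in emerged if e is not None and e <= day) / len(units)
            rows.append({"treatment": treatment, "day": int(day), "fraction": frac})
    return pd.DataFrame(rows, columns=["treatment", "day", "fraction"])


def growth_summary(series_list) -> pd.DataFrame:
    """Per (treatment, day) mean green area with its standard error.

    SE = sd / sqrt(n) with sd the n-1 sample standard deviation; with a
    single replicate the SE is undefined and reported as NaN.
    """
    rows = []
    for s in series_list:
        for day, green in zip(s.days, s.green_pixels):
            rows.append({"treatment": s.treatment, "day": int(day), "green": int(green)})
    if not rows:
        return pd.DataFrame(columns=["treatment", "day", "mean", "se", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["treatment", "day"])["green"]
        .agg(
            mean="mean",
            se=lambda v: np.std(v, ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="count",
        )
        .reset_index()
    )
    return out


def plot_growth_curves(summary: pd.DataFrame, path) -> None:
    """Write a mean +/- SE growth-curve plot (one line per treatment)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for treatment, grp in summary.groupby("treatment"):
        grp = grp.sort_values("day")
        ax.errorbar(
            grp["day"], grp["mean"], yerr=grp["se"], marker="o", capsize=3, label=str(treatment)
        )
    ax.set_xlabel("days after sowing")
    ax.set_ylabel("digital biomass (green pixels)")
    ax.legend(title="treatment", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
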