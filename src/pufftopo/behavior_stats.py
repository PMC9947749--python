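"""Descriptive puff-topography statistics, cross-tabulations and effect sizes.

With >10^5 puffs, null-hypothesis tests reject everything, so this
module deliberately computes no p-values.  Group differences are
reported as effect sizes instead:

* **eta-squared** — the "R^2 coefficient" for a categorical factor: the
  proportion of total variance in a continuous outcome explained by the
  factor in a one-way decomposition, SS_between / SS_total.
* **Cohen d** — standardized mean difference between two factor levels
  using the pooled (n-1) standard deviation; |d| >= 0.5 is read as
  medium, >= 0.8 as large, and the reporting layer suppresses smaller
  values as "N/A" to mirror how such tables are conventionally printed.
* **Coefficient of variance (CV%)** — per-user intra-individual
  variability of daily metrics over the user's own active days,
  100 * sample SD / mean.

The unit of analysis is the puff, as in the source tables; puffs within
a user are statistically dependent, so a per-user-aggregated sensitivity
mode is available (`per_user=True` on the effect-size helpers' callers'
side simply means passing user-level means instead of puff values).
Percentages in printed-style tables are rounded half-up at the printed
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .puff_data import (
    AGE_LEVELS,
    CONC_BIN_LABELS,
    CohortDataset,
    ConfigError,
    ENDS_YEARS_LEVELS,
    POWER_SETTINGS,
    SEX_LEVELS,
    SMOKING_LEVELS,
    SURVEY_COLUMNS,
    bin_concentration_series,
)

__all__ = [
    "UndefinedStatisticError",
    "round_half_up",
    "describe",
    "CrossTab",
    "crosstab",
    "eta_squared",
    "cohen_d",
    "EffectSizeReport",
    "effect_size_report",
    "user_cv",
    "cv_table",
    "demographic_puff_distribution",
]


class UndefinedStatisticError(ValueError):
    """A statistic's defining conditions are not met (it is not silently zeroed)."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half-up at ``decimals`` places (printed-table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def describe(values) -> dict:
    """Mean, median, sample SD (n-1), SE = SD/sqrt(n), and n.

    An empty input yields the explicit empty summary ``{"n": 0}`` with
    NaN statistics.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {"mean": float("nan"), "median": float("nan"), "sd": float("nan"),
                "se": float("nan"), "n": 0}
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sd": sd,
        "se": sd / float(np.sqrt(arr.size)),
        "n": int(arr.size),
    }


# --------------------------------------------------------------------------
# Factor resolution and cross-tabulation
# --------------------------------------------------------------------------

_LEVEL_ORDER = {
    "power_setting": list(POWER_SETTINGS),
    "conc_bin": list(CONC_BIN_LABELS),
    "sex": list(SEX_LEVELS),
    "age_band": list(AGE_LEVELS),
    "smoking_history": list(SMOKING_LEVELS),
    "ends_years_band": list(ENDS_YEARS_LEVELS),
}


def _resolve_factor(frame: pd.DataFrame, spec: str) -> pd.Series:
    """Resolve a factor spec to a per-row label Series (NaN = unresolvable).

    ``"conc_bin"`` derives the concentration bin from
    ``nicotine_conc_mg_ml`` (missing concentration is unresolvable);
    any other spec must name a column of the frame.
    """
    if spec == "conc_bin":
        labels = bin_concentration_series(frame["nicotine_conc_mg_ml"])
        return labels.where(labels != "unknown")
    if spec not in frame.columns:
        raise ConfigError(f"unknown factor spec {spec!r}")
    return frame[spec]


def _ordered_levels(spec: str, present) -> list:
    order = _LEVEL_ORDER.get(spec)
    present = set(present)
    if order is None:
        return sorted(present)
    return [lvl for lvl in order if lvl in present]


@dataclass
class CrossTab:
    """Counts of puffs by one or two categorical factors.

    ``counts`` is a level x level frame (a single-column frame for a
    one-way table); ``denominator_total`` is the count the percentages
    divide by — the resolvable subset by default, or the full input size
    when ``denominator="all"`` was requested; ``n_excluded`` reports the
    rows whose factor could not be resolved.
    """

    counts: pd.DataFrame
    grand_total: int
    denominator_total: int
    n_excluded: int

    def pct(self, decimals: int = 2) -> pd.DataFrame:
        """Percentages of ``denominator_total``, rounded half-up."""
        return (self.counts / self.denominator_total * 100.0).map(
            lambda v: round_half_up(v, decimals))


def crosstab(puffs: pd.DataFrame, row: str, col: str | None = None,
             denominator: str = "subset") -> CrossTab:
    """Cross-tabulate puffs by one or two factor specs.

    Rows with an unresolvable factor (for example a missing nicotine
    concentration under ``conc_bin``) are excluded from the counts and
    reported in ``n_excluded``.  ``denominator="subset"`` (default)
    computes percentages over the included rows — the convention of the
    power x concentration table — while ``"all"`` divides by the full
    input size, the convention of whole-cohort prose shares.
    """
    if denominator not in ("subset", "all"):
        raise ConfigError(f"denominator must be 'subset' or 'all', not {denominator!r}")
    r = _resolve_factor(puffs, row)
    if col is None:
        ok = r.notna()
        counts = r[ok].value_counts()
        table = pd.DataFrame(
            {"count": [int(counts.get(lvl, 0))
                       for lvl in _ordered_levels(row, counts.index)]},
            index=_ordered_levels(row, counts.index))
    else:
        c = _resolve_factor(puffs, col)
        ok = r.notna() & c.notna()
        joint = pd.crosstab(r[ok], c[ok])
        table = joint.reindex(index=_ordered_levels(row, joint.index),
                              columns=_ordered_levels(col, joint.columns),
                              fill_value=0).astype(int)
    grand = int(table.to_numpy().sum())
    denom = len(puffs) if denominator == "all" else grand
    return CrossTab(counts=table, grand_total=grand, denominator_total=denom,
                    n_excluded=int((~ok).sum()))


# --------------------------------------------------------------------------
# Effect sizes
# --------------------------------------------------------------------------


def eta_squared(values, groups) -> float:
    """One-way eta-squared: SS_between / SS_total for a categorical factor.

    Lies in [0, 1]; 0 when all group means coincide, 1 when each
    observation is its own group (zero within-group variance).

    Raises
    ------
    UndefinedStatisticError
        With fewer than two non-empty groups or zero total variance.
    """
    vals = np.asarray(values, dtype=float)
    grp = pd.Series(np.asarray(groups, dtype=object))
    if vals.shape[0] != grp.shape[0]:
        raise ValueError("values and groups must have equal length")
    frame = pd.DataFrame({"v": vals, "g": grp}).dropna()
    counts = frame.groupby("g", observed=True)["v"].agg(["mean", "count"])
    if len(counts) < 2:
        raise UndefinedStatisticError("eta-squared needs >= 2 non-empty groups")
    grand = frame["v"].mean()
    ss_total = float(((frame["v"] - grand) ** 2).sum())
    if ss_total == 0:
        raise UndefinedStatisticError("eta-squared undefined: zero total variance")
    ss_between = float((counts["count"] * (counts["mean"] - grand) ** 2).sum())
    return min(max(ss_between / ss_total, 0.0), 1.0)


def cohen_d(a, b, *, hedges_correction: bool = False) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    The pooled SD is sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a+n_b-2)).
    ``hedges_correction`` applies the small-sample factor
    1 - 3/(4(n_a+n_b)-9); it is off by default.  Swapping the groups
    negates d.

    Raises
    ------
    UndefinedStatisticError
        If either group has n < 2 or the pooled SD is zero.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise UndefinedStatisticError("cohen_d needs n >= 2 in each group")
    pooled_var = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if xa.mean() == xb.mean():
            return 0.0
        raise UndefinedStatisticError("cohen_d undefined: pooled SD is zero")
    d = float((xa.mean() - xb.mean()) / np.sqrt(pooled_var))
    if hedges_correction:
        d *= 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return d


@dataclass
class EffectSizeReport:
    """Effect of one categorical factor on a continuous outcome.

    ``pairwise_d`` has one row per unordered level pair with the Cohen d
    of (level_a - level_b), the per-level n's, and ``presented`` — the
    medium-or-larger flag (|d| >= ``d_threshold``); non-presented values
    print as "N/A" in report tables.
    """

    factor: str
    eta_squared: float
    pairwise_d: pd.DataFrame
    n_per_level: dict

    def table(self, decimals: int = 3) -> pd.DataFrame:
        """Printed-style table: suppressed pairs show 'N/A'."""
        out = self.pairwise_d.copy()
        out["cohen_d"] = [
            format(round_half_up(d, decimals), f".{decimals}f") if pres else "N/A"
            for d, pres in zip(out["cohen_d"], out["presented"])
        ]
        return out[["level_a", "level_b", "cohen_d"]]


def effect_size_report(values, groups, factor: str = "",
                       d_threshold: float = 0.5) -> EffectSizeReport:
    """Eta-squared plus all pairwise Cohen d's for one factor."""
    frame = pd.DataFrame({"v": np.asarray(values, dtype=float),
                          "g": np.asarray(groups, dtype=object)}).dropna()
    eta = eta_squared(frame["v"], frame["g"])
    levels = _ordered_levels(factor, frame["g"].unique())
    by_level = {lvl: frame.loc[frame["g"] == lvl, "v"].to_numpy() for lvl in levels}
    rows = []
    for la, lb in combinations(levels, 2):
        try:
            d = cohen_d(by_level[la], by_level[lb])
        except UndefinedStatisticError:
            continue
        rows.append({"level_a": la, "level_b": lb, "cohen_d": d,
                     "presented": abs(d) >= d_threshold})
    pairwise = pd.DataFrame(rows, columns=["level_a", "level_b", "cohen_d",
                                           "presented"])
    return EffectSizeReport(factor=factor, eta_squared=eta, pairwise_d=pairwise,
                            n_per_level={lvl: int(v.size) for lvl, v in by_level.items()})


# --------------------------------------------------------------------------
# Intra-individual variability
# --------------------------------------------------------------------------


def user_cv(values) -> tuple[float, str]:
    """CV% (100 * sample SD / mean) of one user's daily metric.

    Returns ``(cv, reason)``: the CV is NaN — never silently zero — when
    fewer than two active days are available or the mean is not
    positive, with the reason stated.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return float("nan"), "fewer than 2 active days"
    m = arr.mean()
    if m <= 0:
        return float("nan"), "non-positive mean"
    return float(100.0 * arr.std(ddof=1) / m), ""


def cv_table(daily_summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-user CV% of daily puff count, mean duration and nicotine total.

    Expects the per-user-day summary frame (one row per active user-day
    with ``puff_count``, ``mean_duration_s``, ``total_nicotine_mg``).
    Users with fewer than two active days get NaN CVs and a reason.
    """
    rows = []
    for device_id, grp in daily_summaries.groupby("device_id", sort=True):
        count_cv, reason_c = user_cv(grp["puff_count"])
        dur_cv, _ = user_cv(grp["mean_duration_s"])
        nic = grp["total_nicotine_mg"]
        nic_cv, _ = user_cv(nic[nic > 0]) if (nic > 0).any() else (float("nan"),
                                                                   "no estimable days")
        rows.append({
            "device_id": device_id,
            "n_active_days": int(len(grp)),
            "count_cv_pct": count_cv,
            "duration_cv_pct": dur_cv,
            "nicotine_cv_pct": nic_cv,
            "note": reason_c,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Demographic puff distribution (printed-table layout)
# --------------------------------------------------------------------------


def demographic_puff_distribution(cohort: CohortDataset,
                                  factors=SURVEY_COLUMNS[1:]) -> dict[str, pd.DataFrame]:
    """Participant and puff shares per survey factor level.

    For each factor, returns levels x {participants_n, participants_pct,
    puffs_n, puffs_pct}: participant percentages over all profiles,
    puff percentages over the matched puffs (survey nonresponse appears
    as the ``missing`` level; puffs from devices without any profile are
    excluded from these totals, since they cannot be attributed to a
    respondent).
    """
    matched = cohort.merged[cohort.merged["matched"]]
    n_profiles = len(cohort.profiles)
    n_puffs = len(matched)
    out: dict[str, pd.DataFrame] = {}
    for factor in factors:
        part_counts = cohort.profiles[factor].value_counts()
        puff_counts = matched[factor].value_counts()
        levels = _ordered_levels(factor, set(part_counts.index) | set(puff_counts.index))
        table = pd.DataFrame(index=levels)
        table["participants_n"] = [int(part_counts.get(l, 0)) for l in levels]
        table["participants_pct"] = [
            round_half_up(100.0 * c / n_profiles, 2) if n_profiles else float("nan")
            for c in table["participants_n"]]
        table["puffs_n"] = [int(puff_counts.get(l, 0)) for l in levels]
        table["puffs_pct"] = [
            round_half_up(100.0 * c / n_puffs, 2) if n_puffs else float("nan")
            for c in table["puffs_n"]]
        out[factor] = table
    return out
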