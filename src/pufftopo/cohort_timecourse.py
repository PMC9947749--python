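"""Relative-day alignment, cohort time series and adaptation metrics.

Users enrol on different calendar dates, so longitudinal curves are
aligned on *relative days*: a user's first calendar day with at least
one puff is their day 1, and inactive days are gaps (absent rows), not
zeros.  Cohort-level daily curves average over the users active on each
relative day — each active user contributes one value per metric per
day regardless of how many puffs they took — with an SE band of
sample SD / sqrt(n_active).

Adaptation is summarised by the day-1 mean, the plateau mean over a
stated window (default relative days 8-21, after the first week of
acclimatisation), the ramp length (first relative day whose mean is
within a stated fractional tolerance of the plateau mean), and the
least-squares slope over the plateau window (no trend once adapted).

A zero-filled sensitivity mode counts inactive days between a user's
first and last active day as zero puffs/nicotine, because the
active-user-only convention materially raises the curves for sporadic
users.  Users can also be subgrouped by total use span in whole weeks
to check that the adaptation shape is not an artefact of pooling short-
and long-span users.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "summarize_user_days",
    "cohort_series",
    "AdaptationMetrics",
    "adaptation_metrics",
    "subgroup_by_duration",
]

_SUMMARY_COLUMNS = [
    "device_id", "relative_day", "calendar_date", "puff_count",
    "mean_duration_s", "total_nicotine_mg", "estimable_puffs",
]


def summarize_user_days(puffs: pd.DataFrame) -> pd.DataFrame:
    """One summary row per (user, active calendar day).

    Expects a puff frame, optionally carrying an ``emission_mg`` column
    (absent or NaN emissions count as non-estimable and contribute 0 mg).
    ``relative_day`` is 1 on each user's first active day; calendar gaps
    remain gaps.  The sum of ``puff_count`` over all rows equals the
    number of input puffs.
    """
    if len(puffs) == 0:
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)
    work = puffs.copy()
    work["calendar_date"] = pd.to_datetime(work["timestamp"]).dt.normalize()
    if "emission_mg" not in work.columns:
        work["emission_mg"] = np.nan
    grouped = work.groupby(["device_id", "calendar_date"], sort=True)
    summary = grouped.agg(
        puff_count=("duration_s", "size"),
        mean_duration_s=("duration_s", "mean"),
        total_nicotine_mg=("emission_mg", lambda s: float(np.nansum(s))),
        estimable_puffs=("emission_mg", lambda s: int(s.notna().sum())),
    ).reset_index()
    first = summary.groupby("device_id")["calendar_date"].transform("min")
    summary["relative_day"] = (summary["calendar_date"] - first).dt.days + 1
    return summary[_SUMMARY_COLUMNS]


def _zero_fill(summaries: pd.DataFrame) -> pd.DataFrame:
    """Insert zero-count rows for inactive days inside each user's span.

    Duration on a filled day is undefined (NaN), not zero.
    """
    parts = [summaries]
    for device_id, grp in summaries.groupby("device_id"):
        have = set(grp["relative_day"])
        gaps = sorted(set(range(1, int(grp["relative_day"].max()) + 1)) - have)
        if not gaps:
            continue
        first_date = grp["calendar_date"].min()
        parts.append(pd.DataFrame({
            "device_id": device_id,
            "relative_day": gaps,
            "calendar_date": [first_date + pd.Timedelta(days=g - 1) for g in gaps],
            "puff_count": 0,
            "mean_duration_s": np.nan,
            "total_nicotine_mg": 0.0,
            "estimable_puffs": 0,
        }))
    return pd.concat(parts, ignore_index=True)


def cohort_series(summaries: pd.DataFrame, *, zero_fill: bool = False) -> pd.DataFrame:
    """Cross-user daily means and SE bands, indexed by relative day.

    Per relative day: the number of active users and, for each of
    {puff count, mean duration, nicotine total}, the unweighted mean
    across those users and its SE (sample SD / sqrt(n); NaN when fewer
    than two users contribute).  With ``zero_fill=True``, a user's
    inactive days inside their own active span count as zero puffs and
    zero nicotine (durations stay undefined on such days).
    """
    if len(summaries) == 0:
        return pd.DataFrame(columns=["relative_day", "n_active", "puffs_mean",
                                     "puffs_se", "dur_mean", "dur_se",
                                     "nic_mean", "nic_se"])
    work = _zero_fill(summaries) if zero_fill else summaries

    def _se(s: pd.Series) -> float:
        s = s.dropna()
        return float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else float("nan")

    grouped = work.groupby("relative_day", sort=True)
    out = grouped.agg(
        n_active=("device_id", "nunique"),
        puffs_mean=("puff_count", "mean"),
        puffs_se=("puff_count", _se),
        dur_mean=("mean_duration_s", "mean"),
        dur_se=("mean_duration_s", _se),
        nic_mean=("total_nicotine_mg", "mean"),
        nic_se=("total_nicotine_mg", _se),
    ).reset_index()
    return out


@dataclass
class AdaptationMetrics:
    """Summary of the day-1-low / ramp / plateau adaptation pattern."""

    metric: str
    day1_mean: float
    plateau_mean: float
    ramp_days: int
    plateau_slope: float
    plateau_slope_se: float
    plateau_window: tuple[int, int]


def adaptation_metrics(series: pd.DataFrame, metric: str = "puffs_mean",
                       plateau_window: tuple[int, int] = (8, 21),
                       tolerance: float = 0.1) -> AdaptationMetrics:
    """Quantify adaptation of one cohort-series metric.

    ``ramp_days`` is the smallest relative day whose mean lies within
    ``tolerance * plateau_mean`` of the plateau mean (1 for a flat
    series); the plateau slope comes from an ordinary least-squares fit
    over the window and should be consistent with zero once use has
    stabilised.

    Raises
    ------
    ValueError
        If day 1 is absent or the plateau window lies outside the
        observed relative-day range.
    """
    days = series["relative_day"].to_numpy()
    vals = series[metric].to_numpy(dtype=float)
    lo, hi = plateau_window
    if lo > hi:
        raise ValueError(f"plateau window reversed: {plateau_window}")
    if 1 not in days:
        raise ValueError("series has no relative day 1")
    in_window = (days >= lo) & (days <= hi) & ~np.isnan(vals)
    if not in_window.any() or days.max() < lo:
        raise ValueError(f"plateau window {plateau_window} outside observed days "
                         f"[1, {int(days.max())}]")
    plateau_mean = float(vals[in_window].mean())
    day1_mean = float(vals[days == 1][0])
    close = np.abs(vals - plateau_mean) <= tolerance * abs(plateau_mean)
    candidates = days[close & ~np.isnan(vals)]
    ramp_days = int(candidates.min()) if candidates.size else int(days.max())
    if in_window.sum() >= 3:
        fit = linregress(days[in_window], vals[in_window])
        slope, slope_se = float(fit.slope), float(fit.stderr)
    else:
        slope, slope_se = float("nan"), float("nan")
    return AdaptationMetrics(metric=metric, day1_mean=day1_mean,
                             plateau_mean=plateau_mean, ramp_days=ramp_days,
                             plateau_slope=slope, plateau_slope_se=slope_se,
                             plateau_window=(lo, hi))


def subgroup_by_duration(summaries: pd.DataFrame, *,
                         zero_fill: bool = False) -> dict[int, pd.DataFrame]:
    """Cohort series per use-duration subgroup (whole weeks of span).

    A user's span is last active day - first active day + 1 in days,
    rounded up to whole weeks; the partition over users is exhaustive
    and disjoint, and each subgroup's series equals filtering that
    subgroup's summaries and recomputing :func:`cohort_series`.
    """
    spans = summaries.groupby("device_id")["relative_day"].max()
    weeks = np.ceil(spans / 7.0).astype(int)
    out: dict[int, pd.DataFrame] = {}
    for w in sorted(weeks.unique()):
        members = weeks.index[weeks == w]
        sub = summaries[summaries["device_id"].isin(members)]
        out[int(w)] = cohort_series(sub, zero_fill=zero_fill)
    return out
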