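"""Domain types, file I/O and validation for puff event logs and baseline surveys.

A puff log is a delimited text file with one row per recorded puff:
``device_id, timestamp, duration_s, power_setting, nicotine_conc_mg_ml,
pg_vg_ratio, brand``.  The device enforces a 10-second automatic power
shutoff, so valid puff durations lie in (0, 10] seconds; the self-reported
e-liquid nicotine concentration may be absent (empty field), which is a
first-class state distinct from 0 mg/mL.

The baseline survey is a CSV keyed by device ID with four categorical
covariates (sex, age band, cigarette smoking history, years-of-ENDS-use
band).  Unknown or blank category strings map to an explicit ``missing``
level rather than being dropped.

In-memory containers are :class:`pandas.DataFrame` objects with typed
columns; row-level validation failures are collected and reported, never
silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ConfigError",
    "PowerBand",
    "POWER_SETTINGS",
    "POWER_BANDS",
    "MAX_PUFF_DURATION_S",
    "CONC_BIN_LABELS",
    "bin_concentration",
    "bin_concentration_series",
    "LoadResult",
    "read_puff_log",
    "write_puff_log",
    "read_survey",
    "write_survey",
    "CohortDataset",
    "join_cohort",
    "FilterResult",
    "filter_puffs",
    "PUFF_COLUMNS",
    "SURVEY_COLUMNS",
    "SEX_LEVELS",
    "AGE_LEVELS",
    "SMOKING_LEVELS",
    "ENDS_YEARS_LEVELS",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ConfigError(ValueError):
    """An operation was configured inconsistently (bad predicate, bad table)."""


# --------------------------------------------------------------------------
# Device power bands
# --------------------------------------------------------------------------

POWER_SETTINGS: tuple[str, ...] = ("low", "medium", "high")

#: Hard upper bound on puff duration imposed by the device's automatic
#: power shutoff.  Ten-second puffs are legal (the shutoff itself produces
#: them, visible as a spike at 10 s in duration histograms); longer ones
#: cannot occur and indicate a corrupt record.
MAX_PUFF_DURATION_S: float = 10.0


@dataclass(frozen=True)
class PowerBand:
    """One discrete device power setting and its wattage range.

    ``watt_rep`` is the representative wattage used wherever a single
    number is needed for the band (the midpoint by default).
    """

    setting: str
    watt_lo: float
    watt_hi: float
    watt_rep: float

    def __post_init__(self) -> None:
        if not self.watt_lo < self.watt_hi:
            raise ValueError(f"watt_lo must be < watt_hi for {self.setting!r}")
        if not (self.watt_lo <= self.watt_rep <= self.watt_hi):
            raise ValueError(f"watt_rep outside [{self.watt_lo}, {self.watt_hi}]")


#: The device's three discrete output bands: low 7-9 W, medium 9-11 W,
#: high 11-13 W, each represented by its midpoint wattage.
POWER_BANDS: dict[str, PowerBand] = {
    "low": PowerBand("low", 7.0, 9.0, 8.0),
    "medium": PowerBand("medium", 9.0, 11.0, 10.0),
    "high": PowerBand("high", 11.0, 13.0, 12.0),
}


# --------------------------------------------------------------------------
# Nicotine-concentration bins
# --------------------------------------------------------------------------

CONC_BIN_LABELS: tuple[str, ...] = ("zero", "low", "medium", "high")


def bin_concentration(conc: float | None) -> str:
    """Map a nicotine concentration (mg/mL) to its categorical bin.

    The bins partition [0, inf): ``zero`` = {0}, ``low`` = (0, 6],
    ``medium`` = (6, 14), ``high`` = [14, inf).  A missing concentration
    (``None`` or NaN) yields the distinct label ``"unknown"``; it is never
    silently treated as zero.

    Raises
    ------
    ValueError
        If ``conc`` is negative.
    """
    if conc is None or (isinstance(conc, float) and np.isnan(conc)):
        return "unknown"
    if conc < 0:
        raise ValueError(f"nicotine concentration must be >= 0, got {conc}")
    if conc == 0:
        return "zero"
    if conc <= 6:
        return "low"
    if conc < 14:
        return "medium"
    return "high"


def bin_concentration_series(conc: pd.Series) -> pd.Series:
    """Vectorised :func:`bin_concentration` over a Series (NaN -> "unknown")."""
    arr = pd.to_numeric(conc, errors="raise").to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("nicotine concentration must be >= 0")
    out = np.full(arr.shape, "unknown", dtype=object)
    known = ~np.isnan(arr)
    out[known & (arr == 0)] = "zero"
    out[known & (arr > 0) & (arr <= 6)] = "low"
    out[known & (arr > 6) & (arr < 14)] = "medium"
    out[known & (arr >= 14)] = "high"
    return pd.Series(out, index=conc.index, name="conc_bin")


# --------------------------------------------------------------------------
# Puff log I/O
# --------------------------------------------------------------------------

PUFF_COLUMNS: tuple[str, ...] = (
    "device_id",
    "timestamp",
    "duration_s",
    "power_setting",
    "nicotine_conc_mg_ml",
    "pg_vg_ratio",
    "brand",
)
_REQUIRED_PUFF_COLUMNS = ("device_id", "timestamp", "duration_s", "power_setting")


@dataclass
class LoadResult:
    """Outcome of loading a puff log: validated rows plus a rejection report.

    ``frame`` holds only rows satisfying every puff invariant;
    ``rejections`` has one row per rejected input row with its 0-based
    ``row`` index (relative to the data section of the file) and a
    human-readable ``reason``.
    """

    frame: pd.DataFrame
    rejections: pd.DataFrame

    @property
    def n_loaded(self) -> int:
        return len(self.frame)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def read_puff_log(path, *, delimiter: str = ",") -> LoadResult:
    """Read and validate a puff event log.

    Rows violating an invariant (unparseable timestamp or duration,
    duration outside (0, 10] s, unknown power setting, negative or
    unparseable concentration) are rejected with a per-row reason; an
    empty concentration field is legal and becomes NaN.

    Raises
    ------
    FormatError
        If a mandatory column is absent.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=list(_REQUIRED_PUFF_COLUMNS))
    missing_cols = [c for c in _REQUIRED_PUFF_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"puff log {path} is missing mandatory columns: {missing_cols}")
    for col in PUFF_COLUMNS:
        if col not in raw.columns:
            raw[col] = ""

    n = len(raw)
    reasons: list[tuple[int, str]] = []
    ok = np.ones(n, dtype=bool)

    ts = pd.to_datetime(raw["timestamp"].str.strip(), errors="coerce", format="ISO8601")
    bad = ts.isna().to_numpy()
    for i in np.flatnonzero(bad & ok):
        reasons.append((i, f"unparseable timestamp {raw['timestamp'].iat[i]!r}"))
    ok &= ~bad

    dur = pd.to_numeric(raw["duration_s"].str.strip(), errors="coerce")
    bad = dur.isna().to_numpy()
    for i in np.flatnonzero(bad & ok):
        reasons.append((i, f"unparseable duration {raw['duration_s'].iat[i]!r}"))
    ok &= ~bad
    nonpos = (dur <= 0).fillna(False).to_numpy()
    for i in np.flatnonzero(nonpos & ok):
        reasons.append((i, f"duration {dur.iat[i]} s must be positive"))
    ok &= ~nonpos
    toolong = (dur > MAX_PUFF_DURATION_S).fillna(False).to_numpy()
    for i in np.flatnonzero(toolong & ok):
        reasons.append((i, f"duration {dur.iat[i]} s exceeds 10 s device cutoff"))
    ok &= ~toolong

    power = raw["power_setting"].str.strip().str.lower()
    bad = (~power.isin(POWER_SETTINGS)).to_numpy()
    for i in np.flatnonzero(bad & ok):
        reasons.append((i, f"unknown power setting {raw['power_setting'].iat[i]!r}"))
    ok &= ~bad

    conc_str = raw["nicotine_conc_mg_ml"].str.strip()
    conc = pd.to_numeric(conc_str.where(conc_str != "", other=np.nan), errors="coerce")
    bad = (conc.isna() & (conc_str != "")).to_numpy()
    for i in np.flatnonzero(bad & ok):
        reasons.append((i, f"unparseable nicotine concentration {conc_str.iat[i]!r}"))
    ok &= ~bad
    neg = (conc < 0).fillna(False).to_numpy()
    for i in np.flatnonzero(neg & ok):
        reasons.append((i, f"negative nicotine concentration {conc.iat[i]}"))
    ok &= ~neg

    frame = pd.DataFrame(
        {
            "device_id": raw["device_id"].str.strip(),
            "timestamp": ts,
            "duration_s": dur.astype(float),
            "power_setting": power,
            "nicotine_conc_mg_ml": conc.astype(float),
            "pg_vg_ratio": raw["pg_vg_ratio"].str.strip().where(lambda s: s != ""),
            "brand": raw["brand"].str.strip().where(lambda s: s != ""),
        }
    )[ok].reset_index(drop=True)

    rejections = pd.DataFrame(sorted(reasons), columns=["row", "reason"])
    if len(rejections):
        logger.info("read_puff_log: rejected %d of %d rows", len(rejections), n)
    return LoadResult(frame=frame, rejections=rejections)


def _fmt_conc(v: float) -> str:
    return "" if pd.isna(v) else format(float(v), ".6g")


def write_puff_log(frame: pd.DataFrame, path) -> None:
    """Write a validated puff frame back to CSV.

    Durations are printed with three decimals (the declared precision of
    the format); timestamps as ISO 8601 to whole seconds; missing values
    as empty fields.  ``read_puff_log(write_puff_log(x))`` reproduces all
    fields up to that precision.
    """
    out = frame.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["duration_s"] = out["duration_s"].map(lambda v: format(float(v), ".3f"))
    out["nicotine_conc_mg_ml"] = out["nicotine_conc_mg_ml"].map(_fmt_conc)
    for col in ("pg_vg_ratio", "brand"):
        out[col] = out[col].fillna("")
    out = out[list(PUFF_COLUMNS)]
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Survey I/O
# --------------------------------------------------------------------------

SURVEY_COLUMNS: tuple[str, ...] = (
    "device_id",
    "sex",
    "age_band",
    "smoking_history",
    "ends_years_band",
)

SEX_LEVELS = ("female", "male", "prefer_not_to_say", "missing")
AGE_LEVELS = ("18-25", "26-35", "36-55", ">=56", "missing")
SMOKING_LEVELS = ("yes", "no", "missing")
ENDS_YEARS_LEVELS = ("6mo-1y", "1-5y", "6-10y", ">10y", "missing")

_SURVEY_CANON: dict[str, dict[str, str]] = {
    "sex": {
        "female": "female",
        "f": "female",
        "male": "male",
        "m": "male",
        "prefer_not_to_say": "prefer_not_to_say",
        "prefer not to say": "prefer_not_to_say",
    },
    "age_band": {
        "18-25": "18-25",
        "26-35": "26-35",
        "36-55": "36-55",
        ">=56": ">=56",
        "≥56": ">=56",
        "56+": ">=56",
    },
    "smoking_history": {"yes": "yes", "y": "yes", "no": "no", "n": "no"},
    "ends_years_band": {
        "6mo-1y": "6mo-1y",
        "6 months to 1 year": "6mo-1y",
        "1-5y": "1-5y",
        "1-5 years": "1-5y",
        "6-10y": "6-10y",
        "6-10 years": "6-10y",
        ">10y": ">10y",
        ">10 years": ">10y",
        "10+": ">10y",
    },
}


def read_survey(path) -> pd.DataFrame:
    """Read a baseline survey table, one row per device ID.

    Unknown or blank category strings map to the explicit ``missing``
    level (survey nonresponse is data, not an error).  An empty file
    yields an empty table with a logged warning.

    Raises
    ------
    FormatError
        On absent columns or duplicate device IDs (named in the message).
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("read_survey: %s is empty; returning zero profiles", path)
        return pd.DataFrame(columns=list(SURVEY_COLUMNS))
    missing_cols = [c for c in SURVEY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"survey {path} is missing columns: {missing_cols}")
    if len(raw) == 0:
        logger.warning("read_survey: %s has no data rows", path)

    out = pd.DataFrame({"device_id": raw["device_id"].str.strip()})
    dupes = out["device_id"][out["device_id"].duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"duplicate device_id in survey: {dupes}")
    for col in SURVEY_COLUMNS[1:]:
        canon = _SURVEY_CANON[col]
        vals = raw[col].str.strip().str.lower().map(canon)
        # age bands are case-free but the canon keys are lowercase already
        out[col] = vals.fillna("missing")
    return out


def write_survey(profiles: pd.DataFrame, path) -> None:
    """Write a survey table; the ``missing`` level becomes an empty field."""
    out = profiles[list(SURVEY_COLUMNS)].copy()
    for col in SURVEY_COLUMNS[1:]:
        out[col] = out[col].replace("missing", "")
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Joining puffs to profiles
# --------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """Puff log joined to survey profiles on device ID.

    ``merged`` carries one row per puff with the profile columns appended
    and a boolean ``matched`` flag; device-ID mismatch in either direction
    is recorded, not treated as failure.  ``unmatched_device_ids`` is the
    union of both directions; the two sides are also kept separately.
    """

    puffs: pd.DataFrame
    profiles: pd.DataFrame
    merged: pd.DataFrame
    unmatched_puff_devices: frozenset = field(default_factory=frozenset)
    profiles_without_puffs: frozenset = field(default_factory=frozenset)

    @property
    def unmatched_device_ids(self) -> frozenset:
        return self.unmatched_puff_devices | self.profiles_without_puffs

    @property
    def n_puffs(self) -> int:
        return len(self.puffs)


def join_cohort(puffs: pd.DataFrame, profiles: pd.DataFrame) -> CohortDataset:
    """Join a puff frame to a survey frame on ``device_id``.

    Every input puff is preserved: matched puffs carry their profile
    columns, unmatched puffs keep ``missing`` profile levels and have
    their device IDs reported.  Profiles with zero puffs are reported
    symmetrically.
    """
    merged = puffs.merge(profiles, on="device_id", how="left", indicator=True)
    merged["matched"] = merged.pop("_merge") == "both"
    for col in SURVEY_COLUMNS[1:]:
        if col in merged.columns:
            merged[col] = merged[col].fillna("missing")
        else:
            merged[col] = "missing"
    puff_devices = set(puffs["device_id"].unique())
    prof_devices = set(profiles["device_id"].unique())
    ds = CohortDataset(
        puffs=puffs,
        profiles=profiles,
        merged=merged,
        unmatched_puff_devices=frozenset(puff_devices - prof_devices),
        profiles_without_puffs=frozenset(prof_devices - puff_devices),
    )
    assert len(ds.merged) == len(puffs), "join must conserve puff count"
    return ds


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------


@dataclass
class FilterResult:
    """A filtered puff frame plus the count removed by each criterion."""

    frame: pd.DataFrame
    removed: dict[str, int]

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def filter_puffs(
    puffs: pd.DataFrame,
    *,
    nonmissing_conc: bool = False,
    nonzero_conc: bool = False,
    power: str | list[str] | None = None,
    date_range: tuple | None = None,
    users: set | list | None = None,
) -> FilterResult:
    """Subset a puff frame by declarative criteria, reporting removals.

    Criteria are applied in the order of the keyword list; ``removed``
    maps each active criterion to the number of rows it removed.
    ``nonzero_conc`` removes rows whose concentration is exactly 0 mg/mL;
    rows with *missing* concentration are untouched by it (combine with
    ``nonmissing_conc`` for the strictly-positive recorded subset).

    Raises
    ------
    ConfigError
        On a contradictory or unintelligible predicate (unknown power
        level, reversed date range).
    """
    frame = puffs
    removed: dict[str, int] = {}

    if nonmissing_conc:
        keep = frame["nicotine_conc_mg_ml"].notna()
        removed["nonmissing_conc"] = int((~keep).sum())
        frame = frame[keep]
    if nonzero_conc:
        keep = frame["nicotine_conc_mg_ml"].isna() | (frame["nicotine_conc_mg_ml"] != 0)
        removed["nonzero_conc"] = int((~keep).sum())
        frame = frame[keep]
    if power is not None:
        levels = [power] if isinstance(power, str) else list(power)
        bad = [p for p in levels if p not in POWER_SETTINGS]
        if bad:
            raise ConfigError(f"unknown power setting(s) in filter: {bad}")
        keep = frame["power_setting"].isin(levels)
        removed["power"] = int((~keep).sum())
        frame = frame[keep]
    if date_range is not None:
        start, end = (pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1]))
        if start > end:
            raise ConfigError(f"date_range start {start} is after end {end}")
        dates = pd.to_datetime(frame["timestamp"]).dt.normalize()
        keep = (dates >= start) & (dates <= end)
        removed["date_range"] = int((~keep).sum())
        frame = frame[keep]
    if users is not None:
        keep = frame["device_id"].isin(set(users))
        removed["users"] = int((~keep).sum())
        frame = frame[keep]

    return FilterResult(frame=frame.reset_index(drop=True), removed=removed)
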