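"""Published aggregate tables of the observational cohort, as machine-readable fixtures.

These are the printed integer counts from the study's summary tables:
the 61-participant demographic/nicotine-history table with per-level puff
counts (n = 200,411 puffs from the 58 participants who supplied a device
ID), the 12-cell device-power x concentration-bin cross-tabulation
(n = 118,947 puffs with a recorded nicotine concentration), the per-power
puff totals, and the per-concentration-value puff counts.  They serve two
purposes: exact-reproduction tests of the cross-tabulation machinery, and
the default usage mixture of the synthetic cohort generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TOTAL_PUFFS",
    "N_PARTICIPANTS",
    "CONC_RECORDED_PUFFS",
    "TABLE2_TOTAL",
    "NONZERO_CONC_PUFFS",
    "TABLE1_COUNTS",
    "TABLE2_COUNTS",
    "POWER_PUFF_COUNTS",
    "CONC_VALUE_COUNTS",
    "generate_fixture_tables",
    "table1_counts_frame",
    "table2_counts_frame",
    "table2_fixture_puffs",
    "table1_fixture_cohort",
    "default_usage_mixture",
]

#: Total identified puffs over the two-month observation window.
TOTAL_PUFFS = 200_411
#: Enrolled participants (58 of whom supplied a device ID).
N_PARTICIPANTS = 61
#: Puffs carrying a recorded e-liquid nicotine concentration (~59.35%).
CONC_RECORDED_PUFFS = 118_949
#: Denominator of the power x concentration-bin table (2 fewer than the
#: prose figure above; the published tables are internally consistent
#: with this value: 113,797 nonzero + 5,150 zero-nicotine puffs).
TABLE2_TOTAL = 118_947
#: Puffs with a recorded, strictly positive nicotine concentration.
NONZERO_CONC_PUFFS = 113_797

#: Participant and puff counts per survey factor level.
TABLE1_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {
        "female": (31, 98_619),
        "male": (29, 100_899),
        "prefer_not_to_say": (1, 893),
    },
    "age_band": {
        "18-25": (7, 9_304),
        "26-35": (16, 58_099),
        "36-55": (33, 92_327),
        ">=56": (5, 40_681),
    },
    "smoking_history": {
        "yes": (23, 106_647),
        "no": (7, 27_607),
        "missing": (31, 66_157),
    },
    "ends_years_band": {
        "6mo-1y": (4, 23_060),
        "1-5y": (26, 51_306),
        "6-10y": (23, 94_923),
        ">10y": (6, 30_832),
        "missing": (2, 290),
    },
}

#: Puff counts by concentration bin (rows) and power setting (columns).
TABLE2_COUNTS: dict[str, dict[str, int]] = {
    "zero": {"low": 4_633, "medium": 517, "high": 0},
    "low": {"low": 6_464, "medium": 22_933, "high": 36_108},
    "medium": {"low": 2_955, "medium": 12_361, "high": 3_075},
    "high": {"low": 4_816, "medium": 10_996, "high": 14_089},
}

#: Puff totals per device power setting (denominator: all 200,411 puffs).
POWER_PUFF_COUNTS: dict[str, int] = {"low": 32_333, "medium": 75_016, "high": 93_062}

#: Puff counts for the most prevalent recorded concentration values
#: (mg/mL), out of all 200,411 puffs.
CONC_VALUE_COUNTS: dict[float, int] = {
    3.0: 32_602,
    6.0: 32_333,
    11.0: 14_480,
    18.0: 13_533,
    14.0: 8_695,
}

#: Representative concentration value (mg/mL) used when expanding a bin
#: into puff-level fixture rows.
_BIN_REP_CONC = {"zero": 0.0, "low": 3.0, "medium": 11.0, "high": 14.0}


def table1_counts_frame() -> pd.DataFrame:
    """Demographic table as a tidy frame: factor, level, participants, puffs."""
    rows = [
        (factor, level, n_part, n_puffs)
        for factor, levels in TABLE1_COUNTS.items()
        for level, (n_part, n_puffs) in levels.items()
    ]
    return pd.DataFrame(rows, columns=["factor", "level", "participants", "puffs"])


def table2_counts_frame() -> pd.DataFrame:
    """Power x concentration-bin counts with bins as rows, powers as columns."""
    return pd.DataFrame(TABLE2_COUNTS).T[["low", "medium", "high"]]


def generate_fixture_tables() -> dict[str, pd.DataFrame]:
    """Return every printed-count fixture as a machine-readable table."""
    return {
        "table1": table1_counts_frame(),
        "table2": table2_counts_frame(),
        "power_totals": pd.DataFrame(
            {"puffs": pd.Series(POWER_PUFF_COUNTS)}, index=list(POWER_PUFF_COUNTS)
        ),
        "conc_values": pd.DataFrame(
            sorted(CONC_VALUE_COUNTS.items()), columns=["conc_mg_ml", "puffs"]
        ),
    }


def table2_fixture_puffs() -> pd.DataFrame:
    """Expand the power x bin counts into one puff-like row per counted puff.

    Each bin is represented by a single in-bin concentration value, so the
    frame realises the printed 12-cell joint distribution exactly
    (n = 118,947 rows) and can be fed to the cross-tabulation operation.
    """
    powers: list[np.ndarray] = []
    concs: list[np.ndarray] = []
    for bin_label, per_power in TABLE2_COUNTS.items():
        for power, count in per_power.items():
            powers.append(np.repeat(power, count))
            concs.append(np.repeat(_BIN_REP_CONC[bin_label], count))
    return pd.DataFrame(
        {
            "power_setting": np.concatenate(powers),
            "nicotine_conc_mg_ml": np.concatenate(concs),
        }
    )


def table1_fixture_cohort(factor: str):
    """Build a (puffs, profiles) pair realising one demographic marginal exactly.

    The published demographic table reports each survey factor's marginal
    separately (the joint distribution is not released), so reproduction
    is checked one factor at a time: participants of each level receive
    synthetic device IDs and the level's puff count is split among them.

    Returns
    -------
    (pandas.DataFrame, pandas.DataFrame)
        A minimal puff frame (``device_id`` plus constant filler columns)
        and a survey frame in which every other factor is ``missing``.
    """
    if factor not in TABLE1_COUNTS:
        raise KeyError(f"unknown demographic factor {factor!r}")
    prof_rows = []
    dev_ids: list[np.ndarray] = []
    uid = 0
    for level, (n_part, n_puffs) in TABLE1_COUNTS[factor].items():
        ids = [f"FIX-{uid + k:03d}" for k in range(n_part)]
        uid += n_part
        for d in ids:
            row = {"device_id": d, "sex": "missing", "age_band": "missing",
                   "smoking_history": "missing", "ends_years_band": "missing"}
            row[factor] = level
            prof_rows.append(row)
        per = n_puffs // n_part
        counts = [per] * n_part
        counts[0] += n_puffs - per * n_part
        dev_ids.append(np.repeat(ids, counts))
    devices = np.concatenate(dev_ids)
    puffs = pd.DataFrame(
        {
            "device_id": devices,
            "timestamp": pd.Timestamp("2022-03-01T12:00:00"),
            "duration_s": 3.0,
            "power_setting": "medium",
            "nicotine_conc_mg_ml": np.nan,
            "pg_vg_ratio": np.nan,
            "brand": np.nan,
        }
    )
    profiles = pd.DataFrame(prof_rows)
    return puffs, profiles


def default_usage_mixture() -> dict[tuple[str, float], float]:
    """Default (power setting, concentration value) usage mixture.

    Cell masses follow the published power x concentration-bin joint
    distribution; within each bin, mass is split across discrete
    concentration values (0, 1, 3, 6, 10, 11, 14, 18 mg/mL) in proportion
    to the published per-value puff counts, with each bin's unattributed
    remainder assigned to the bin's most common value.  Probabilities sum
    to 1 over the 118,947 concentration-recorded puffs.
    """
    bin_totals = {b: sum(d.values()) for b, d in TABLE2_COUNTS.items()}
    # per-bin value shares derived from the published per-value counts
    value_split: dict[str, dict[float, float]] = {
        "zero": {0.0: 1.0},
        "low": {},
        "medium": {},
        "high": {},
    }
    low_known = CONC_VALUE_COUNTS[3.0] + CONC_VALUE_COUNTS[6.0]
    value_split["low"] = {
        1.0: (bin_totals["low"] - low_known) / bin_totals["low"],
        3.0: CONC_VALUE_COUNTS[3.0] / bin_totals["low"],
        6.0: CONC_VALUE_COUNTS[6.0] / bin_totals["low"],
    }
    value_split["medium"] = {
        10.0: (bin_totals["medium"] - CONC_VALUE_COUNTS[11.0]) / bin_totals["medium"],
        11.0: CONC_VALUE_COUNTS[11.0] / bin_totals["medium"],
    }
    value_split["high"] = {
        14.0: CONC_VALUE_COUNTS[14.0] / bin_totals["high"],
        18.0: (bin_totals["high"] - CONC_VALUE_COUNTS[14.0]) / bin_totals["high"],
    }
    total = float(TABLE2_TOTAL)
    mixture: dict[tuple[str, float], float] = {}
    for bin_label, per_power in TABLE2_COUNTS.items():
        for power, count in per_power.items():
            for conc, share in value_split[bin_label].items():
                p = count / total * share
                if p > 0:
                    mixture[(power, conc)] = mixture.get((power, conc), 0.0) + p
    return mixture
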