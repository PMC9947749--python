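"""Per-puff nicotine-emission estimation anchored to a laboratory calibration.

The device does not measure aerosol nicotine directly; it records puff
duration, power setting and the self-reported e-liquid concentration.
The emission model converts those into an estimated nicotine mass per
puff (mg) by scaling a laboratory reference point: machine-puffing tests
of the device under the Coresta regime (55 mL / 3 s / 30 s) with
12 mg/mL e-liquid at high power yielded ~0.0952 mg of nicotine per puff.

The default model is separable and calibration-anchored::

    e = E_ref * (c / c_ref) * (d / d_ref) * (w_rep(P) / w_rep(P_ref))

i.e. proportional in concentration ``c``, duration ``d`` and the power
band's representative wattage, and exactly equal to ``E_ref`` at the
reference condition.  It uses exactly the four quantities the device
records, and is injected as a replaceable strategy so that a richer
laboratory-derived formula (nonlinear wattage, duty-cycle or PG/VG
terms) can be swapped in without touching any caller.

Puffs with a missing concentration are *not estimable*; they are never
imputed, and aggregation reports how many were excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .puff_data import POWER_BANDS, POWER_SETTINGS, PowerBand

__all__ = [
    "EmissionCalibration",
    "EmissionModel",
    "separable_emission",
    "estimate_puff_emission",
    "add_emission",
    "daily_nicotine",
    "emission_summary",
]


@dataclass(frozen=True)
class EmissionCalibration:
    """Laboratory reference condition anchoring the emission model.

    Defaults are the machine-puffing result for this device: 12 mg/mL
    e-liquid, high power, a 3-second (Coresta-regime) puff, emitting
    0.0952 mg of nicotine.  The Coresta 55-mL puff volume enters only
    through this constant — the device records no flow rate.
    """

    conc_ref: float = 12.0          # mg/mL
    power_ref: str = "high"
    duration_ref: float = 3.0       # s
    emission_ref: float = 0.0952    # mg/puff

    def __post_init__(self) -> None:
        if self.emission_ref <= 0 or self.duration_ref <= 0 or self.conc_ref <= 0:
            raise ValueError("calibration reference values must be positive")
        if self.power_ref not in POWER_SETTINGS:
            raise ValueError(f"unknown reference power setting {self.power_ref!r}")


#: An emission strategy maps vectorised (conc mg/mL, duration s,
#: representative wattage W) to mg/puff under a calibration.
EmissionModel = Callable[[np.ndarray, np.ndarray, np.ndarray, EmissionCalibration],
                         np.ndarray]


def separable_emission(conc: np.ndarray, duration_s: np.ndarray,
                       watt_rep: np.ndarray,
                       cal: EmissionCalibration,
                       power_bands: dict[str, PowerBand] = POWER_BANDS,
                       ) -> np.ndarray:
    """Default separable model: linear in each of c, d and wattage."""
    w_ref = power_bands[cal.power_ref].watt_rep
    return (cal.emission_ref
            * (np.asarray(conc, dtype=float) / cal.conc_ref)
            * (np.asarray(duration_s, dtype=float) / cal.duration_ref)
            * (np.asarray(watt_rep, dtype=float) / w_ref))


def estimate_puff_emission(conc: float | None, duration_s: float,
                           power_setting: str,
                           cal: EmissionCalibration = EmissionCalibration(),
                           power_bands: dict[str, PowerBand] = POWER_BANDS,
                           model: EmissionModel | None = None) -> float | None:
    """Estimate the nicotine emission (mg) of a single puff.

    Returns ``None`` for a puff whose concentration is missing (the puff
    is not estimable; it is never imputed).  The result is nonnegative
    and, for the default model, monotone nondecreasing in concentration,
    duration and representative wattage.

    Raises
    ------
    ValueError
        On an unknown power setting or negative concentration.
    """
    if power_setting not in power_bands:
        raise ValueError(f"unknown power setting {power_setting!r}")
    if conc is None or (isinstance(conc, float) and np.isnan(conc)):
        return None
    if conc < 0:
        raise ValueError(f"nicotine concentration must be >= 0, got {conc}")
    fn = model if model is not None else separable_emission
    if fn is separable_emission:
        out = separable_emission(np.array([conc]), np.array([duration_s]),
                                 np.array([power_bands[power_setting].watt_rep]),
                                 cal, power_bands)
    else:
        out = fn(np.array([conc]), np.array([duration_s]),
                 np.array([power_bands[power_setting].watt_rep]), cal)
    return float(out[0])


def add_emission(puffs: pd.DataFrame,
                 cal: EmissionCalibration = EmissionCalibration(),
                 power_bands: dict[str, PowerBand] = POWER_BANDS,
                 model: EmissionModel | None = None) -> pd.DataFrame:
    """Append an ``emission_mg`` column to a puff frame.

    Missing concentrations yield NaN emission (not estimable); all other
    puff fields pass through unchanged.
    """
    unknown = set(puffs["power_setting"].unique()) - set(power_bands)
    if unknown:
        raise ValueError(f"unknown power setting(s) in frame: {sorted(unknown)}")
    watts = puffs["power_setting"].map(
        {name: band.watt_rep for name, band in power_bands.items()}
    ).to_numpy(dtype=float)
    conc = puffs["nicotine_conc_mg_ml"].to_numpy(dtype=float)
    dur = puffs["duration_s"].to_numpy(dtype=float)
    if np.nanmin(conc, initial=0.0) < 0:
        raise ValueError("nicotine concentration must be >= 0")
    fn = model if model is not None else separable_emission
    if fn is separable_emission:
        emission = separable_emission(conc, dur, watts, cal, power_bands)
    else:
        emission = fn(conc, dur, watts, cal)
    out = puffs.copy()
    out["emission_mg"] = emission
    return out


def daily_nicotine(emissions: pd.Series | np.ndarray) -> tuple[float, int, int]:
    """Total nicotine (mg) over one user-day of per-puff emissions.

    Non-estimable puffs (NaN) are excluded from the sum and their count
    reported.

    Returns
    -------
    (total_mg, n_estimable, n_excluded)
    """
    arr = np.asarray(emissions, dtype=float)
    ok = ~np.isnan(arr)
    return float(arr[ok].sum()), int(ok.sum()), int((~ok).sum())


def emission_summary(emissions: pd.Series | np.ndarray) -> dict:
    """Descriptive statistics {mean, median, sd, n} of per-puff emissions.

    An empty (or all-non-estimable) input yields the explicit empty
    summary ``{"n": 0}`` with NaN statistics.
    """
    arr = np.asarray(emissions, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {"mean": float("nan"), "median": float("nan"),
                "sd": float("nan"), "n": 0}
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n": int(arr.size),
    }
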