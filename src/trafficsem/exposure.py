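"""Exposure preprocessing.

Transforms raw hourly pollutant/weather series and a visit schedule into the
model-ready exposure design: multi-station averaging, strictly pre-visit
moving averages, apparent temperature, seasonal sine/cosine terms, and
seasonal residualisation of apparent temperature.

Hourly series are long tables with columns ``station``, ``timestamp``,
``variable`` and ``value``; recognised variables are the four pollutants plus
``at`` (ambient temperature, degC) and ``dpt`` (dew-point temperature, degC).

Conventions (documented here because the analysis they come from leaves them
open):

* a ``w``-hour window for a visit at time ``t`` covers the half-open interval
  ``(t - w, t]``, i.e. the on-the-hour values ending at ``floor(t)``;
* a window mean is missing when the fraction of available hours falls below
  the completeness threshold (default 0.75);
* apparent temperature is computed hourly and then window-averaged (the
  nonlinear dew-point term is applied before averaging);
* the day-of-year angle starts at 0 on January 1st;
* the seasonal regression used to residualise apparent temperature includes
  an intercept and is fit on the analysis visit set of each window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DAYS_PER_YEAR, POLLUTANTS, SEASONAL_COLUMNS, WINDOWS

__all__ = [
    "apparent_temperature",
    "seasonal_terms",
    "station_average",
    "station_average_table",
    "moving_average",
    "residualize_atemp",
    "build_exposure_design",
    "ExposureDesignSet",
    "DegenerateDesignError",
]


class DegenerateDesignError(ValueError):
    """Raised when a regression design is rank deficient."""


def apparent_temperature(at, dpt):
    """Apparent temperature (degC) from ambient and dew-point temperature.

    ``ATemp = -2.653 + 0.994 * AT + 0.0153 * DPT**2``

    Accepts scalars or arrays; inputs must be finite.
    """
    at = np.asarray(at, dtype=float)
    dpt = np.asarray(dpt, dtype=float)
    if not (np.all(np.isfinite(at)) and np.all(np.isfinite(dpt))):
        raise ValueError("apparent_temperature requires finite inputs")
    out = -2.653 + 0.994 * at + 0.0153 * dpt**2
    return float(out) if out.ndim == 0 else out


def _day_of_year(dates) -> np.ndarray:
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]")))
    return idx.dayofyear.to_numpy(dtype=float) - 1.0  # Jan 1 -> 0


def seasonal_terms(visit_date):
    """Return ``(sin, cos)`` of ``2*pi*theta/365.24``.

    ``visit_date`` may be a date (or array of dates), in which case ``theta``
    is the calendar day of year counted from 0 on January 1st, or a numeric
    ``theta`` given directly.
    """
    arr = np.asarray(visit_date)
    if np.issubdtype(arr.dtype, np.number):
        theta = arr.astype(float)
    else:
        theta = _day_of_year(visit_date)
        if np.ndim(visit_date) == 0:
            theta = theta[0]
    ang = 2.0 * np.pi * theta / DAYS_PER_YEAR
    return np.sin(ang), np.cos(ang)


def station_average_table(series: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long hourly series to one row per timestamp.

    Values are averaged across all stations reporting the variable at that
    hour; hours where no station reports remain absent / NaN.
    """
    required = {"station", "timestamp", "variable", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"hourly series missing columns: {sorted(missing)}")
    table = series.pivot_table(
        values="value", index="timestamp", columns="variable", aggfunc="mean"
    )
    table.index = pd.DatetimeIndex(table.index)
    return table.sort_index()


def station_average(series: pd.DataFrame, variable: str, timestamp) -> float:
    """Mean of ``variable`` over stations reporting at ``timestamp``.

    Missing stations are excluded; if no station reports, NaN is returned
    (missingness propagates, it is never imputed as zero).
    """
    ts = pd.Timestamp(timestamp)
    sel = series[(series["variable"] == variable) & (series["timestamp"] == ts)]
    vals = sel["value"].dropna()
    return float(vals.mean()) if len(vals) else float("nan")


def _window_slots(visit_time, window_hours: int) -> pd.DatetimeIndex:
    end = pd.Timestamp(visit_time).floor("h")
    return pd.date_range(end=end, periods=window_hours, freq="h")


def moving_average(
    series: pd.DataFrame,
    variable: str,
    visit_time,
    window_hours: int,
    completeness: float = 0.75,
    table: pd.DataFrame | None = None,
) -> float:
    """Pre-visit moving average of a station-averaged hourly variable.

    Averages over the half-open interval ``(visit_time - window, visit_time]``.
    Returns NaN when the fraction of available hours is below ``completeness``
    or the window precedes the start of the series.
    """
    if window_hours not in WINDOWS:
        warnings.warn(
            f"window of {window_hours} h is outside the standard set {WINDOWS}",
            stacklevel=2,
        )
    if table is None:
        table = station_average_table(series)
    slots = _window_slots(visit_time, window_hours)
    if variable not in table.columns:
        return float("nan")
    vals = table[variable].reindex(slots).to_numpy(dtype=float)
    n_present = int(np.sum(~np.isnan(vals)))
    if n_present / window_hours < completeness:
        return float("nan")
    return float(np.nanmean(vals))


def residualize_atemp(atemp, sine, cosine):
    """Residualise window-averaged apparent temperature on the seasonal basis.

    Fits OLS of ``atemp`` on an intercept plus the sine and cosine columns and
    returns ``(residual, residual**2)``. Residuals are mean zero and
    orthogonal to both seasonal columns by construction.
    """
    atemp = np.asarray(atemp, dtype=float)
    sine = np.asarray(sine, dtype=float)
    cosine = np.asarray(cosine, dtype=float)
    n = atemp.shape[0]
    if n < 3:
        raise ValueError("residualize_atemp requires at least 3 visits")
    design = np.column_stack([np.ones(n), sine, cosine])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateDesignError(
            "seasonal design is rank deficient (are all visits on the same date?)"
        )
    beta, *_ = np.linalg.lstsq(design, atemp, rcond=None)
    resid = atemp - design @ beta
    return resid, resid**2


@dataclass
class ExposureDesignSet:
    """Per-window model-ready exposure designs plus an exclusion log."""

    designs: dict[int, pd.DataFrame]
    exclusions: dict[int, dict] = field(default_factory=dict)
    completeness: float = 0.75

    def __getitem__(self, window: int) -> pd.DataFrame:
        return self.designs[window]

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for w, df in self.designs.items():
            df.to_csv(out / f"design_{w}hr.csv", index=False)
        with open(out / "exclusions.json", "w") as fh:
            json.dump(self.exclusions, fh, indent=2, default=int)


def _cumulative(values: np.ndarray):
    """Prefix sums of values (NaN as 0) and of presence indicators."""
    present = ~np.isnan(values)
    csum = np.concatenate([[0.0], np.cumsum(np.where(present, values, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(present.astype(np.int64))])
    return csum, ccnt


def _window_means(csum, ccnt, end_idx, window, completeness):
    """Vectorised window means from prefix sums; NaN below completeness."""
    hi = end_idx + 1
    lo = hi - window
    valid = (lo >= 0) & (hi <= len(ccnt) - 1)
    lo_c = np.clip(lo, 0, None)
    hi_c = np.clip(hi, 0, len(ccnt) - 1)
    total = csum[hi_c] - csum[lo_c]
    count = ccnt[hi_c] - ccnt[lo_c]
    frac = np.where(valid, count / window, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return np.where(valid & (frac >= completeness), mean, np.nan)


def build_exposure_design(
    hourly: pd.DataFrame,
    visits: pd.DataFrame,
    windows=WINDOWS,
    completeness: float = 0.75,
) -> ExposureDesignSet:
    """Assemble one model-ready exposure design per moving-average window.

    For each visit and window this computes the station-averaged pre-visit
    moving average of every pollutant and of hourly apparent temperature,
    attaches the seasonal sine/cosine terms, and residualises the
    window-averaged apparent temperature on the seasonal basis within the
    retained visit set. Visits with any missing pollutant or apparent
    temperature window mean are excluded from that window's design; exclusion
    counts are logged in the returned :class:`ExposureDesignSet`.
    """
    if visits is None or len(visits) == 0:
        raise ValueError("empty visit table")
    table = station_average_table(hourly)
    if {"at", "dpt"} <= set(table.columns):
        both = table["at"].notna() & table["dpt"].notna()
        atemp = np.full(len(table), np.nan)
        atemp[both.to_numpy()] = apparent_temperature(
            table.loc[both, "at"].to_numpy(), table.loc[both, "dpt"].to_numpy()
        )
        table = table.assign(atemp=atemp)

    full_idx = pd.date_range(table.index.min(), table.index.max(), freq="h")
    arrays = {
        var: table[var].reindex(full_idx).to_numpy(dtype=float)
        for var in table.columns
    }
    cums = {var: _cumulative(arr) for var, arr in arrays.items()}

    vtimes = pd.DatetimeIndex(visits["visit_time"])
    end_idx = (
        (vtimes.floor("h") - full_idx[0]) // pd.Timedelta(hours=1)
    ).to_numpy(dtype=np.int64)
    sine, cosine = seasonal_terms(vtimes)

    designs: dict[int, pd.DataFrame] = {}
    exclusions: dict[int, dict] = {}
    for w in windows:
        cols = {}
        for pol in POLLUTANTS:
            if pol in cums:
                csum, ccnt = cums[pol]
                cols[pol] = _window_means(csum, ccnt, end_idx, w, completeness)
            else:
                cols[pol] = np.full(len(visits), np.nan)
        if "atemp" in cums:
            csum, ccnt = cums["atemp"]
            cols["atemp"] = _window_means(csum, ccnt, end_idx, w, completeness)
        else:
            cols["atemp"] = np.full(len(visits), np.nan)

        df = pd.DataFrame(
            {
                "visit_id": visits["visit_id"].to_numpy(),
                **(
                    {"participant_id": visits["participant_id"].to_numpy()}
                    if "participant_id" in visits.columns
                    else {}
                ),
                "visit_time": vtimes,
                "window": w,
                **cols,
                "sine": sine,
                "cosine": cosine,
            }
        )
        pollutant_missing = {
            pol: int(df[pol].isna().sum()) for pol in POLLUTANTS
        }
        keep = df[list(POLLUTANTS) + ["atemp"]].notna().all(axis=1)
        excluded = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        if len(df) >= 3:
            resid, resid2 = residualize_atemp(
                df["atemp"].to_numpy(), df["sine"].to_numpy(), df["cosine"].to_numpy()
            )
            df["resid_atemp"] = resid
            df["resid_atemp_sq"] = resid2
        else:
            df["resid_atemp"] = np.nan
            df["resid_atemp_sq"] = np.nan
        designs[w] = df[
            ["visit_id"]
            + (["participant_id"] if "participant_id" in df.columns else [])
            + ["visit_time", "window"]
            + list(POLLUTANTS)
            + ["atemp"]
            + list(SEASONAL_COLUMNS)
        ]
        exclusions[w] = {
            "n_visits": int(len(visits)),
            "n_retained": int(len(df)),
            "n_excluded": excluded,
            "missing_by_pollutant": pollutant_missing,
        }
    return ExposureDesignSet(designs=designs, exclusions=exclusions, completeness=completeness)
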