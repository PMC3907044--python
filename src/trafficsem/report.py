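"""Presentation quantities: % change per IQR, posterior sign probabilities,
descriptive tables, factor-loading tables and SEM-vs-BLMM comparisons.

Outcomes are modelled on the natural-log scale (and the latent
parasympathetic tone is on the log-HF scale because the HF loading is fixed
at 1), so the default % change per IQR increase of the reference pollutant is
``100 * (exp(coef * IQR) - 1)``; a linear approximation ``100 * coef * IQR``
is available and the choice is recorded in every summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sem import PosteriorDraws

__all__ = [
    "EffectSummary",
    "percent_change_per_iqr",
    "posterior_probability",
    "descriptives",
    "DescriptiveTable",
    "loading_table",
    "comparison_table",
]

#: hypothesised direction of the traffic/BC effect per outcome.
HYPOTHESIZED_DIRECTION = {
    "parasympathetic": "negative",
    "log_hf": "negative",
    "lfhf": "positive",
    "log_lf_hf": "positive",
}


@dataclass
class EffectSummary:
    """% change in mean outcome per IQR increase, with posterior interval."""

    exposure: str
    outcome: str
    window: int
    percent_change: float
    pi_low: float
    pi_high: float
    posterior_probability: float
    direction: str
    iqr_used: float
    n_visits: int
    method: str = "exp"

    def to_dict(self) -> dict:
        return asdict(self)


def posterior_probability(draws, direction: str) -> float:
    """Fraction of draws with the stated sign."""
    arr = np.asarray(draws, dtype=float).reshape(-1)
    if arr.size == 0:
        raise ValueError("no draws")
    if direction == "negative":
        return float(np.mean(arr < 0))
    if direction == "positive":
        return float(np.mean(arr > 0))
    raise ValueError(f"direction must be 'negative' or 'positive', got {direction!r}")


def percent_change_per_iqr(
    draws,
    iqr: float,
    exposure: str = "traffic",
    outcome: str = "parasympathetic",
    window: int = 24,
    direction: str | None = None,
    n_visits: int = 0,
    method: str = "exp",
) -> EffectSummary:
    """Summarise coefficient draws as % change per IQR increase in exposure.

    Per draw the % change is ``100*(exp(coef*iqr)-1)`` (or ``100*coef*iqr``
    with ``method='linear'``); the summary is the posterior mean with the
    equal-tailed 2.5/97.5 percentile interval, plus the posterior probability
    that the coefficient has the hypothesised sign.
    """
    if iqr <= 0:
        raise ValueError("iqr must be > 0")
    arr = np.asarray(draws, dtype=float).reshape(-1)
    if arr.size == 0:
        raise ValueError("no draws")
    if direction is None:
        direction = HYPOTHESIZED_DIRECTION.get(outcome, "negative")
    if method == "exp":
        pc = 100.0 * (np.exp(arr * iqr) - 1.0)
    elif method == "linear":
        pc = 100.0 * arr * iqr
    else:
        raise ValueError(f"unknown method {method!r}")
    return EffectSummary(
        exposure=exposure,
        outcome=outcome,
        window=window,
        percent_change=float(pc.mean()),
        pi_low=float(np.percentile(pc, 2.5)),
        pi_high=float(np.percentile(pc, 97.5)),
        posterior_probability=posterior_probability(arr, direction),
        direction=direction,
        iqr_used=float(iqr),
        n_visits=int(n_visits),
        method=method,
    )


@dataclass
class DescriptiveTable:
    """Summary statistics plus a Spearman correlation matrix."""

    stats: pd.DataFrame
    spearman: pd.DataFrame


def descriptives(frame: pd.DataFrame, columns: list[str] | None = None) -> DescriptiveTable:
    """Mean/median/SD/5th/95th/IQR per column plus Spearman correlations.

    Correlations are rank based with midranked ties; constant columns yield
    missing correlations.
    """
    if columns is None:
        columns = [c for c in frame.columns if pd.api.types.is_numeric_dtype(frame[c])]
    if len(frame) < 2:
        raise ValueError("descriptives requires at least 2 rows")
    rows = {}
    for c in columns:
        x = frame[c].dropna().to_numpy(dtype=float)
        q25, q75 = np.percentile(x, [25, 75])
        rows[c] = {
            "average": x.mean(),
            "median": np.median(x),
            "sd": x.std(ddof=1),
            "p5": np.percentile(x, 5),
            "p95": np.percentile(x, 95),
            "iqr": q75 - q25,
        }
    stats_df = pd.DataFrame(rows).T

    corr = pd.DataFrame(np.nan, index=columns, columns=columns, dtype=float)
    for i, ci in enumerate(columns):
        for cj in columns[i:]:
            if ci == cj:
                corr.loc[ci, cj] = 1.0 if frame[ci].nunique() >= 2 else np.nan
                continue
            sub = frame[[ci, cj]].dropna()
            if sub[ci].nunique() < 2 or sub[cj].nunique() < 2:
                rho = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho = stats.spearmanr(sub[ci], sub[cj]).statistic
            corr.loc[ci, cj] = corr.loc[cj, ci] = rho
    return DescriptiveTable(stats=stats_df, spearman=corr)


def loading_table(result: PosteriorDraws) -> pd.DataFrame:
    """Factor-loading / variance report for one SEM fit.

    One row per latent variable and indicator, with posterior mean and 95%
    interval for each free loading and for each variance (summaries of the
    reciprocal-precision draws, not reciprocals of precision summaries);
    reference indicators print a loading of exactly 1.00 with no interval.
    """
    def summarise(arr):
        flat = np.asarray(arr).reshape(-1)
        return flat.mean(), np.percentile(flat, 2.5), np.percentile(flat, 97.5)

    rows = []

    def variance_row(tau_name):
        if tau_name in result.draws:
            inv = 1.0 / result.get(tau_name)
            return summarise(inv)
        return (np.nan, np.nan, np.nan)

    window = result.info.get("window", np.nan)
    lat_var = variance_row("tau_traffic")
    rows.append(
        {
            "window": window, "latent": "traffic", "indicator": "",
            "loading": np.nan, "loading_low": np.nan, "loading_high": np.nan,
            "variance": lat_var[0], "variance_low": lat_var[1], "variance_high": lat_var[2],
            "reference": False,
        }
    )
    for name in result.names():
        if name.startswith("lambda0["):
            pol = name[len("lambda0["):-1]
            free = f"lambda1[{pol}]" in result.draws
            if free:
                lmean, llo, lhi = summarise(result.draws[f"lambda1[{pol}]"])
            else:
                lmean, llo, lhi = 1.0, np.nan, np.nan
            v = variance_row(f"tau_x[{pol}]")
            rows.append(
                {
                    "window": window, "latent": "traffic", "indicator": pol,
                    "loading": lmean, "loading_low": llo, "loading_high": lhi,
                    "variance": v[0], "variance_low": v[1], "variance_high": v[2],
                    "reference": not free,
                }
            )
    if "tau_para" in result.draws:
        lat_var = variance_row("tau_para")
        rows.append(
            {
                "window": window, "latent": "parasympathetic_tone", "indicator": "",
                "loading": np.nan, "loading_low": np.nan, "loading_high": np.nan,
                "variance": lat_var[0], "variance_low": lat_var[1], "variance_high": lat_var[2],
                "reference": False,
            }
        )
        for name in result.names():
            if name.startswith("alpha0["):
                mk = name[len("alpha0["):-1]
                free = f"alpha1[{mk}]" in result.draws
                if free:
                    lmean, llo, lhi = summarise(result.draws[f"alpha1[{mk}]"])
                else:
                    lmean, llo, lhi = 1.0, np.nan, np.nan
                v = variance_row(f"tau_y[{mk}]")
                rows.append(
                    {
                        "window": window, "latent": "parasympathetic_tone",
                        "indicator": mk,
                        "loading": lmean, "loading_low": llo, "loading_high": lhi,
                        "variance": v[0], "variance_low": v[1], "variance_high": v[2],
                        "reference": not free,
                    }
                )
    return pd.DataFrame(rows)


def comparison_table(sem_summaries, blmm_summaries) -> pd.DataFrame:
    """Side-by-side SEM vs BLMM effect summaries, keyed by outcome/window.

    Flags rows where the SEM interval is *narrower* than the BLMM interval
    (the opposite of the expected ordering under indicator measurement
    error).
    """
    def frame(summaries, side):
        if not summaries:
            raise ValueError(f"empty {side} summaries")
        df = pd.DataFrame([s.to_dict() for s in summaries])
        df["width"] = df["pi_high"] - df["pi_low"]
        keep = [
            "outcome", "window", "exposure", "percent_change",
            "pi_low", "pi_high", "posterior_probability", "width",
        ]
        return df[keep].rename(
            columns={
                c: f"{c}_{side}" for c in keep if c not in ("outcome", "window")
            }
        )

    sem_df = frame(sem_summaries, "sem")
    blmm_df = frame(blmm_summaries, "blmm")
    merged = sem_df.merge(blmm_df, on=["outcome", "window"], how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("SEM and BLMM summaries do not share outcome/window keys")
    merged = merged.drop(columns="_merge")
    merged["width_ordering_violated"] = merged["width_sem"] < merged["width_blmm"]
    return merged
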