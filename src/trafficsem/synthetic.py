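"""Synthetic study generator.

Produces a full synthetic repeated-measures cohort — hourly pollutant and
weather series, a visit schedule with covariates, latent traffic and
parasympathetic-tone scores, and log-scale HRV outcomes — with exactly the
generative structure the structural equation model assumes, so that every
downstream stage is testable offline and parameter recovery is the natural
acceptance surface.

Two distinct exposure products are generated on purpose:

* ``SyntheticDataset.hourly`` is a plumbing product: hourly pollutant series
  (sinusoidal annual cycle plus noise, truncated at zero) and weather series
  that give the preprocessing stage realistic input.  The generator retains
  the window means of these series (``hourly_window_means``) so the
  preprocessing round trip can be checked exactly.
* The visit table additionally carries model-consistent exposure indicator
  columns drawn directly from the latent-factor measurement model; these are
  the columns used by parameter-recovery experiments and are *not* derived
  from the hourly series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    COVARIATES,
    ConfigurationError,
    DAYS_PER_YEAR,
    LFHF_COLUMN,
    MARKER_COLUMNS,
    MARKERS,
    POLLUTANTS,
    SEASONAL_COLUMNS,
    WINDOWS,
)
from . import exposure

__all__ = [
    "GenerativeTruth",
    "CohortConfig",
    "SyntheticDataset",
    "simulate_cohort",
    "simulate_hourly_pollutants",
    "simulate_hourly_weather",
    "add_modifier_columns",
]


def _default_lambda0():
    return {"bc": 0.83, "co": 0.43, "no": 0.02, "no2": 0.02}


def _default_lambda1():
    return {"bc": 1.0, "co": 0.95, "no": 0.06, "no2": 0.02}


def _default_sigma2_x():
    return {"bc": 0.127, "co": 0.010, "no": 1.1e-4, "no2": 3.2e-5}


def _default_alpha0():
    return {"hf": 6.15, "sdnn": 4.19, "rmssd": 4.20}


def _default_alpha1():
    return {"hf": 1.0, "sdnn": 0.39, "rmssd": 0.56}


def _default_sigma2_y():
    return {"hf": 0.305, "sdnn": 0.074, "rmssd": 0.051}


def _default_gamma_cov():
    return {
        "age": -0.010,
        "glucose": -0.002,
        "bmi": -0.010,
        "ever_smoker": -0.05,
        "room_temp": 0.010,
        "sitting_map": -0.002,
        "alcohol2": 0.05,
        "beta_blocker": -0.05,
        "ace_inhibitor": -0.03,
        "ccb": -0.02,
    }


def _default_delta_cov():
    return {
        "age": 0.002,
        "glucose": -0.002,
        "bmi": 0.005,
        "ever_smoker": 0.05,
        "room_temp": -0.020,
        "sitting_map": 0.001,
        "alcohol2": 0.05,
        "beta_blocker": 0.05,
        "ace_inhibitor": 0.02,
        "ccb": 0.02,
    }


@dataclass
class GenerativeTruth:
    """True parameter values of the generative latent-variable model.

    Measurement defaults (loadings and variances) are the 24-hour window
    values of the fitted measurement models; structural coefficients are
    configurable placeholders since covariate effect magnitudes are not part
    of the published record.
    """

    lambda0: dict = field(default_factory=_default_lambda0)
    lambda1: dict = field(default_factory=_default_lambda1)
    sigma2_x: dict = field(default_factory=_default_sigma2_x)
    sigma2_traffic: float = 0.036
    phi: tuple = (0.05, 0.10, 0.002, 0.0001)
    alpha0: dict = field(default_factory=_default_alpha0)
    alpha1: dict = field(default_factory=_default_alpha1)
    sigma2_y: dict = field(default_factory=_default_sigma2_y)
    sigma2_para: float = 1.728
    gamma_traffic: float = -0.3
    delta_traffic: float = 0.3
    gamma_cov: dict = field(default_factory=_default_gamma_cov)
    delta_cov: dict = field(default_factory=_default_delta_cov)
    gamma_seasonal: tuple = (0.10, -0.10, -0.010, 0.0010)
    delta_seasonal: tuple = (-0.05, 0.05, 0.005, -0.0005)
    sigma2_a: float = 0.5
    sigma2_b: float = 0.4
    sigma2_lfhf: float = 0.6
    #: optional dichotomous effect modifier ("diabetic" or "obese"); the
    #: traffic slopes become gamma_traffic + gamma_mod * M (same for delta).
    modifier: str | None = None
    gamma_mod: float = 0.0
    delta_mod: float = 0.0
    diabetes_prevalence: float = 0.15
    p_obese_and_diabetic: float = 0.08

    def __post_init__(self) -> None:
        for name, d in (("sigma2_x", self.sigma2_x), ("sigma2_y", self.sigma2_y)):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError(f"{name} entries must be >= 0")
        for name, v in (
            ("sigma2_traffic", self.sigma2_traffic),
            ("sigma2_para", self.sigma2_para),
            ("sigma2_a", self.sigma2_a),
            ("sigma2_b", self.sigma2_b),
            ("sigma2_lfhf", self.sigma2_lfhf),
        ):
            if v <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.lambda1["bc"] != 1.0 or self.alpha1["hf"] != 1.0:
            raise ConfigurationError("reference loadings must be exactly 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GenerativeTruth":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("phi", "gamma_seasonal", "delta_seasonal"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _default_hourly_baseline():
    return {"bc": 0.83, "co": 0.43, "no": 0.02, "no2": 0.02}


@dataclass
class CohortConfig:
    """Layout of a synthetic study."""

    n_participants: int = 700
    #: probability weights over visit counts {1, 2, 3, 4}; normalised.
    visit_count_weights: tuple = (214.0, 216.0, 259.0, 11.0)
    study_start: str = "2000-11-01"
    study_end: str = "2009-12-31"
    seed: int = 0
    #: moving-average window (hours) the visit-level indicator columns
    #: represent; one model-consistent design is generated per dataset.
    window: int = 24
    #: draw visit counts multinomially (False) or assign them in exact
    #: proportion to the weights (True).
    exact_visit_counts: bool = False
    truth: GenerativeTruth = field(default_factory=GenerativeTruth)
    stations_per_pollutant: int = 1
    seasonal_amplitude_frac: float = 0.2
    hourly_noise_frac: float = 0.3
    pollutant_noise_frac: float = 0.1
    station_noise_frac: float = 0.1
    hourly_baseline: dict = field(default_factory=_default_hourly_baseline)

    def __post_init__(self) -> None:
        w = np.asarray(self.visit_count_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("visit_count_weights must be 4 nonnegative weights")
        self.visit_count_weights = tuple(w / w.sum())
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ConfigurationError("study_start must precede study_end")
        if self.stations_per_pollutant < 1:
            raise ConfigurationError("stations_per_pollutant must be >= 1")


@dataclass
class SyntheticDataset:
    """A complete synthetic study with the generative truth retained."""

    hourly: pd.DataFrame
    visits: pd.DataFrame
    truth: GenerativeTruth
    latent_scores: pd.DataFrame
    config: CohortConfig
    #: window means of the *hourly* pollutant series at each visit, for
    #: checking the preprocessing round trip.
    hourly_window_means: pd.DataFrame | None = None

    def model_design(self) -> pd.DataFrame:
        """Model-consistent exposure design drawn from the factor model."""
        cols = ["visit_id", "participant_id", "visit_time"] + list(POLLUTANTS) + [
            "atemp"
        ] + list(SEASONAL_COLUMNS)
        out = self.visits[cols].copy()
        out.insert(3, "window", self.config.window)
        return out

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.hourly.to_csv(out / "hourly.csv", index=False)
        self.visits.to_csv(out / "visits.csv", index=False)
        self.latent_scores.to_csv(out / "latent_scores.csv", index=False)
        self.truth.to_json(out / "truth.json")
        with open(out / "data_dictionary.json", "w") as fh:
            json.dump(DATA_DICTIONARY, fh, indent=2)


DATA_DICTIONARY = {
    "hourly.csv": {
        "station": "monitoring station identifier",
        "timestamp": "hour (local), on the hour",
        "variable": "bc | co | no | no2 | at | dpt",
        "value": "bc ug/m3; co, no, no2 ppm; at, dpt degC",
    },
    "visits.csv": {
        "participant_id": "participant index",
        "visit_id": "unique visit index",
        "visit_time": "clinic visit datetime",
        "age": "age at visit, years",
        "glucose": "fasting blood glucose, mg/dL",
        "bmi": "body mass index, kg/m2",
        "ever_smoker": "ever cigarette smoker, 0/1",
        "room_temp": "examination room temperature, degC",
        "sitting_map": "sitting mean arterial pressure, mmHg",
        "alcohol2": ">= 2 servings of alcohol per day, 0/1",
        "beta_blocker": "beta blocker use, 0/1",
        "ace_inhibitor": "ACE inhibitor use, 0/1",
        "ccb": "calcium-channel blocker use, 0/1",
        "diabetic_dx": "physician diagnosis of diabetes, 0/1",
        "diabetic": "diagnosis or fasting glucose > 126 mg/dL, 0/1",
        "obese": "BMI >= 30, 0/1",
        "log_hf": "ln high-frequency power",
        "log_sdnn": "ln 5-min SDNN",
        "log_rmssd": "ln rMSSD",
        "log_lf_hf": "ln LF/HF ratio",
        "bc/co/no/no2": "model-consistent window-average indicator draws",
        "atemp": "window-averaged apparent temperature, degC",
        "sine/cosine": "seasonal basis of the visit date",
        "resid_atemp(_sq)": "seasonal residual of atemp (and its square)",
        "window": "moving-average window (hours) of the indicator columns",
    },
    "latent_scores.csv": {
        "visit_id": "unique visit index",
        "traffic": "true latent traffic score",
        "para_tone": "true latent parasympathetic tone score",
    },
}


def _hourly_index(config: CohortConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.study_start) - pd.Timedelta(hours=max(WINDOWS))
    end = pd.Timestamp(config.study_end) + pd.Timedelta(hours=23)
    return pd.date_range(start, end, freq="h")


def _theta(index: pd.DatetimeIndex) -> np.ndarray:
    return (index.dayofyear.to_numpy(dtype=float) - 1.0) + index.hour.to_numpy() / 24.0


def simulate_hourly_pollutants(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Hourly pollutant series driven by a common hourly traffic factor.

    The factor is an annual sinusoid (scale set by the reference-pollutant
    baseline) plus hourly noise; each pollutant reflects it through its
    generative loading, with small idiosyncratic noise on top, and values are
    truncated at 0.  Each pollutant is reported by
    ``config.stations_per_pollutant`` stations; with more than one station,
    independent station-level noise is added so multi-station averaging is
    exercised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = _hourly_index(config)
    theta = _theta(idx)
    ref_base = config.hourly_baseline["bc"]
    factor = config.seasonal_amplitude_frac * ref_base * np.cos(
        2.0 * np.pi * theta / DAYS_PER_YEAR
    ) + rng.normal(0.0, config.hourly_noise_frac * ref_base, len(idx))
    frames = []
    for pol in POLLUTANTS:
        base = config.hourly_baseline[pol]
        loading = config.truth.lambda1[pol]
        common = base + loading * factor + rng.normal(
            0.0, config.pollutant_noise_frac * base, len(idx)
        )
        for s in range(config.stations_per_pollutant):
            vals = common
            if config.stations_per_pollutant > 1:
                vals = common + rng.normal(
                    0.0, config.station_noise_frac * base, len(idx)
                )
            frames.append(
                pd.DataFrame(
                    {
                        "station": f"{pol}_st{s}",
                        "timestamp": idx,
                        "variable": pol,
                        "value": np.clip(vals, 0.0, None),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_hourly_weather(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Hourly ambient and dew-point temperature at a single airport station."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    idx = _hourly_index(config)
    theta = _theta(idx)
    at = (
        10.8
        + 12.5 * np.cos(2.0 * np.pi * (theta - 201.0) / DAYS_PER_YEAR)
        + rng.normal(0.0, 3.0, len(idx))
    )
    dpt = at - 5.0 + rng.normal(0.0, 2.0, len(idx))
    return pd.concat(
        [
            pd.DataFrame(
                {"station": "airport", "timestamp": idx, "variable": "at", "value": at}
            ),
            pd.DataFrame(
                {"station": "airport", "timestamp": idx, "variable": "dpt", "value": dpt}
            ),
        ],
        ignore_index=True,
    )


def _visit_counts(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    weights = np.asarray(config.visit_count_weights)
    if config.exact_visit_counts:
        counts = np.floor(weights * config.n_participants).astype(int)
        counts[1] = max(counts[1], 0)
        while counts.sum() < config.n_participants:
            counts[np.argmax(weights * config.n_participants - counts)] += 1
        per_participant = np.repeat(np.arange(1, 5), counts)
        rng.shuffle(per_participant)
        return per_participant
    return rng.choice(np.arange(1, 5), size=config.n_participants, p=weights)


def add_modifier_columns(visits: pd.DataFrame) -> pd.DataFrame:
    """Attach the dichotomous effect-modifier columns.

    ``diabetic`` is a physician diagnosis or fasting glucose > 126 mg/dL;
    ``obese`` is BMI >= 30.
    """
    out = visits.copy()
    dx = out["diabetic_dx"] if "diabetic_dx" in out.columns else 0
    out["diabetic"] = ((dx == 1) | (out["glucose"] > 126.0)).astype(int)
    out["obese"] = (out["bmi"] >= 30.0).astype(int)
    return out


def simulate_cohort(config: CohortConfig) -> SyntheticDataset:
    """Generate a full synthetic study.

    For each visit, the latent traffic score is drawn from its seasonal
    structural model, pollutant indicators from the exposure measurement
    model, latent parasympathetic tone from its structural model (traffic,
    covariates, seasonal terms and a subject random intercept), HRV markers
    from the outcome measurement model, and log LF/HF from its own structural
    model. Identical seeds yield identical datasets.
    """
    truth = config.truth
    rng = np.random.default_rng(config.seed)

    # --- participants and visit schedule -------------------------------
    n_visits_per = _visit_counts(config, rng)
    n_total = int(n_visits_per.sum())
    pidx = np.repeat(np.arange(config.n_participants), n_visits_per)

    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    total_days = (end - start).days
    day_offsets = rng.integers(0, total_days + 1, size=n_total)
    tmp = pd.DataFrame({"p": pidx, "d": day_offsets})
    day_offsets = tmp.sort_values(["p", "d"], kind="stable")["d"].to_numpy()
    hours = rng.integers(8, 17, size=n_total)
    visit_time = (
        start
        + pd.to_timedelta(day_offsets, unit="D")
        + pd.to_timedelta(hours, unit="h")
    )

    # --- covariates ----------------------------------------------------
    mid = start + (end - start) / 2
    age_base = rng.normal(75.0, 6.7, config.n_participants)
    bmi = rng.normal(28.1, 4.2, config.n_participants)
    obese_p = (bmi >= 30.0).astype(int)
    p_ob = max(obese_p.mean(), 1e-9)
    prev = truth.diabetes_prevalence
    p_joint = min(truth.p_obese_and_diabetic, prev)
    p_d_given_ob = min(p_joint / p_ob, 1.0)
    p_d_given_not = min(max(prev - p_joint, 0.0) / max(1.0 - p_ob, 1e-9), 1.0)
    u = rng.random(config.n_participants)
    diabetic_dx = np.where(obese_p == 1, u < p_d_given_ob, u < p_d_given_not).astype(int)
    glucose_p = np.where(
        diabetic_dx == 1,
        rng.normal(140.0, 25.0, config.n_participants),
        rng.normal(97.0, 12.0, config.n_participants),
    )
    ever_smoker = (rng.random(config.n_participants) < 0.695).astype(int)
    alcohol2 = (rng.random(config.n_participants) < 0.20).astype(int)
    beta_blocker = (rng.random(config.n_participants) < 0.40).astype(int)
    ace_inhibitor = (rng.random(config.n_participants) < 0.30).astype(int)
    ccb = (rng.random(config.n_participants) < 0.15).astype(int)

    elapsed_years = (visit_time - mid) / pd.Timedelta(days=365.25)
    cov = pd.DataFrame(
        {
            "age": age_base[pidx] + elapsed_years,
            "glucose": glucose_p[pidx],
            "bmi": bmi[pidx],
            "ever_smoker": ever_smoker[pidx],
            "room_temp": rng.normal(23.0, 2.0, n_total),
            "sitting_map": rng.normal(95.0, 10.0, n_total),
            "alcohol2": alcohol2[pidx],
            "beta_blocker": beta_blocker[pidx],
            "ace_inhibitor": ace_inhibitor[pidx],
            "ccb": ccb[pidx],
        }
    )

    # --- hourly series and visit-level seasonal / temperature terms -----
    hourly_pol = simulate_hourly_pollutants(config, rng)
    hourly_wx = simulate_hourly_weather(config, rng)
    hourly = pd.concat([hourly_pol, hourly_wx], ignore_index=True)

    idx = _hourly_index(config)
    wx_at = hourly_wx.loc[hourly_wx["variable"] == "at", "value"].to_numpy()
    wx_dpt = hourly_wx.loc[hourly_wx["variable"] == "dpt", "value"].to_numpy()
    atemp_hourly = exposure.apparent_temperature(wx_at, wx_dpt)
    csum = np.concatenate([[0.0], np.cumsum(atemp_hourly)])
    end_idx = (
        (pd.DatetimeIndex(visit_time).floor("h") - idx[0]) // pd.Timedelta(hours=1)
    ).to_numpy(dtype=np.int64)
    w = config.window
    atemp_visit = (csum[end_idx + 1] - csum[end_idx + 1 - w]) / w

    sine, cosine = exposure.seasonal_terms(pd.DatetimeIndex(visit_time))
    resid, resid2 = exposure.residualize_atemp(atemp_visit, sine, cosine)
    S = np.column_stack([sine, cosine, resid, resid2])

    # --- hourly-series window means retained for round-trip checks ------
    visit_id = np.arange(n_total)
    hwm_rows = []
    pol_avg = {
        pol: hourly_pol.loc[hourly_pol["variable"] == pol]
        .groupby("timestamp")["value"]
        .mean()
        .reindex(idx)
        .to_numpy()
        for pol in POLLUTANTS
    }
    for pol, arr in pol_avg.items():
        cs = np.concatenate([[0.0], np.cumsum(arr)])
        for win in WINDOWS:
            ok = end_idx + 1 - win >= 0
            means = np.full(n_total, np.nan)
            means[ok] = (cs[end_idx[ok] + 1] - cs[end_idx[ok] + 1 - win]) / win
            hwm_rows.append(
                pd.DataFrame(
                    {"visit_id": visit_id, "window": win, "pollutant": pol, "value": means}
                )
            )
    hourly_window_means = pd.concat(hwm_rows, ignore_index=True)

    # --- latent traffic and exposure indicators ------------------------
    phi = np.asarray(truth.phi, dtype=float)
    traffic = S @ phi + rng.normal(0.0, np.sqrt(truth.sigma2_traffic), n_total)
    X = {}
    for pol in POLLUTANTS:
        X[pol] = (
            truth.lambda0[pol]
            + truth.lambda1[pol] * traffic
            + rng.normal(0.0, np.sqrt(truth.sigma2_x[pol]), n_total)
        )

    # --- structural outcomes -------------------------------------------
    cov_mod = add_modifier_columns(
        cov.assign(diabetic_dx=diabetic_dx[pidx])
    )
    if truth.modifier is not None:
        M = cov_mod[truth.modifier].to_numpy(dtype=float)
    else:
        M = np.zeros(n_total)
    g1 = truth.gamma_traffic + truth.gamma_mod * M
    d1 = truth.delta_traffic + truth.delta_mod * M

    Z = cov[list(COVARIATES)].to_numpy(dtype=float)
    gcov = np.array([truth.gamma_cov[c] for c in COVARIATES])
    dcov = np.array([truth.delta_cov[c] for c in COVARIATES])
    gseas = np.asarray(truth.gamma_seasonal, dtype=float)
    dseas = np.asarray(truth.delta_seasonal, dtype=float)

    a_i = rng.normal(0.0, np.sqrt(truth.sigma2_a), config.n_participants)
    b_i = rng.normal(0.0, np.sqrt(truth.sigma2_b), config.n_participants)

    para = (
        g1 * traffic
        + Z @ gcov
        + S @ gseas
        + a_i[pidx]
        + rng.normal(0.0, np.sqrt(truth.sigma2_para), n_total)
    )
    Y = {}
    for mk in MARKERS:
        Y[MARKER_COLUMNS[mk]] = (
            truth.alpha0[mk]
            + truth.alpha1[mk] * para
            + rng.normal(0.0, np.sqrt(truth.sigma2_y[mk]), n_total)
        )
    lfhf = (
        d1 * traffic
        + Z @ dcov
        + S @ dseas
        + b_i[pidx]
        + rng.normal(0.0, np.sqrt(truth.sigma2_lfhf), n_total)
    )

    visits = pd.DataFrame(
        {
            "participant_id": pidx,
            "visit_id": visit_id,
            "visit_time": pd.DatetimeIndex(visit_time),
        }
    )
    visits = pd.concat([visits, cov_mod.reset_index(drop=True)], axis=1)
    for col, vals in {**X}.items():
        visits[col] = vals
    visits["atemp"] = atemp_visit
    visits["sine"] = sine
    visits["cosine"] = cosine
    visits["resid_atemp"] = resid
    visits["resid_atemp_sq"] = resid2
    visits["window"] = w
    for col, vals in Y.items():
        visits[col] = vals
    visits[LFHF_COLUMN] = lfhf

    latent_scores = pd.DataFrame(
        {"visit_id": visit_id, "traffic": traffic, "para_tone": para}
    )
    return SyntheticDataset(
        hourly=hourly,
        visits=visits,
        truth=truth,
        latent_scores=latent_scores,
        config=config,
        hourly_window_means=hourly_window_means,
    )
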