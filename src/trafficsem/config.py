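"""Shared column vocabularies and small configuration dataclasses.

The package works on plain :class:`pandas.DataFrame` tables; the tuples below
pin down the canonical column names used throughout so that every stage of the
pipeline (simulation, preprocessing, model fitting, reporting) speaks the same
dialect.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Traffic-related pollutant indicators; ``bc`` is the reference indicator
#: whose loading is fixed at 1 to set the latent scale.
POLLUTANTS: tuple[str, ...] = ("bc", "co", "no", "no2")

#: Parasympathetic-tone marker keys (log scale); ``hf`` is the reference
#: marker whose loading is fixed at 1.
MARKERS: tuple[str, ...] = ("hf", "sdnn", "rmssd")

#: Visit-table column holding each log-scale marker.
MARKER_COLUMNS: dict[str, str] = {
    "hf": "log_hf",
    "sdnn": "log_sdnn",
    "rmssd": "log_rmssd",
}

#: Visit-table column holding the (log) sympathetic balance marker.
LFHF_COLUMN: str = "log_lf_hf"

#: Fixed covariates entering both structural equations, in canonical order.
COVARIATES: tuple[str, ...] = (
    "age",
    "glucose",
    "bmi",
    "ever_smoker",
    "room_temp",
    "sitting_map",
    "alcohol2",
    "beta_blocker",
    "ace_inhibitor",
    "ccb",
)

#: Seasonal / temperature adjustment columns added by exposure preprocessing.
SEASONAL_COLUMNS: tuple[str, ...] = ("sine", "cosine", "resid_atemp", "resid_atemp_sq")

#: Pre-visit moving-average windows (hours) used throughout.
WINDOWS: tuple[int, ...] = (4, 24, 48, 72)

#: Tropical-year length used by the seasonal basis.
DAYS_PER_YEAR: float = 365.24


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass
class PriorSpec:
    """Vague conjugate priors shared by the SEM and BLMM samplers.

    All free intercepts, loadings and regression coefficients receive a
    Normal(0, ``coef_variance``) prior; every precision (measurement, latent,
    residual and random-intercept) receives a Gamma(``precision_shape``,
    ``precision_rate``) prior.
    """

    coef_variance: float = 1e6
    precision_shape: float = 1e-3
    precision_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.coef_variance <= 0:
            raise ConfigurationError("coef_variance must be > 0")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ConfigurationError("precision prior shape/rate must be > 0")


@dataclass
class MCMCSettings:
    """Chain layout for the Gibbs samplers."""

    chains: int = 2
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    init_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ConfigurationError("iterations must exceed burn_in")
        if self.chains < 1 or self.thin < 1:
            raise ConfigurationError("chains and thin must be >= 1")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin
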