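"""Comparison Bayesian linear mixed model and its frequentist REML oracle.

The BLMM regresses a single log-scale outcome (log HF or log LF/HF) on one
pollutant's moving average, the fixed covariates, seasonal terms and a
subject random intercept, by Gibbs sampling with the same conjugate priors
as the SEM.  ``fit_lmm_reml`` maximises the restricted likelihood of the same
random-intercept model directly (profiled fixed effects, log-variance
parameterisation) and serves as a deterministic internal oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import _samplers
from .config import (
    COVARIATES,
    ConfigurationError,
    MCMCSettings,
    PriorSpec,
    SEASONAL_COLUMNS,
)
from .sem import PosteriorDraws, _diagnostics

__all__ = ["BLMMSpec", "LMMResult", "fit_blmm", "fit_lmm_reml", "SingularDesignError"]

_OUTCOME_ALIASES = {
    "loghf": "log_hf",
    "hf": "log_hf",
    "log_hf": "log_hf",
    "loglfhf": "log_lf_hf",
    "lfhf": "log_lf_hf",
    "log_lf_hf": "log_lf_hf",
}


class SingularDesignError(ValueError):
    """Raised when the fixed-effects design is rank deficient."""


@dataclass
class BLMMSpec:
    """Configuration of one BLMM (or REML) fit."""

    outcome: str = "log_hf"
    exposure: str = "bc"
    window: int = 24
    covariates: tuple = COVARIATES
    include_seasonal: bool = True
    random_intercept: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        key = self.outcome.replace("/", "").lower()
        if key not in _OUTCOME_ALIASES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        self.outcome = _OUTCOME_ALIASES[key]


def _assemble(design: pd.DataFrame, visits: pd.DataFrame, spec: BLMMSpec):
    dcols = ["visit_id", spec.exposure] + list(SEASONAL_COLUMNS)
    vcols = ["visit_id", "participant_id", spec.outcome] + list(spec.covariates)
    for frame, cols, label in ((design, dcols, "design"), (visits, vcols, "visits")):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"{label} table is missing columns: {missing}")
    merged = design[dcols].merge(visits[vcols], on="visit_id", how="inner")
    merged = merged.dropna(subset=[c for c in merged.columns if c != "visit_id"])
    merged = merged.reset_index(drop=True)
    if merged.empty:
        raise ValueError("no complete-case visits")

    names = ["const", spec.exposure] + list(spec.covariates)
    cols = [np.ones(len(merged)), merged[spec.exposure].to_numpy(dtype=float)]
    for c in spec.covariates:
        cols.append(merged[c].to_numpy(dtype=float))
    if spec.include_seasonal:
        names += list(SEASONAL_COLUMNS)
        for c in SEASONAL_COLUMNS:
            cols.append(merged[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise SingularDesignError(f"collinear fixed-effect columns: {bad}")
    y = merged[spec.outcome].to_numpy(dtype=float)
    codes, uniques = pd.factorize(merged["participant_id"], sort=True)
    return X, y, codes, np.bincount(codes), names, merged


def fit_blmm(design: pd.DataFrame, visits: pd.DataFrame, spec: BLMMSpec,
             compute_diagnostics: bool = True) -> PosteriorDraws:
    """Gibbs sampler for the random-intercept Bayesian linear mixed model."""
    X, y, pidx, n_i, names, merged = _assemble(design, visits, spec)
    n, p = X.shape
    n_groups = len(n_i)
    mc, pr = spec.mcmc, spec.priors
    v0 = 1.0 / pr.coef_variance
    a0, b0 = pr.precision_shape, pr.precision_rate
    kept = mc.kept_per_chain

    par_names = [f"beta[{nm}]" for nm in names] + ["tau_resid"]
    if spec.random_intercept:
        par_names.append("tau_ri")
    store = np.empty((mc.chains, kept, len(par_names)))

    root = np.random.SeedSequence(mc.seed)
    for ci, ss in enumerate(root.spawn(mc.chains)):
        rng = np.random.default_rng(ss)
        beta = mc.init_jitter * rng.standard_normal(p)
        c = np.zeros(n_groups)
        tau_e, tau_c = 1.0, 1.0
        k = 0
        for it in range(mc.iterations):
            beta = _samplers.draw_linreg(X, y - c[pidx], tau_e, v0, rng)
            fitted = X @ beta
            if spec.random_intercept:
                prec = tau_c + n_i * tau_e
                num = tau_e * np.bincount(pidx, weights=y - fitted, minlength=n_groups)
                c = _samplers.draw_scalar_normal(num, prec, rng)
                tau_c = _samplers.draw_precision(c, a0, b0, rng)
            tau_e = _samplers.draw_precision(y - fitted - c[pidx], a0, b0, rng)
            if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0 and k < kept:
                row = list(beta) + [tau_e] + ([tau_c] if spec.random_intercept else [])
                store[ci, k] = row
                k += 1

    draws = {name: store[:, :, i] for i, name in enumerate(par_names)}
    diag = _diagnostics(draws) if compute_diagnostics and mc.chains > 1 else None
    info = {
        "n_visits": int(n),
        "n_participants": int(n_groups),
        "outcome": spec.outcome,
        "exposure": spec.exposure,
        "window": spec.window,
    }
    return PosteriorDraws(draws=draws, diagnostics=diag, info=info)


@dataclass
class LMMResult:
    """REML point estimates for the random-intercept model."""

    params: pd.Series
    bse: pd.Series
    sigma2_resid: float
    sigma2_group: float
    reml_criterion: float
    n_visits: int
    n_groups: int
    converged: bool


def _reml_pieces(X, y, pidx, n_i, s2e, s2a):
    """Profile the fixed effects out of the REML criterion.

    Uses the closed-form inverse of V = s2e I + s2a J within each group.
    """
    n, p = X.shape
    n_groups = len(n_i)
    # group sums
    Xsum = np.zeros((n_groups, p))
    for j in range(p):
        Xsum[:, j] = np.bincount(pidx, weights=X[:, j], minlength=n_groups)
    ysum = np.bincount(pidx, weights=y, minlength=n_groups)
    cg = s2a / (s2e + n_i * s2a)  # (I,)

    XtVX = (X.T @ X - Xsum.T @ (cg[:, None] * Xsum)) / s2e
    XtVy = (X.T @ y - Xsum.T @ (cg * ysum)) / s2e
    ytVy = (y @ y - ysum @ (cg * ysum)) / s2e
    beta = np.linalg.solve(XtVX, XtVy)
    ypy = ytVy - XtVy @ beta
    logdetV = float(np.sum((n_i - 1) * np.log(s2e) + np.log(s2e + n_i * s2a)))
    sign, logdetA = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise SingularDesignError("X'V^-1 X is not positive definite")
    return beta, XtVX, -0.5 * (logdetV + logdetA + ypy)


def fit_lmm_reml(design: pd.DataFrame, visits: pd.DataFrame, spec: BLMMSpec) -> LMMResult:
    """Maximise the REML criterion of the random-intercept Gaussian model.

    The two variance components are optimised on the log scale (unconstrained
    search, tolerance 1e-10 on the criterion); fixed effects are profiled out
    and recovered by GLS at the optimum. Deterministic given the data.
    """
    X, y, pidx, n_i, names, merged = _assemble(design, visits, spec)
    n, p = X.shape

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s2_start = max(float(resid @ resid) / max(n - p, 1), 1e-8)

    def negloglik(theta):
        s2e = float(np.exp(np.clip(theta[0], -40, 40)))
        s2a = float(np.exp(np.clip(theta[1], -40, 40)))
        try:
            return -_reml_pieces(X, y, pidx, n_i, s2e, s2a)[2]
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.log([s2_start / 2.0, s2_start / 2.0])
    res = optimize.minimize(
        negloglik, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
    )
    if not res.success:
        raise RuntimeError(f"REML optimisation failed to converge: {res.message}")
    s2e, s2a = np.exp(res.x)
    beta, XtVX, crit = _reml_pieces(X, y, pidx, n_i, s2e, s2a)
    cov = np.linalg.inv(XtVX)
    return LMMResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        sigma2_resid=float(s2e),
        sigma2_group=float(s2a),
        reml_criterion=float(crit),
        n_visits=int(n),
        n_groups=int(len(n_i)),
        converged=bool(res.success),
    )
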