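"""Bayesian structural equation model with repeated measures.

The model couples a latent traffic-pollution exposure, reflected by four
pollutant indicators, to either a latent parasympathetic tone reflected by
three log-scale HRV markers, or to the observed log LF/HF sympathetic-balance
marker (or to both jointly):

* exposure measurement: ``X_vj ~ N(lambda0_j + lambda1_j * T_v, 1/tau^X_j)``
  with the reference pollutant loading fixed at 1;
* latent exposure: ``T_v ~ N(S_v @ phi, 1/tau^T)`` where ``S`` holds the
  seasonal sine/cosine and apparent-temperature residual terms (no intercept;
  latent locations are fixed at zero);
* outcome measurement: ``Y_vk ~ N(alpha0_k + alpha1_k * P_v, 1/tau^Y_k)``
  with the reference marker loading fixed at 1;
* structural: ``P_v ~ N(gamma1 * T_v + Z_v @ gamma + a_i, 1/tau^P)`` with a
  subject random intercept ``a_i ~ N(0, 1/tau_a)`` (and the analogous
  ``delta`` equation with intercept ``b_i`` for log LF/HF).

With a dichotomous effect modifier ``M`` the traffic slope becomes
``gamma1 + gamma_int * M`` via a latent-by-modifier interaction construct.

Everything is linear-Gaussian, so posterior sampling uses a blocked Gibbs
sweep whose full conditionals are all Normal or Gamma; each update lives in
its own method of :class:`GibbsSampler` so it can be validated in isolation
against its closed-form conditional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _samplers
from ._samplers import NumericalStabilityError
from .config import (
    COVARIATES,
    ConfigurationError,
    LFHF_COLUMN,
    MARKER_COLUMNS,
    MARKERS,
    MCMCSettings,
    POLLUTANTS,
    PriorSpec,
    SEASONAL_COLUMNS,
)

__all__ = [
    "SEMSpec",
    "SEMModel",
    "GibbsSampler",
    "PosteriorDraws",
    "build_sem",
    "fit_sem",
    "fit_effect_modification",
    "NumericalStabilityError",
]

PARA = "parasympathetic"
LFHF = "lfhf"
JOINT = "joint"


@dataclass
class SEMSpec:
    """Configuration of one SEM fit (one moving-average window)."""

    window: int = 24
    outcome: str = PARA  # "parasympathetic", "lfhf" or "joint"
    reference_pollutant: str = "bc"
    reference_marker: str = "hf"
    pollutants: tuple = POLLUTANTS
    markers: tuple = MARKERS
    covariates: tuple = COVARIATES
    include_seasonal: bool = True
    #: name of a dichotomous modifier column in the visit table; adds a
    #: latent-by-modifier interaction to each structural equation.
    modifier: str | None = None
    #: center the structural covariate columns in-sample. The latent-location
    #: constraint (no structural intercept) makes raw high-mean covariates
    #: nearly collinear with the level of the latent variable; centering
    #: leaves every slope parameter untouched and only shifts the meaning of
    #: the measurement intercepts.
    center_covariates: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    #: single-indicator degenerate mode: the latent equals its (only)
    #: indicator exactly and a free intercept enters the structural equation;
    #: the SEM then reduces to a Bayesian linear mixed model.
    collapse_single_indicator: bool = False
    store_latent_draws: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in (PARA, LFHF, JOINT):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.reference_pollutant not in self.pollutants:
            raise ConfigurationError("reference pollutant not in pollutant list")
        if self.outcome in (PARA, JOINT) and self.reference_marker not in self.markers:
            raise ConfigurationError("reference marker not in marker list")
        if self.collapse_single_indicator and len(self.pollutants) != 1:
            raise ConfigurationError(
                "collapse_single_indicator requires a single pollutant indicator"
            )

    @property
    def has_para(self) -> bool:
        return self.outcome in (PARA, JOINT)

    @property
    def has_lfhf(self) -> bool:
        return self.outcome in (LFHF, JOINT)


@dataclass
class SEMModel:
    """Assembled data arrays and index maps for one SEM fit."""

    spec: SEMSpec
    X: np.ndarray            # (n, J) pollutant indicators, reference first
    Y: np.ndarray | None     # (n, K) log HRV markers, reference first
    L: np.ndarray | None     # (n,) log LF/HF
    S: np.ndarray            # (n, 4) seasonal / atemp-residual design
    Z: np.ndarray            # (n, p) structural covariate design
    M: np.ndarray | None     # (n,) dichotomous modifier
    pidx: np.ndarray         # (n,) participant codes 0..I-1
    n_i: np.ndarray          # (I,) visits per participant
    pollutant_names: tuple
    marker_names: tuple
    z_names: tuple
    visit_ids: np.ndarray
    participant_ids: np.ndarray
    info: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_participants(self) -> int:
        return self.n_i.shape[0]

    def gamma_names(self) -> tuple:
        names = ["traffic"]
        if self.M is not None:
            names.append("traffic_x_mod")
        names.extend(self.z_names)
        return tuple(names)


def build_sem(design: pd.DataFrame, visits: pd.DataFrame, spec: SEMSpec) -> SEMModel:
    """Merge the exposure design with the visit table and assemble arrays.

    Complete-case: visits missing any indicator, outcome or covariate used by
    the fit are dropped and counted in ``model.info``.
    """
    pols = [spec.reference_pollutant] + [
        p for p in spec.pollutants if p != spec.reference_pollutant
    ]
    design_cols = ["visit_id"] + pols + list(SEASONAL_COLUMNS)
    missing = [c for c in design_cols if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns: {missing}")

    vcols = ["visit_id", "participant_id"] + list(spec.covariates)
    if spec.has_para:
        vcols += [MARKER_COLUMNS[m] for m in spec.markers]
    if spec.has_lfhf:
        vcols += [LFHF_COLUMN]
    if spec.modifier is not None:
        if spec.modifier not in visits.columns:
            raise ValueError(f"modifier column {spec.modifier!r} not in visit table")
        vcols.append(spec.modifier)
    missing = [c for c in vcols if c not in visits.columns]
    if missing:
        raise ValueError(f"visit table is missing columns: {missing}")

    merged = design[design_cols].merge(visits[vcols], on="visit_id", how="inner")
    if merged.empty:
        raise ValueError("design and visit table share no visits")
    n_before = len(merged)
    used = [c for c in merged.columns if c != "visit_id"]
    merged = merged.dropna(subset=used).reset_index(drop=True)
    n_dropped = n_before - len(merged)
    if merged.empty:
        raise ValueError("no complete-case visits left after dropping missing data")

    codes, uniques = pd.factorize(merged["participant_id"], sort=True)
    n_i = np.bincount(codes)

    markers = ()
    Y = None
    if spec.has_para:
        markers = tuple(
            [spec.reference_marker]
            + [m for m in spec.markers if m != spec.reference_marker]
        )
        Y = merged[[MARKER_COLUMNS[m] for m in markers]].to_numpy(dtype=float)
    L = merged[LFHF_COLUMN].to_numpy(dtype=float) if spec.has_lfhf else None

    z_names = list(spec.covariates)
    if spec.include_seasonal:
        z_names += list(SEASONAL_COLUMNS)
    Zparts = [merged[list(spec.covariates)].to_numpy(dtype=float)] if spec.covariates else []
    if spec.include_seasonal:
        Zparts.append(merged[list(SEASONAL_COLUMNS)].to_numpy(dtype=float))
    Z = np.column_stack(Zparts) if Zparts else np.empty((len(merged), 0))
    z_means = np.zeros(Z.shape[1])
    if spec.center_covariates and Z.size:
        z_means = Z.mean(axis=0)
        Z = Z - z_means
    if spec.collapse_single_indicator:
        Z = np.column_stack([np.ones(len(merged)), Z])
        z_names = ["const"] + z_names
        z_means = np.concatenate([[0.0], z_means])

    M = None
    if spec.modifier is not None:
        M = merged[spec.modifier].to_numpy(dtype=float)

    model = SEMModel(
        spec=spec,
        X=merged[pols].to_numpy(dtype=float),
        Y=Y,
        L=L,
        S=merged[list(SEASONAL_COLUMNS)].to_numpy(dtype=float),
        Z=Z,
        M=M,
        pidx=codes,
        n_i=n_i,
        pollutant_names=tuple(pols),
        marker_names=markers,
        z_names=tuple(z_names),
        visit_ids=merged["visit_id"].to_numpy(),
        participant_ids=uniques.to_numpy(),
        info={
            "n_visits": int(len(merged)),
            "n_participants": int(len(n_i)),
            "n_dropped_incomplete": int(n_dropped),
            "window": spec.window,
            "z_means": dict(zip(z_names, np.round(z_means, 10))),
        },
    )
    if np.all(n_i == 1):
        model.info["random_intercept_unidentifiable"] = True
        warnings.warn(
            "every participant has a single visit: the random-intercept "
            "variance is unidentifiable from the data",
            stacklevel=2,
        )
    return model


class GibbsSampler:
    """Blocked Gibbs sampler for :class:`SEMModel`.

    Every ``update_*`` method draws one parameter block from its exact full
    conditional given the current state, so each block can be exercised in
    isolation; :meth:`step` performs one full sweep.
    """

    def __init__(self, model: SEMModel, rng: np.random.Generator,
                 init_jitter: float = 0.0):
        self.m = model
        self.spec = model.spec
        self.rng = rng
        pr = self.spec.priors
        self.v0 = 1.0 / pr.coef_variance
        self.a0 = pr.precision_shape
        self.b0 = pr.precision_rate
        self._init_state(init_jitter)

    # ------------------------------------------------------------ state
    def _init_state(self, jitter: float) -> None:
        m, rng = self.m, self.rng
        n, J = m.X.shape
        jit = lambda size: jitter * rng.standard_normal(size)

        self.lam0 = m.X.mean(axis=0) + jit(J)
        self.lam1 = np.ones(J)
        if J > 1:
            self.lam1[1:] += jit(J - 1)
        self.tau_x = np.ones(J)
        self.phi = np.zeros(4) + jit(4)
        self.tau_T = 1.0
        if self.spec.collapse_single_indicator:
            self.T = m.X[:, 0].copy()
        else:
            self.T = m.X[:, 0] - m.X[:, 0].mean()

        q = len(m.gamma_names())
        if self.spec.has_para:
            K = m.Y.shape[1]
            self.alpha0 = m.Y.mean(axis=0) + jit(K)
            self.alpha1 = np.ones(K)
            if K > 1:
                self.alpha1[1:] += jit(K - 1)
            self.tau_y = np.ones(K)
            self.tau_P = 1.0
            if self.spec.collapse_single_indicator:
                self.P = m.Y[:, 0].copy()
            else:
                self.P = m.Y[:, 0] - m.Y[:, 0].mean()
            self.gamma = np.zeros(q) + jit(q)
            self.a = np.zeros(m.n_participants)
            self.tau_a = 1.0
        if self.spec.has_lfhf:
            self.delta = np.zeros(q) + jit(q)
            self.b = np.zeros(m.n_participants)
            self.tau_b = 1.0
            self.tau_L = 1.0
        self._W_cache = None

    # ------------------------------------------------------- structural
    def _slope(self, coef: np.ndarray):
        """Effective traffic slope per visit (scalar without a modifier)."""
        if self.m.M is None:
            return coef[0]
        return coef[0] + coef[1] * self.m.M

    def _zcoef(self, coef: np.ndarray) -> np.ndarray:
        off = 1 if self.m.M is None else 2
        return coef[off:]

    def _W(self) -> np.ndarray:
        """Structural design [T (, T*M), Z]; cached until T changes."""
        if self._W_cache is None:
            cols = [self.T]
            if self.m.M is not None:
                cols.append(self.T * self.m.M)
            if self.m.Z.size:
                cols.append(self.m.Z)
            self._W_cache = np.column_stack(cols)
        return self._W_cache

    # ---------------------------------------------------- latent scores
    def update_traffic(self) -> None:
        m = self.m
        prec = self.tau_T + float((self.lam1**2) @ self.tau_x)
        num = (m.S @ self.phi) * self.tau_T + (m.X - self.lam0) @ (self.lam1 * self.tau_x)
        if self.spec.has_para:
            s = self._slope(self.gamma)
            rest = m.Z @ self._zcoef(self.gamma) + self.a[m.pidx]
            num = num + s * self.tau_P * (self.P - rest)
            prec = prec + s * s * self.tau_P
        if self.spec.has_lfhf:
            s = self._slope(self.delta)
            rest = m.Z @ self._zcoef(self.delta) + self.b[m.pidx]
            num = num + s * self.tau_L * (m.L - rest)
            prec = prec + s * s * self.tau_L
        self.T = _samplers.draw_scalar_normal(num, np.broadcast_to(prec, (m.n,)), self.rng)
        self._W_cache = None

    def update_para(self) -> None:
        m = self.m
        prec = self.tau_P + float((self.alpha1**2) @ self.tau_y)
        struct = self._slope(self.gamma) * self.T + m.Z @ self._zcoef(self.gamma) + self.a[m.pidx]
        num = self.tau_P * struct + (m.Y - self.alpha0) @ (self.alpha1 * self.tau_y)
        self.P = _samplers.draw_scalar_normal(num, np.broadcast_to(prec, (m.n,)), self.rng)

    # ------------------------------------------------- measurement part
    def update_pollutant_loadings(self) -> None:
        m, n = self.m, self.m.n
        resid = m.X[:, 0] - self.T  # reference: loading fixed at 1
        prec0 = n * self.tau_x[0] + self.v0
        self.lam0[0] = float(
            _samplers.draw_scalar_normal(
                np.array(self.tau_x[0] * resid.sum()), np.array(prec0), self.rng
            )
        )
        W = np.column_stack([np.ones(n), self.T])
        for j in range(1, m.X.shape[1]):
            coef = _samplers.draw_linreg(W, m.X[:, j], self.tau_x[j], self.v0, self.rng)
            self.lam0[j], self.lam1[j] = coef

    def update_pollutant_precisions(self) -> None:
        resid = self.m.X - (self.lam0 + np.outer(self.T, self.lam1))
        for j in range(resid.shape[1]):
            self.tau_x[j] = _samplers.draw_precision(resid[:, j], self.a0, self.b0, self.rng)

    def update_marker_loadings(self) -> None:
        m, n = self.m, self.m.n
        resid = m.Y[:, 0] - self.P
        prec0 = n * self.tau_y[0] + self.v0
        self.alpha0[0] = float(
            _samplers.draw_scalar_normal(
                np.array(self.tau_y[0] * resid.sum()), np.array(prec0), self.rng
            )
        )
        W = np.column_stack([np.ones(n), self.P])
        for k in range(1, m.Y.shape[1]):
            coef = _samplers.draw_linreg(W, m.Y[:, k], self.tau_y[k], self.v0, self.rng)
            self.alpha0[k], self.alpha1[k] = coef

    def update_marker_precisions(self) -> None:
        resid = self.m.Y - (self.alpha0 + np.outer(self.P, self.alpha1))
        for k in range(resid.shape[1]):
            self.tau_y[k] = _samplers.draw_precision(resid[:, k], self.a0, self.b0, self.rng)

    def update_phi(self) -> None:
        self.phi = _samplers.draw_linreg(self.m.S, self.T, self.tau_T, self.v0, self.rng)

    def update_tau_traffic(self) -> None:
        resid = self.T - self.m.S @ self.phi
        self.tau_T = _samplers.draw_precision(resid, self.a0, self.b0, self.rng)

    # -------------------------------------------------- structural part
    def update_gamma(self) -> None:
        y = self.P - self.a[self.m.pidx]
        self.gamma = _samplers.draw_linreg(self._W(), y, self.tau_P, self.v0, self.rng)

    def update_a(self) -> None:
        m = self.m
        resid = self.P - self._W() @ self.gamma
        prec = self.tau_a + m.n_i * self.tau_P
        num = self.tau_P * np.bincount(m.pidx, weights=resid, minlength=m.n_participants)
        self.a = _samplers.draw_scalar_normal(num, prec, self.rng)

    def update_tau_a(self) -> None:
        self.tau_a = _samplers.draw_precision(self.a, self.a0, self.b0, self.rng)

    def update_tau_para(self) -> None:
        resid = self.P - self._W() @ self.gamma - self.a[self.m.pidx]
        self.tau_P = _samplers.draw_precision(resid, self.a0, self.b0, self.rng)

    def update_recenter_para(self) -> None:
        """Translation move over the level of the latent tone.

        The transformation ``P -> P + c, a -> a + c, alpha0 -> alpha0 -
        alpha1 * c`` leaves every likelihood term invariant, so the level of
        the latent tone is identified only through the priors on ``a`` and
        ``alpha0`` and mixes very slowly under one-at-a-time updates.  This
        generalised Gibbs (translation-group) step draws ``c`` from its exact
        conditional under those priors and applies the shift, which leaves
        the posterior invariant while decorrelating successive sweeps.
        """
        m = self.m
        prec = m.n_participants * self.tau_a + self.v0 * float(self.alpha1 @ self.alpha1)
        num = -self.tau_a * self.a.sum() + self.v0 * float(self.alpha1 @ self.alpha0)
        c = float(_samplers.draw_scalar_normal(np.array(num), np.array(prec), self.rng))
        self.P = self.P + c
        self.a = self.a + c
        self.alpha0 = self.alpha0 - self.alpha1 * c

    def update_delta(self) -> None:
        y = self.m.L - self.b[self.m.pidx]
        self.delta = _samplers.draw_linreg(self._W(), y, self.tau_L, self.v0, self.rng)

    def update_b(self) -> None:
        m = self.m
        resid = m.L - self._W() @ self.delta
        prec = self.tau_b + m.n_i * self.tau_L
        num = self.tau_L * np.bincount(m.pidx, weights=resid, minlength=m.n_participants)
        self.b = _samplers.draw_scalar_normal(num, prec, self.rng)

    def update_tau_b(self) -> None:
        self.tau_b = _samplers.draw_precision(self.b, self.a0, self.b0, self.rng)

    def update_tau_lfhf(self) -> None:
        resid = self.m.L - self._W() @ self.delta - self.b[self.m.pidx]
        self.tau_L = _samplers.draw_precision(resid, self.a0, self.b0, self.rng)

    # -------------------------------------------------------------- sweep
    def step(self) -> None:
        """One full Gibbs sweep over all unknowns."""
        collapse = self.spec.collapse_single_indicator
        if not collapse:
            self.update_traffic()
            if self.spec.has_para:
                self.update_para()
            self.update_pollutant_loadings()
            self.update_pollutant_precisions()
            self.update_phi()
            self.update_tau_traffic()
            if self.spec.has_para:
                self.update_marker_loadings()
                self.update_marker_precisions()
        if self.spec.has_para:
            self.update_gamma()
            self.update_a()
            self.update_tau_a()
            self.update_tau_para()
            if not collapse:
                self.update_recenter_para()
        if self.spec.has_lfhf:
            self.update_delta()
            self.update_b()
            self.update_tau_b()
            self.update_tau_lfhf()

    # ---------------------------------------------------------- recording
    def record_names(self) -> list[str]:
        m, spec = self.m, self.spec
        names = []
        if not spec.collapse_single_indicator:
            for j, p in enumerate(m.pollutant_names):
                names.append(f"lambda0[{p}]")
            for p in m.pollutant_names[1:]:
                names.append(f"lambda1[{p}]")
            for p in m.pollutant_names:
                names.append(f"tau_x[{p}]")
            names += [f"phi[{c}]" for c in SEASONAL_COLUMNS]
            names.append("tau_traffic")
            if spec.has_para:
                for k in m.marker_names:
                    names.append(f"alpha0[{k}]")
                for k in m.marker_names[1:]:
                    names.append(f"alpha1[{k}]")
                for k in m.marker_names:
                    names.append(f"tau_y[{k}]")
        if spec.has_para:
            names += [f"gamma[{c}]" for c in m.gamma_names()]
            names += ["tau_a", "tau_para"]
        if spec.has_lfhf:
            names += [f"delta[{c}]" for c in m.gamma_names()]
            names += ["tau_b", "tau_lfhf"]
        return names

    def record(self) -> np.ndarray:
        m, spec = self.m, self.spec
        vals = []
        if not spec.collapse_single_indicator:
            vals += list(self.lam0)
            vals += list(self.lam1[1:])
            vals += list(self.tau_x)
            vals += list(self.phi)
            vals.append(self.tau_T)
            if spec.has_para:
                vals += list(self.alpha0)
                vals += list(self.alpha1[1:])
                vals += list(self.tau_y)
        if spec.has_para:
            vals += list(self.gamma)
            vals += [self.tau_a, self.tau_P]
        if spec.has_lfhf:
            vals += list(self.delta)
            vals += [self.tau_b, self.tau_L]
        return np.asarray(vals)


@dataclass
class PosteriorDraws:
    """MCMC output: per-parameter draw arrays of shape (chains, kept)."""

    draws: dict
    diagnostics: pd.DataFrame | None = None
    latent_mean: pd.DataFrame | None = None
    latent_draws: dict | None = None
    info: dict = field(default_factory=dict)

    def names(self) -> list[str]:
        return list(self.draws)

    def get(self, name: str) -> np.ndarray:
        """Flattened (all chains pooled) draws of one scalar parameter."""
        return np.asarray(self.draws[name]).reshape(-1)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, arr in self.draws.items():
            flat = np.asarray(arr).reshape(-1)
            rows[name] = {
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": np.percentile(flat, 2.5),
                "q97.5": np.percentile(flat, 97.5),
            }
        out = pd.DataFrame(rows).T
        if self.diagnostics is not None:
            out = out.join(self.diagnostics, how="left")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.get(k) for k in self.draws})

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "draws.csv", index=False)
        if self.diagnostics is not None:
            self.diagnostics.to_csv(out / "diagnostics.csv")
        if self.latent_mean is not None:
            self.latent_mean.to_csv(out / "latent_means.csv", index=False)
        with open(out / "fit_info.json", "w") as fh:
            json.dump(self.info, fh, indent=2, default=str)


def _diagnostics(draws: dict) -> pd.DataFrame:
    import arviz as az

    data = {k: np.asarray(v) for k, v in draws.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(data)
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    return pd.DataFrame(
        {
            "rhat": {k: float(rhat[k].values) for k in data},
            "ess": {k: float(ess[k].values) for k in data},
        }
    )


def fit_sem(design: pd.DataFrame, visits: pd.DataFrame, spec: SEMSpec,
            compute_diagnostics: bool = True) -> PosteriorDraws:
    """Fit the SEM by Gibbs sampling and return posterior draws.

    Runs ``spec.mcmc.chains`` chains from over-dispersed initial values,
    discards burn-in, and attaches split-R-hat / effective-sample-size
    diagnostics for every recorded scalar. A warning is emitted when any
    R-hat exceeds 1.1.
    """
    model = build_sem(design, visits, spec)
    mc = spec.mcmc
    kept = mc.kept_per_chain
    root = np.random.SeedSequence(mc.seed)
    chains_store = None
    names = None
    latent_T = np.zeros(model.n)
    latent_P = np.zeros(model.n)
    latent_count = 0
    latent_draws = {"traffic": [], "para": []} if spec.store_latent_draws else None

    for c, ss in enumerate(root.spawn(mc.chains)):
        rng = np.random.default_rng(ss)
        sampler = GibbsSampler(model, rng, init_jitter=mc.init_jitter)
        if names is None:
            names = sampler.record_names()
            chains_store = np.empty((mc.chains, kept, len(names)))
        ch_T = [] if spec.store_latent_draws else None
        k = 0
        for it in range(mc.iterations):
            sampler.step()
            if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0 and k < kept:
                row = sampler.record()
                if not np.all(np.isfinite(row)):
                    bad = [n for n, v in zip(names, row) if not np.isfinite(v)]
                    raise NumericalStabilityError(
                        f"chain {c} diverged; non-finite blocks: {bad[:5]}"
                    )
                chains_store[c, k] = row
                latent_T += sampler.T
                if spec.has_para:
                    latent_P += sampler.P
                latent_count += 1
                if spec.store_latent_draws:
                    ch_T.append(sampler.T.copy())
                k += 1
        if spec.store_latent_draws:
            latent_draws["traffic"].append(np.asarray(ch_T))

    draws = {name: chains_store[:, :, i] for i, name in enumerate(names)}
    diag = _diagnostics(draws) if compute_diagnostics and mc.chains > 1 else None
    if diag is not None:
        bad = diag[diag["rhat"] > 1.1]
        if len(bad):
            warnings.warn(
                f"convergence warning: R-hat > 1.1 for {list(bad.index)[:8]}",
                stacklevel=2,
            )
    latent_mean = pd.DataFrame(
        {
            "visit_id": model.visit_ids,
            "traffic_mean": latent_T / max(latent_count, 1),
            **(
                {"para_mean": latent_P / max(latent_count, 1)}
                if spec.has_para
                else {}
            ),
        }
    )
    info = dict(model.info)
    info.update(
        {
            "outcome": spec.outcome,
            "chains": mc.chains,
            "iterations": mc.iterations,
            "burn_in": mc.burn_in,
            "modifier": spec.modifier,
        }
    )
    return PosteriorDraws(
        draws=draws,
        diagnostics=diag,
        latent_mean=latent_mean,
        latent_draws=latent_draws,
        info=info,
    )


def fit_effect_modification(design: pd.DataFrame, visits: pd.DataFrame,
                            spec: SEMSpec) -> PosteriorDraws:
    """Fit with a dichotomous effect modifier and add group-specific slopes.

    The modifier-positive traffic effect is ``gamma1 + gamma_int`` and the
    modifier-negative effect is ``gamma1`` (likewise for ``delta``); both are
    attached as derived draw arrays.
    """
    if spec.modifier is None:
        raise ConfigurationError("fit_effect_modification requires spec.modifier")
    if spec.modifier not in visits.columns:
        raise ValueError(f"modifier column {spec.modifier!r} not in visit table")
    mvals = visits[spec.modifier].dropna().unique()
    if not set(np.asarray(mvals).astype(float)) <= {0.0, 1.0}:
        raise ValueError(f"modifier {spec.modifier!r} must be coded 0/1")
    if len(mvals) < 2:
        raise ValueError(f"modifier {spec.modifier!r} is constant in the sample")
    n_pos = int((visits[spec.modifier] == 1).sum())
    n_neg = int((visits[spec.modifier] == 0).sum())
    if min(n_pos, n_neg) < 5:
        warnings.warn(
            f"modifier subgroup has only {min(n_pos, n_neg)} visits; expect "
            "wide posterior intervals",
            stacklevel=2,
        )
    result = fit_sem(design, visits, spec)
    for block in ("gamma", "delta"):
        base = f"{block}[traffic]"
        inter = f"{block}[traffic_x_mod]"
        if base in result.draws and inter in result.draws:
            result.draws[f"{block}[traffic|mod=1]"] = (
                result.draws[base] + result.draws[inter]
            )
            result.draws[f"{block}[traffic|mod=0]"] = result.draws[base].copy()
    result.info["modifier_group_sizes"] = {"mod=1": n_pos, "mod=0": n_neg}
    return result
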