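"""Conjugate draw primitives shared by the SEM and BLMM Gibbs samplers."""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular


class NumericalStabilityError(RuntimeError):
    """Raised when a full conditional becomes numerically degenerate."""


def draw_linreg(W: np.ndarray, y: np.ndarray, noise_prec: float,
                prior_prec: float, rng: np.random.Generator,
                WtW: np.ndarray | None = None) -> np.ndarray:
    """Draw the coefficient block of a Gaussian linear regression.

    Full conditional is N(A^-1 tau W'y, A^-1) with A = tau W'W + v0 I.
    ``WtW`` may be supplied to reuse a precomputed cross-product.
    """
    q = W.shape[1]
    A = noise_prec * (WtW if WtW is not None else W.T @ W)
    A[np.diag_indices(q)] += prior_prec
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise NumericalStabilityError(f"non-PD conditional precision: {exc}") from exc
    b = noise_prec * (W.T @ y)
    tmp = solve_triangular(L, b, lower=True, check_finite=False)
    mean = solve_triangular(L, tmp, lower=True, trans="T", check_finite=False)
    z = rng.standard_normal(q)
    return mean + solve_triangular(L, z, lower=True, trans="T", check_finite=False)


def linreg_posterior(W: np.ndarray, y: np.ndarray, noise_prec: float,
                     prior_prec: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form mean and covariance of the same conditional (no draw)."""
    q = W.shape[1]
    A = noise_prec * (W.T @ W)
    A[np.diag_indices(q)] += prior_prec
    cov = np.linalg.inv(A)
    return cov @ (noise_prec * (W.T @ y)), cov


def draw_precision(resid: np.ndarray, shape0: float, rate0: float,
                   rng: np.random.Generator) -> float:
    """Draw a precision from its Gamma full conditional given residuals."""
    n = resid.size
    rate = rate0 + 0.5 * float(resid @ resid)
    return float(rng.gamma(shape0 + 0.5 * n, 1.0 / rate))


def draw_scalar_normal(num: np.ndarray, prec: np.ndarray,
                       rng: np.random.Generator, floor: float = 1e-12) -> np.ndarray:
    """Vectorised N(num/prec, 1/prec) draws with a floored precision."""
    prec = np.maximum(prec, floor)
    sd = 1.0 / np.sqrt(prec)
    return num / prec + rng.standard_normal(np.shape(num)) * sd
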