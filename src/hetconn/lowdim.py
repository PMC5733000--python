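"""Low-dimensional (rank-one) Bayesian covariance regression.

Each observed vector is modeled as

    y_i = gamma_i * B x_i + eps_i,
    gamma_i ~ Normal(0, 1),   eps_i ~ Normal(0, diag(sigma^2)),

so the implied covariance at design row x is

    Sigma_x = (B x)(B x)^T + diag(sigma^2).

The latent scalars gamma_i are integrated out analytically: y_i is then
mean-zero multivariate normal with a rank-one-plus-diagonal covariance, and
the Sherman-Morrison / matrix-determinant identities reduce every density
evaluation to O(p) per observation.  Because the likelihood depends on the
data only through per-group second moments, the stacked observations are
compressed to sufficient statistics before sampling, making the cost of an
MCMC step independent of the number of time points.

``B`` and ``-B`` produce the same covariance function (and, with a 0/1
contrast design, the identified directions ``B x_g`` carry an independent
sign each), so chains are started from a canonically signed moment estimate
and :func:`align_signs` resolves any residual sign disagreement between
chains before summarization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._mcmc import SamplerConfig, run_chains, split_rhat
from .data_io import DesignMatrix

__all__ = [
    "LowDimParams",
    "LowDimPosterior",
    "expected_covariance",
    "marginal_loglik",
    "fit_lowdim",
    "align_signs",
    "summarize_coefficients",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LowDimParams:
    """Coefficient matrix ``B`` (p x J) and per-parcel noise scales sigma."""

    B: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if B.shape[0] != sigma.shape[0]:
            raise ValueError("B rows and sigma length must both equal p")
        if np.any(sigma <= 0):
            raise ValueError("all noise scales must be positive")
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class LowDimPosterior:
    """MCMC draws of the rank-one covariance regression.

    ``B`` has shape (chains, draws, p, J) and ``sigma`` (chains, draws, p).
    ``aligned`` records whether cross-chain sign alignment has been applied;
    summaries refuse to run on unaligned posteriors.
    """

    B: np.ndarray
    sigma: np.ndarray
    column_names: tuple[str, ...]
    parcel_labels: tuple[str, ...]
    seed: int
    aligned: bool
    diagnostics: dict

    @property
    def n_chains(self) -> int:
        return self.B.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.B.shape[2]


def expected_covariance(params: LowDimParams, x: Sequence[float]) -> np.ndarray:
    """Model-implied covariance ``(Bx)(Bx)^T + diag(sigma^2)`` at design row x."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.B.shape[1],):
        raise ValueError(
            f"design row of length {x.size} does not match J = {params.B.shape[1]}"
        )
    v = params.B @ x
    return np.outer(v, v) + np.diag(params.sigma**2)


def _group_sufficient_stats(
    X: np.ndarray, Y: np.ndarray
) -> list[tuple[np.ndarray, int, np.ndarray, np.ndarray]]:
    """Per distinct design row: (x, count, column sums of squares, scatter)."""
    rows, inverse = np.unique(X, axis=0, return_inverse=True)
    stats = []
    for g in range(rows.shape[0]):
        Yg = Y[inverse == g]
        stats.append((rows[g], Yg.shape[0], np.sum(Yg**2, axis=0), Yg.T @ Yg))
    return stats


def _loglik_from_stats(
    B: np.ndarray, log_sigma: np.ndarray, stats, p: int
) -> np.ndarray:
    """Marginal log likelihood for a batch of parameters.

    ``B``: (W, p, J); ``log_sigma``: (W, p); returns (W,).  Uses the
    determinant lemma and Sherman-Morrison on the rank-one update, with the
    data entering only through the per-group sufficient statistics.
    """
    s2 = np.exp(2.0 * log_sigma)  # (W, p)
    total = np.zeros(B.shape[0])
    for x, n_g, ss_g, S_g in stats:
        v = B @ x  # (W, p)
        c = 1.0 + np.sum(v**2 / s2, axis=1)  # (W,)
        logdet = 2.0 * np.sum(log_sigma, axis=1) + np.log(c)
        w = v / s2
        quad = np.sum(ss_g / s2, axis=1) - np.einsum("wi,ij,wj->w", w, S_g, w) / c
        total += -0.5 * (n_g * (p * _LOG_2PI + logdet) + quad)
    return total


def marginal_loglik(
    params: LowDimParams, X: DesignMatrix | np.ndarray, Y: np.ndarray
) -> float:
    """Sum of mean-zero normal log densities with covariance Sigma_{x_i}.

    Equivalent to (but much faster than) evaluating a dense multivariate
    normal density per observation.
    """
    Xv = X.values if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Xv.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in input")
    p = Y.shape[1]
    stats = _group_sufficient_stats(Xv, Y)
    value = _loglik_from_stats(
        params.B[None], np.log(params.sigma)[None], stats, p
    )[0]
    return float(value)


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its largest-magnitude entry is positive (ties keep +)."""
    pivot = v[np.argmax(np.abs(v))]
    return -v if pivot < 0 else v


def _moment_init(stats, p: int, J: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonically signed rank-one moment estimate of (B, sigma)."""
    xs, vs, resid = [], [], []
    for x, n_g, ss_g, S_g in stats:
        C = S_g / max(n_g, 1)
        eigval, eigvec = np.linalg.eigh(C)
        lead = max(eigval[-1] - np.median(eigval[:-1]) if p > 1 else eigval[-1], 1e-6)
        v = _canonical_sign(eigvec[:, -1] * np.sqrt(lead))
        xs.append(x)
        vs.append(v)
        resid.append(np.clip(np.diag(C) - v**2, 1e-4 * np.mean(np.diag(C)) + 1e-12, None))
    Xu = np.asarray(xs)
    V = np.asarray(vs)
    B0, *_ = np.linalg.lstsq(Xu, V, rcond=None)  # (J, p)
    sigma0 = np.sqrt(np.mean(resid, axis=0))
    return B0.T, sigma0


def fit_lowdim(
    Y: np.ndarray,
    X: DesignMatrix,
    config: SamplerConfig,
) -> LowDimPosterior:
    """Sample the posterior of (B, sigma) from stacked thinned observations.

    ``Y`` holds one centered p-vector per design row of ``X``.  Flat
    (improper) priors are the default: uniform on B entries and on
    sigma_j > 0; ``config.prior == 'weak'`` switches to Normal(0, 10^2) on B
    and lognormal(0, 2) on sigma for stress cases.  Split-R-hat diagnostics
    (computed on sign-aligned draws) are stored in ``diagnostics``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    if p < 1 or n < 2:
        raise ValueError("need at least 2 observations of at least 1 parcel")
    if X.values.shape[0] != n:
        raise ValueError("number of design rows must equal number of observations")
    J = X.n_columns
    stats = _group_sufficient_stats(X.values, Y)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        B = theta[:, : p * J].reshape(-1, p, J)
        log_sigma = theta[:, p * J :]
        ll = _loglik_from_stats(B, log_sigma, stats, p)
        if config.prior == "flat":
            lp = np.sum(log_sigma, axis=1)  # Jacobian of sigma = exp(u)
        else:
            lp = -0.5 * np.sum(B**2, axis=(1, 2)) / 100.0
            lp -= 0.5 * np.sum(log_sigma**2, axis=1) / 4.0
        return ll + lp

    B0, sigma0 = _moment_init(stats, p, J)
    center = np.concatenate([B0.ravel(), np.log(sigma0)])
    scale = 0.05 * (np.abs(center) + 0.1)
    draws, info = run_chains(log_prob, center, scale, config)
    B_draws = draws[:, :, : p * J].reshape(
        config.chains, config.iterations, p, J
    )
    sigma_draws = np.exp(draws[:, :, p * J :])

    aligned_B = _column_aligned(B_draws, reference=0)
    rhat = np.concatenate(
        [split_rhat(aligned_B).ravel(), split_rhat(sigma_draws).ravel()]
    )
    diagnostics = dict(info)
    diagnostics["rhat"] = rhat
    diagnostics["rhat_max"] = float(np.nanmax(rhat)) if rhat.size else float("nan")
    labels = tuple(f"R{j + 1}" for j in range(p))
    return LowDimPosterior(
        B=B_draws,
        sigma=sigma_draws,
        column_names=tuple(X.column_names),
        parcel_labels=labels,
        seed=config.seed,
        aligned=False,
        diagnostics=diagnostics,
    )


def _column_aligned(B_draws: np.ndarray, reference: int) -> np.ndarray:
    """Per-chain, per-column sign flips toward the reference chain's mean."""
    ref_mean = B_draws[reference].mean(axis=0)  # (p, J)
    out = B_draws.copy()
    for c in range(B_draws.shape[0]):
        chain_mean = B_draws[c].mean(axis=0)
        inner = np.sum(chain_mean * ref_mean, axis=0)  # (J,)
        signs = np.where(inner < 0, -1.0, 1.0)  # ties -> +1
        out[c] = out[c] * signs[None, None, :]
    return out


def align_signs(posterior: LowDimPosterior, reference: int = 0) -> LowDimPosterior:
    """Resolve the sign non-identifiability of B across chains.

    For each chain and each design column, the column is flipped when the
    inner product of its chain-mean with the reference chain-mean is
    negative (the Frobenius-optimal per-column sign); sigma draws and all
    likelihood values are untouched.  Idempotent.
    """
    if not 0 <= reference < posterior.n_chains:
        raise ValueError("reference chain index out of range")
    return replace(
        posterior,
        B=_column_aligned(posterior.B, reference),
        aligned=True,
    )


def summarize_coefficients(
    posterior: LowDimPosterior,
    column: int = 1,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected credible intervals and parcel-set classification.

    Endpoints are the ``alpha/m`` and ``1 - alpha/m`` posterior quantiles
    (``m`` defaults to the number of parcels).  A parcel whose interval lies
    entirely below zero goes to ``set1``, entirely above to ``set2``, and
    an interval containing zero leaves the parcel ``undecided``.  Only the
    side structure is meaningful: parcels on the same side are positively
    correlated in the contrast, across sides negatively.
    """
    if not posterior.aligned:
        raise ValueError("posterior must be sign-aligned before summarization")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = posterior.n_parcels
    m = m if m is not None else p
    if m < 1:
        raise ValueError("Bonferroni divisor m must be >= 1")
    draws = posterior.B[:, :, :, column].reshape(-1, p)
    lo_q, hi_q = alpha / m, 1.0 - alpha / m
    lower = np.quantile(draws, lo_q, axis=0)
    upper = np.quantile(draws, hi_q, axis=0)
    median = np.median(draws, axis=0)
    assignment = np.where(
        upper < 0.0, "set1", np.where(lower > 0.0, "set2", "undecided")
    )
    return pd.DataFrame(
        {
            "parcel": list(posterior.parcel_labels),
            "median": median,
            "lower": lower,
            "upper": upper,
            "set": assignment,
        }
    )
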