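"""Full covariance regression of subject scatter matrices.

Each subject contributes a scatter matrix ``S_k = Y_k^T Y_k`` of its
centered timeseries, modeled as

    S_k ~ Wishart(x_k^(1) Sigma^(1) + x_k^(2) Sigma^(2), nu)

in the scale parameterization (``E[S] = nu * Sigma``): if the rows of Y were
iid normal the degrees of freedom would equal the number of time points N,
and temporal dependence shows up as a posterior for ``nu`` concentrated
below N.  Each covariance term is decomposed into scales and a correlation
matrix, ``Sigma^(m) = diag(sigma^(m)) Omega^(m) diag(sigma^(m))``, with
LKJ(eta) priors on the correlation matrices (eta = 1 by default: uniform
over valid correlation matrices), flat priors on the scale vectors, and a
uniform prior for ``nu`` on ``(p - 1, N - 1)``.

``Omega^(2)`` is the group difference in correlation; for every parcel pair
the posterior sign evidence

    P_ij = | 2 * Prob(Omega^(2)_ij > 0) - 1 |

is thresholded at a level chosen by grid search to control the posterior
expected false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from ._mcmc import SamplerConfig, run_chains, split_rhat
from .data_io import DesignMatrix, ScatterMatrix
from .lkj import corr_from_partials, lkj_cpc_logprior, partials_from_corr, tri_index

__all__ = [
    "FullCovPosterior",
    "DifferentialReport",
    "fit_fullcov",
    "differential_probability",
    "posterior_fdr",
    "fdr_threshold",
    "pair_count",
    "wishart_logpdf_terms",
]

_DEFAULT_GRID_STEP = 0.001


@dataclass(frozen=True)
class FullCovPosterior:
    """Posterior draws of the Wishart covariance regression.

    Arrays are laid out (chains, draws, ...).  ``sigma2``/``omega2`` are
    ``None`` when the design is intercept-only (single group).
    """

    sigma1: np.ndarray
    omega1: np.ndarray
    sigma2: np.ndarray | None
    omega2: np.ndarray | None
    nu: np.ndarray
    eta: float
    nu_bounds: tuple[float, float]
    parcel_labels: tuple[str, ...]
    seed: int
    diagnostics: dict

    def sigma_matrix(self, term: int = 1) -> np.ndarray:
        """Reconstructed Sigma^(term) draws, diag(sigma) Omega diag(sigma)."""
        sigma = self.sigma1 if term == 1 else self.sigma2
        omega = self.omega1 if term == 1 else self.omega2
        if sigma is None:
            raise ValueError(f"term {term} not present in this fit")
        return omega * sigma[..., :, None] * sigma[..., None, :]


@dataclass(frozen=True)
class DifferentialReport:
    """FDR-thresholded differential-connectivity selection.

    ``selected_pairs`` holds 0-based parcel index pairs (i, j), i < j, with
    ``P[i, j] > lambda_star``; ``fdr_achieved`` is NaN when nothing is
    selected.
    """

    P: np.ndarray
    lambda_star: float
    fdr_achieved: float
    selected_pairs: tuple[tuple[int, int], ...]
    target_fdr: float


def pair_count(p: int) -> int:
    """Number of distinct parcel pairs, p(p-1)/2."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return p * (p - 1) // 2


def _multigammaln(a: np.ndarray, p: int) -> np.ndarray:
    """Vectorized log multivariate gamma."""
    a = np.asarray(a, dtype=float)[..., None]
    j = np.arange(1, p + 1)
    return p * (p - 1) / 4.0 * np.log(np.pi) + np.sum(
        special.gammaln(a + (1.0 - j) / 2.0), axis=-1
    )


def wishart_logpdf_terms(
    nu: np.ndarray, V: np.ndarray, k: int, sum_logdet_s: float, s_sum: np.ndarray, p: int
) -> np.ndarray:
    """Summed Wishart log density of ``k`` scatters against scale ``V``.

    ``nu``: (W,) degrees of freedom; ``V``: (W, p, p) scale matrices;
    ``sum_logdet_s`` and ``s_sum`` are the data sufficient statistics
    ``sum_k log|S_k|`` and ``sum_k S_k``.  Returns (W,), ``-inf`` where V is
    not positive definite.
    """
    sign, logdet_v = np.linalg.slogdet(V)
    ok = sign > 0
    logdet_v = np.where(ok, logdet_v, 0.0)
    safe_v = np.where(ok[:, None, None], V, np.eye(p))
    trace = np.einsum("wii->w", np.linalg.solve(safe_v, np.broadcast_to(s_sum, V.shape)))
    out = (
        0.5 * (nu - p - 1.0) * sum_logdet_s
        - 0.5 * trace
        - k * (0.5 * nu * p * np.log(2.0) + 0.5 * nu * logdet_v + _multigammaln(nu / 2.0, p))
    )
    return np.where(ok, out, -np.inf)


def _validate_design(X: DesignMatrix, n_subjects: int) -> np.ndarray:
    Xv = X.values
    if Xv.shape[0] != n_subjects:
        raise ValueError("one design row per scatter matrix is required")
    if Xv.shape[1] not in (1, 2):
        raise ValueError("the Wishart model supports J = 1 or J = 2 designs")
    if Xv.shape[1] == 2:
        contrast = Xv[:, 1]
        if not np.all(np.isin(contrast, (0.0, 1.0))):
            raise ValueError(
                "the contrast column must be 0/1: negative weights could make "
                "the Wishart scale indefinite"
            )
        if not np.any(contrast == 1.0):
            raise ValueError(
                "no subject in the contrast group; refit with an intercept-only design"
            )
    return Xv


def fit_fullcov(
    scatters: Sequence[ScatterMatrix],
    X: DesignMatrix,
    config: SamplerConfig,
    eta: float = 1.0,
    common_n: int | None = None,
) -> FullCovPosterior:
    """Sample the posterior of (sigma, Omega, nu) given subject scatters.

    The prior upper bound for ``nu`` uses the minimum subject N (or
    ``common_n`` when supplied), which is conservative when subjects have
    unequal run lengths.  MCMC runs on unconstrained parameters: log scales,
    tanh-transformed canonical partial correlations (whose pushforward prior
    is exactly LKJ(eta)), and a logit-interval transform of nu.
    """
    if len(scatters) == 0:
        raise ValueError("at least one scatter matrix is required")
    p = scatters[0].n_parcels
    if any(s.n_parcels != p for s in scatters):
        raise ValueError("all scatter matrices must share the same dimension")
    Xv = _validate_design(X, len(scatters))
    two_term = Xv.shape[1] == 2
    n_common = common_n if common_n is not None else min(s.n_timepoints for s in scatters)
    lo, hi = p - 1.0, n_common - 1.0
    if hi <= lo:
        raise ValueError(f"need N > p for the nu prior, got N = {n_common}, p = {p}")

    group = Xv[:, 1].astype(int) if two_term else np.zeros(len(scatters), dtype=int)
    stats = []
    diag_stacks = {}
    for g in sorted(set(group)):
        members = [s.values for s, gg in zip(scatters, group) if gg == g]
        logdets = []
        for s in members:
            sign, ld = np.linalg.slogdet(s)
            if sign <= 0:
                raise ValueError(
                    "singular scatter matrix: the Wishart density needs S positive "
                    "definite (N >= p time points per subject)"
                )
            logdets.append(ld)
        stats.append((g, len(members), float(np.sum(logdets)), np.sum(members, axis=0)))
        diag_stacks[g] = np.array([np.diag(s) for s in members])

    q = pair_count(p)
    n_sigma = 2 * p if two_term else p
    n_corr = 2 * q if two_term else q
    ndim = n_sigma + n_corr + 1

    def unpack(theta: np.ndarray):
        theta = np.atleast_2d(theta)
        u1 = theta[:, :p]
        y1 = theta[:, n_sigma : n_sigma + q]
        if two_term:
            u2 = theta[:, p : 2 * p]
            y2 = theta[:, n_sigma + q : n_sigma + 2 * q]
        else:
            u2 = y2 = None
        t = theta[:, -1]
        return u1, u2, y1, y2, t

    def scaled_sigma_from(u: np.ndarray, y: np.ndarray) -> np.ndarray:
        # u parameterizes the scales of Sigma* = nu * Sigma: the likelihood
        # pins Sigma* tightly, so sampling (Sigma*, nu) removes the stiff
        # nu-sigma ridge of the naive parameterization
        sig = np.exp(u)
        omega = corr_from_partials(np.tanh(y))
        return omega * sig[:, :, None] * sig[:, None, :]

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        u1, u2, y1, y2, t = unpack(theta)
        nu = lo + (hi - lo) * special.expit(t)
        star1 = scaled_sigma_from(u1, y1)
        star2 = scaled_sigma_from(u2, y2) if two_term else None
        inv_nu = 1.0 / nu[:, None, None]
        ll = np.zeros(theta.shape[0])
        for g, k_g, sum_ld, s_sum in stats:
            V = star1 * inv_nu if g == 0 else (star1 + star2) * inv_nu
            ll = ll + wishart_logpdf_terms(nu, V, k_g, sum_ld, s_sum, p)
        # flat prior on each sigma_j of Sigma = Sigma*/nu, written in terms of
        # u = log(sigma* scale): d sigma/d u = sigma and sigma = e^u / sqrt(nu)
        lp = np.sum(u1, axis=1) + lkj_cpc_logprior(y1, p, eta)
        if two_term:
            lp += np.sum(u2, axis=1) + lkj_cpc_logprior(y2, p, eta)
        lp -= 0.5 * n_sigma * np.log(nu)
        # flat prior on nu over (lo, hi), Jacobian of the logit-interval map
        lp += np.log(hi - lo) + special.log_expit(t) + special.log_expit(-t)
        return ll + lp

    center, scale = _moment_init(stats, diag_stacks, p, two_term, lo, hi)
    draws, info = run_chains(log_prob, center, scale, config)
    flat = draws.reshape(-1, ndim)
    u1, u2, y1, y2, t = unpack(flat)
    shape2 = (config.chains, config.iterations)
    nu_flat = lo + (hi - lo) * special.expit(t)
    nu = nu_flat.reshape(*shape2)
    sigma1 = (np.exp(u1) / np.sqrt(nu_flat)[:, None]).reshape(*shape2, p)
    omega1 = corr_from_partials(np.tanh(y1)).reshape(*shape2, p, p)
    sigma2 = (
        (np.exp(u2) / np.sqrt(nu_flat)[:, None]).reshape(*shape2, p)
        if two_term
        else None
    )
    omega2 = corr_from_partials(np.tanh(y2)).reshape(*shape2, p, p) if two_term else None

    diagnostics = dict(info)
    rhat = np.concatenate([split_rhat(sigma1).ravel(), split_rhat(nu)[None]])
    diagnostics["rhat"] = rhat
    diagnostics["rhat_max"] = float(np.nanmax(rhat))
    return FullCovPosterior(
        sigma1=sigma1,
        omega1=omega1,
        sigma2=sigma2,
        omega2=omega2,
        nu=nu,
        eta=eta,
        nu_bounds=(lo, hi),
        parcel_labels=tuple(f"R{j + 1}" for j in range(p)),
        seed=config.seed,
        diagnostics=diagnostics,
    )


def _moment_init(stats, diag_stacks, p, two_term, lo, hi):
    """Moment-based starting point in the unconstrained parameterization.

    The mean scatter estimates Sigma* = nu * Sigma directly; nu is started
    at the Wishart moment estimator 2 E[S_ii]^2 / Var(S_ii) (averaged over
    parcels) when at least two reference-group subjects are available.
    """
    star0 = next(s_sum / k for g, k, _, s_sum in stats if g == 0)
    sigma0 = np.sqrt(np.clip(np.diag(star0), 1e-8, None))
    corr0 = star0 / np.outer(sigma0, sigma0)
    y0 = np.arctanh(np.clip(partials_from_corr(_nearest_corr(corr0)), -0.9, 0.9))
    parts = [np.log(sigma0)]

    diags = diag_stacks.get(0)
    if diags is not None and diags.shape[0] >= 2:
        variances = diags.var(axis=0, ddof=1)
        means = diags.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            nu_hat = float(np.nanmedian(2.0 * means**2 / variances))
    else:
        nu_hat = 0.5 * (lo + hi)
    nu_hat = float(np.clip(nu_hat, lo + 0.02 * (hi - lo), hi - 0.02 * (hi - lo)))
    t0 = float(special.logit((nu_hat - lo) / (hi - lo)))

    if two_term:
        entries = [s_sum / k for g, k, _, s_sum in stats if g == 1]
        diff = entries[0] - star0
        diff = _nearest_pd(diff, 1e-3 * float(np.mean(np.diag(star0))))
        sig2 = np.sqrt(np.clip(np.diag(diff), 1e-8, None))
        corr2 = diff / np.outer(sig2, sig2)
        y2 = np.arctanh(np.clip(partials_from_corr(_nearest_corr(corr2)), -0.9, 0.9))
        parts += [np.log(sig2)]
        corr_parts = [y0, y2]
    else:
        corr_parts = [y0]
    center = np.concatenate(parts + corr_parts + [[t0]])
    scale = np.full(center.size, 0.05)
    return center, scale


def _nearest_pd(a: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (a + a.T))
    return (vecs * np.clip(vals, floor, None)) @ vecs.T


def _nearest_corr(r: np.ndarray) -> np.ndarray:
    r = _nearest_pd(r, 1e-4)
    d = 1.0 / np.sqrt(np.diag(r))
    out = r * np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def differential_probability(omega2_draws: np.ndarray) -> np.ndarray:
    """Posterior sign evidence ``P_ij = |2 Prob(Omega_ij > 0) - 1|``.

    Accepts draws of shape (..., p, p); leading axes are pooled.  The
    probability is the fraction of draws strictly greater than zero (draws
    exactly zero count as not positive).  The diagonal is set to zero and
    ignored everywhere downstream.
    """
    draws = np.asarray(omega2_draws, dtype=float)
    if draws.ndim < 3:
        draws = draws[None]
    p = draws.shape[-1]
    flat = draws.reshape(-1, p, p)
    prob = np.mean(flat > 0.0, axis=0)
    P = np.abs(2.0 * prob - 1.0)
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 0.0)
    return P


def posterior_fdr(P: np.ndarray, lam: float) -> float | None:
    """Posterior expected FDR of the selection ``{(i, j): P_ij > lam}``.

    Returns ``None`` when no pair exceeds the threshold (the quantity is
    undefined for an empty selection).
    """
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must lie in [0, 1)")
    rows, cols = tri_index(P.shape[0])
    vals = np.asarray(P, dtype=float)[rows, cols]
    selected = vals > lam
    if not np.any(selected):
        return None
    return float(np.mean(1.0 - vals[selected]))


def fdr_threshold(
    P: np.ndarray,
    target_fdr: float,
    grid_step: float = _DEFAULT_GRID_STEP,
) -> DifferentialReport:
    """Grid-search the smallest threshold controlling the posterior FDR.

    Scans ``lambda = 0, grid_step, ..., < 1`` and returns the smallest value
    whose nonempty selection has posterior expected FDR at or below
    ``target_fdr`` (smallest lambda = largest surviving selection).  If no
    grid point qualifies the report is empty with ``lambda_star = 1``.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must lie in (0, 1)")
    P = np.asarray(P, dtype=float)
    for lam in np.arange(0.0, 1.0, grid_step):
        fdr = posterior_fdr(P, lam)
        if fdr is not None and fdr <= target_fdr:
            rows, cols = tri_index(P.shape[0])
            mask = P[rows, cols] > lam
            pairs = tuple(
                (int(i), int(j)) for i, j in zip(rows[mask], cols[mask])
            )
            return DifferentialReport(
                P=P,
                lambda_star=float(lam),
                fdr_achieved=float(fdr),
                selected_pairs=pairs,
                target_fdr=target_fdr,
            )
    return DifferentialReport(
        P=P,
        lambda_star=1.0,
        fdr_achieved=float("nan"),
        selected_pairs=(),
        target_fdr=target_fdr,
    )
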