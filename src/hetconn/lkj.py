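"""LKJ distribution over correlation matrices via the C-vine construction.

The LKJ(eta) distribution has density proportional to det(Omega)^(eta-1)
over the set of valid correlation matrices; eta = 1 is uniform.  Sampling
and reparameterization both go through canonical partial correlations
(CPCs): in a C-vine with tree levels k = 1..p-1, the level-k partial
correlations are independent with

    z ~ 2 * Beta(a_k, a_k) - 1,   a_k = eta + (p - 1 - k) / 2,

and the induced distribution of the assembled correlation matrix is exactly
LKJ(eta).  For p = 2 and eta = 1 this reduces to a Uniform(-1, 1)
off-diagonal.  MCMC works on unconstrained y with z = tanh(y); the target
then needs only the independent Beta log densities plus the tanh Jacobian,
never a correlation-matrix Jacobian.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "tri_index",
    "level_shapes",
    "corr_from_partials",
    "partials_from_corr",
    "sample_lkj",
    "lkj_cpc_logprior",
]


def tri_index(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, row-major."""
    return np.triu_indices(p, k=1)


def level_shapes(p: int, eta: float) -> np.ndarray:
    """Beta shape a_k for each upper-triangle entry (k = row index + 1)."""
    rows, _ = tri_index(p)
    return eta + (p - 1 - (rows + 1)) / 2.0


def corr_from_partials(z: np.ndarray) -> np.ndarray:
    """Assemble correlation matrices from C-vine partial correlations.

    ``z`` has shape ``(..., q)`` with ``q = p(p-1)/2`` strict-upper-triangle
    entries in row-major order; entry ``(k, i)`` is the partial correlation
    of variables ``k`` and ``i`` given variables ``0..k-1``.  Returns
    ``(..., p, p)`` correlation matrices (symmetric, unit diagonal, PD for
    ``|z| < 1``).
    """
    z = np.asarray(z, dtype=float)
    q = z.shape[-1]
    p = int(round((1 + np.sqrt(1 + 8 * q)) / 2))
    if p * (p - 1) // 2 != q:
        raise ValueError(f"last axis of length {q} is not p(p-1)/2")
    rows, cols = tri_index(p)
    part = np.zeros(z.shape[:-1] + (p, p))
    part[..., rows, cols] = z
    corr = np.zeros_like(part)
    idx = np.arange(p)
    corr[..., idx, idx] = 1.0
    for i in range(p):
        for j in range(i + 1, p):
            r = part[..., i, j]
            for k in range(i - 1, -1, -1):
                r = r * np.sqrt(
                    (1.0 - part[..., k, i] ** 2) * (1.0 - part[..., k, j] ** 2)
                ) + part[..., k, i] * part[..., k, j]
            corr[..., i, j] = r
            corr[..., j, i] = r
    return corr


def partials_from_corr(corr: np.ndarray) -> np.ndarray:
    """Invert :func:`corr_from_partials` for one correlation matrix.

    Used to initialize samplers near a moment estimate.  Entry ``(k, i)`` is
    the partial correlation of ``k`` and ``i`` given ``0..k-1``, computed by
    the standard one-variable-at-a-time recursion.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    # partial[c][i, j]: correlation of i and j given variables 0..c-1
    current = corr.copy()
    out = np.zeros((p, p))
    out[0, 1:] = corr[0, 1:]
    for c in range(1, p - 1):
        nxt = current.copy()
        for i in range(c, p):
            for j in range(c, p):
                if i == j:
                    continue
                denom = np.sqrt(
                    (1.0 - current[c - 1, i] ** 2) * (1.0 - current[c - 1, j] ** 2)
                )
                nxt[i, j] = (current[i, j] - current[c - 1, i] * current[c - 1, j]) / denom
        current = nxt
        out[c, c + 1 :] = current[c, c + 1 :]
    rows, cols = tri_index(p)
    return out[rows, cols]


def sample_lkj(
    p: int, eta: float, n_draws: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n_draws`` correlation matrices from LKJ(eta), shape (n, p, p)."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    if p < 2:
        raise ValueError("p must be at least 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shapes = level_shapes(p, eta)
    z = 2.0 * rng.beta(shapes, shapes, size=(n_draws, shapes.size)) - 1.0
    return corr_from_partials(z)


def lkj_cpc_logprior(y: np.ndarray, p: int, eta: float) -> np.ndarray:
    """Log prior of unconstrained CPCs ``y`` inducing LKJ(eta) on Omega.

    ``y`` has shape ``(..., q)``; the return collapses the last axis.  The
    density is the product of scaled-Beta densities of ``z = tanh(y)`` times
    the Jacobian ``dz/dy = 1 - z^2``.
    """
    y = np.asarray(y, dtype=float)
    a = level_shapes(p, eta)
    z = np.tanh(y)
    # scaled Beta(a, a) on (-1, 1): log f(z) = (a-1) log((1-z^2)/4) - log B(a,a) - log 2
    log_beta = special.betaln(a, a)
    log1mz2 = 2.0 * (np.log(2.0) + y - np.logaddexp(0.0, 2.0 * y))  # log(1 - tanh^2)
    logf = (a - 1.0) * (log1mz2 - np.log(4.0)) - log_beta - np.log(2.0)
    return np.sum(logf + log1mz2, axis=-1)
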