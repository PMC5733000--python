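"""Thin multi-chain wrapper around the affine-invariant ensemble sampler.

Both regression models expose their posteriors through unconstrained
parameter vectors with vectorized log densities; this module runs a
requested number of independent ensembles ("chains"), each seeded from a
single user seed, and condenses every chain's post-burn-in walker cloud to
a fixed number of draws so downstream code sees the conventional
``(chain, draw, ...)`` layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import emcee
import numpy as np

__all__ = ["SamplerConfig", "run_chains", "split_rhat"]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings shared by both models.

    Defaults are 4 chains of 500 adaptation/burn-in steps plus 500 retained
    steps.  ``walkers`` is the ensemble size per chain (default
    ``max(2*ndim + 2, 32)``, rounded up to even).  ``seed`` is mandatory:
    every source of randomness in a fit flows from it.
    """

    seed: int
    chains: int = 4
    iterations: int = 500
    burnin: int = 500
    walkers: int | None = None
    prior: str = "flat"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        if self.chains < 1 or self.iterations < 1 or self.burnin < 0:
            raise ValueError("chains, iterations must be >= 1 and burnin >= 0")
        if self.prior not in ("flat", "weak"):
            raise ValueError("prior must be 'flat' or 'weak'")


def _n_walkers(config: SamplerConfig, ndim: int) -> int:
    nw = config.walkers if config.walkers is not None else max(2 * ndim + 2, 32)
    if nw < 2 * ndim:
        raise ValueError(f"need at least {2 * ndim} walkers for {ndim} parameters")
    return nw + (nw % 2)


def run_chains(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init_center: np.ndarray,
    init_scale: np.ndarray,
    config: SamplerConfig,
) -> tuple[np.ndarray, dict]:
    """Run ``config.chains`` independent ensembles of a vectorized target.

    ``log_prob`` maps a ``(walkers, ndim)`` array to ``(walkers,)`` log
    densities.  Walkers start in a Gaussian ball ``init_center +
    init_scale * z``.  Returns draws of shape ``(chains, iterations, ndim)``
    (each chain's post-burn-in walker cloud evenly subsampled to
    ``iterations`` rows) and a metadata dict with acceptance fractions and
    any mixing warnings.
    """
    ndim = init_center.size
    n_walkers = _n_walkers(config, ndim)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    draws = np.empty((config.chains, config.iterations, ndim))
    acceptance = []
    warnings: list[str] = []
    for c, seq in enumerate(seeds):
        chain_seed = int(seq.generate_state(1)[0]) % (2**32 - 1)
        rng = np.random.default_rng(chain_seed)
        start = init_center + init_scale * rng.standard_normal((n_walkers, ndim))
        sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(chain_seed).get_state()
        sampler.run_mcmc(
            start, config.burnin + config.iterations, skip_initial_state_check=True
        )
        cloud = sampler.get_chain(discard=config.burnin)  # (steps, walkers, ndim)
        steps = cloud.shape[0]
        # spread retained draws over steps AND walkers so consecutive draws
        # come from different walkers (decorrelates the condensed chain)
        i = np.arange(config.iterations)
        step_idx = (i * steps) // config.iterations
        walker_idx = i % n_walkers
        draws[c] = cloud[step_idx, walker_idx]
        acceptance.append(float(np.mean(sampler.acceptance_fraction)))
    if min(acceptance) < 0.1:
        warnings.append(
            f"low ensemble acceptance fraction (min {min(acceptance):.3f}); "
            "treat posterior summaries with caution"
        )
    info = {
        "acceptance_fraction": acceptance,
        "n_walkers": n_walkers,
        "warnings": warnings,
    }
    return draws, info


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat convergence diagnostic for ``(chain, draw, ...)`` draws."""
    import arviz as az

    arr = draws if draws.ndim > 2 else draws[..., None]
    result = az.rhat(az.convert_to_dataset(arr))
    values = np.asarray(result["x"])
    return values if draws.ndim > 2 else values[..., 0]
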