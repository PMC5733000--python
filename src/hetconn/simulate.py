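"""Synthetic data with the exact statistical structure the models assume.

Two generators are provided.  ``simulate_lowdim`` realizes the rank-one
covariance regression: per time point, ``y = gamma * B x + eps`` with
standard-normal ``gamma`` and diagonal-normal ``eps``, so that with no
temporal dependence the vectors are iid with covariance exactly
``(Bx)(Bx)^T + diag(sigma^2)``.  ``simulate_scatter`` draws subject scatter
matrices as ``Y^T Y`` from mean-zero normal rows, i.e. exactly Wishart with
degrees of freedom N when rows are independent.

Temporal dependence, used to exercise effective-sample-size estimation, is
introduced by AR(1)-filtering the latent ``gamma`` sequence and each noise
component (or each row process) with coefficient ``ar_coeff``, scaled by
``sqrt(1 - ar_coeff^2)`` so marginal variances — and hence the implied
covariance — are unchanged.  This is a deliberate testing construction: the
models themselves treat time points as exchangeable.

All randomness flows from one integer seed through ``SeedSequence``
spawning, so each subject is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ScatterMatrix, TimeseriesMatrix
from .lkj import sample_lkj

__all__ = [
    "GroupSpec",
    "SimulationSpec",
    "simulate_lowdim",
    "simulate_scatter",
    "sample_lkj_prior",
]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: label, subject count and its design row."""

    label: str
    n_subjects: int
    x: tuple[float, ...]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth configuration for the rank-one generator."""

    p: int
    groups: tuple[GroupSpec, ...]
    B_true: np.ndarray
    sigma_true: np.ndarray
    N_per_subject: int
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B_true, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma_true, dtype=float))
        if B.shape[0] != self.p or sigma.shape[0] != self.p:
            raise ValueError("B_true rows and sigma_true length must equal p")
        if np.any(sigma <= 0):
            raise ValueError("sigma_true must be positive")
        if not -1.0 < self.ar_coeff < 1.0:
            raise ValueError("|ar_coeff| must be below 1")
        if self.N_per_subject < 2:
            raise ValueError("need at least 2 time points per subject")
        groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        )
        if not groups:
            raise ValueError("at least one group is required")
        J = B.shape[1]
        if any(len(g.x) != J for g in groups):
            raise ValueError("every design row must have J entries")
        object.__setattr__(self, "B_true", B)
        object.__setattr__(self, "sigma_true", sigma)
        object.__setattr__(self, "groups", groups)


def _ar1_filter(white: np.ndarray, phi: float) -> np.ndarray:
    """Variance-preserving AR(1) filter along axis 0 (stationary start)."""
    if phi == 0.0:
        return white
    out = np.empty_like(white)
    out[0] = white[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, white.shape[0]):
        out[t] = phi * out[t - 1] + scale * white[t]
    return out


def simulate_lowdim(
    spec: SimulationSpec,
) -> tuple[list[TimeseriesMatrix], pd.DataFrame, dict]:
    """Generate per-subject timeseries from the rank-one covariance model.

    Returns the series, a subjects table (subject_id, group, path) and a
    ground-truth record including the parcel-set partition implied by the
    sign pattern of the contrast column (column 2 of ``B_true``) when the
    design has one.
    """
    root = np.random.SeedSequence(spec.seed)
    series: list[TimeseriesMatrix] = []
    rows = []
    subject_seqs = root.spawn(sum(g.n_subjects for g in spec.groups))
    idx = 0
    for group in spec.groups:
        v = spec.B_true @ np.asarray(group.x, dtype=float)
        for _ in range(group.n_subjects):
            rng = np.random.default_rng(subject_seqs[idx])
            gamma = _ar1_filter(
                rng.standard_normal((spec.N_per_subject, 1)), spec.ar_coeff
            )
            eps = _ar1_filter(
                rng.standard_normal((spec.N_per_subject, spec.p)), spec.ar_coeff
            ) * spec.sigma_true
            values = gamma * v + eps
            subject_id = f"sub{idx + 1:04d}"
            series.append(TimeseriesMatrix(values=values, subject_id=subject_id))
            rows.append({"subject_id": subject_id, "group": group.label, "path": ""})
            idx += 1
    subjects = pd.DataFrame(rows)
    truth: dict = {
        "B_true": spec.B_true.tolist(),
        "sigma_true": spec.sigma_true.tolist(),
        "seed": spec.seed,
        "ar_coeff": spec.ar_coeff,
    }
    if spec.B_true.shape[1] >= 2:
        contrast = spec.B_true[:, 1]
        truth["set1"] = [int(j) for j in np.nonzero(contrast < 0)[0]]
        truth["set2"] = [int(j) for j in np.nonzero(contrast > 0)[0]]
    return series, subjects, truth


def simulate_scatter(
    Sigma1: np.ndarray,
    Sigma2: np.ndarray | None,
    groups: Sequence[tuple[Sequence[float], int]],
    N: int,
    ar_coeff: float = 0.0,
    seed: int = 0,
) -> list[ScatterMatrix]:
    """Draw subject scatter matrices ``S = Y^T Y`` from the Wishart model.

    Each group supplies a design row ``x`` (length 2; length 1 means
    intercept only) and a subject count; rows of ``Y`` are mean-zero normal
    with covariance ``x^(1) Sigma1 + x^(2) Sigma2``, which must be positive
    definite.  With ``ar_coeff = 0`` each S is exactly Wishart(scale, N).
    """
    Sigma1 = np.asarray(Sigma1, dtype=float)
    p = Sigma1.shape[0]
    root = np.random.SeedSequence(seed)
    total = sum(n for _, n in groups)
    seqs = root.spawn(total)
    out: list[ScatterMatrix] = []
    idx = 0
    for x, n_subjects in groups:
        x = np.asarray(x, dtype=float)
        combo = x[0] * Sigma1
        if x.size > 1 and x[1] != 0.0:
            if Sigma2 is None:
                raise ValueError("Sigma2 required for a nonzero contrast weight")
            combo = combo + x[1] * np.asarray(Sigma2, dtype=float)
        try:
            chol = np.linalg.cholesky(combo)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"group covariance for x = {x.tolist()} is not positive definite"
            ) from exc
        for _ in range(n_subjects):
            rng = np.random.default_rng(seqs[idx])
            white = _ar1_filter(rng.standard_normal((N, p)), ar_coeff)
            Y = white @ chol.T
            out.append(
                ScatterMatrix(
                    values=Y.T @ Y, n_timepoints=N, subject_id=f"sub{idx + 1:04d}"
                )
            )
            idx += 1
    return out


def sample_lkj_prior(
    p: int, eta: float, n_draws: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw correlation matrices from the LKJ(eta) prior, shape (n, p, p)."""
    return sample_lkj(p, eta, n_draws, seed)
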