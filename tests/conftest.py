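"""Shared fixtures: small simulated datasets and fitted posteriors.

Model fits are session-scoped so several tests can interrogate one
posterior; sizes are kept small enough that the whole suite runs on one
CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hetconn import (
    DesignMatrix,
    GroupSpec,
    SamplerConfig,
    SimulationSpec,
    align_signs,
    build_design,
    fit_fullcov,
    fit_lowdim,
    simulate_lowdim,
    simulate_scatter,
)

B1_TRUE = np.array([1.2, 0.8, 1.0, 0.9, 1.1])
B2_TRUE = np.array([-1.5, 1.6, 0.0, 1.2, -1.2])
SIGMA_TRUE = np.ones(5)


def make_lowdim_population(
    seed: int,
    n_per_group: int = 4,
    n_timepoints: int = 100,
    ar_coeff: float = 0.0,
):
    spec = SimulationSpec(
        p=5,
        groups=(
            GroupSpec("conv", n_per_group, (1.0, 0.0)),
            GroupSpec("short", n_per_group, (1.0, 1.0)),
        ),
        B_true=np.column_stack([B1_TRUE, B2_TRUE]),
        sigma_true=SIGMA_TRUE,
        N_per_subject=n_timepoints,
        ar_coeff=ar_coeff,
        seed=seed,
    )
    return simulate_lowdim(spec)


def stack_population(series, subjects, reference_group="conv"):
    design = build_design(subjects, reference_group)
    Y = np.vstack([ts.values for ts in series])
    X = DesignMatrix(
        values=np.repeat(design.values, [ts.n_timepoints for ts in series], axis=0),
        column_names=design.column_names,
    )
    return Y, X


@pytest.fixture(scope="session")
def lowdim_population():
    return make_lowdim_population(seed=42)


@pytest.fixture(scope="session")
def lowdim_posterior(lowdim_population):
    series, subjects, _ = lowdim_population
    Y, X = stack_population(series, subjects)
    return align_signs(fit_lowdim(Y, X, SamplerConfig(seed=7)))


@pytest.fixture(scope="session")
def fullcov_two_group_fit():
    p = 5
    sigma1 = np.eye(p)
    sigma2 = 0.5 * np.eye(p)
    sigma2[0, 1] = sigma2[1, 0] = 0.4
    scatters = simulate_scatter(
        sigma1, sigma2, [((1.0, 0.0), 60), ((1.0, 1.0), 60)], N=150, seed=3
    )
    subjects = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scatters],
            "group": ["conv"] * 60 + ["short"] * 60,
            "path": "",
        }
    )
    X = build_design(subjects, "conv")
    config = SamplerConfig(seed=9, chains=2, iterations=500, burnin=500)
    return fit_fullcov(scatters, X, config), sigma1, sigma2
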