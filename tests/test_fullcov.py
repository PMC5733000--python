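import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wishart

from hetconn import (
    SamplerConfig,
    ScatterMatrix,
    build_design,
    differential_probability,
    fdr_threshold,
    fit_fullcov,
    pair_count,
    posterior_fdr,
    simulate_scatter,
)
from hetconn.fullcov import wishart_logpdf_terms
from hetconn.lkj import tri_index


def upper_to_matrix(values):
    """Build a symmetric P matrix (zero diagonal) from upper-tri entries."""
    q = len(values)
    p = int(round((1 + np.sqrt(1 + 8 * q)) / 2))
    P = np.zeros((p, p))
    rows, cols = tri_index(p)
    P[rows, cols] = values
    return P + P.T


def test_pair_count_values():
    assert pair_count(50) == 1225
    assert pair_count(15) == 105
    assert pair_count(1) == 0
    with pytest.raises(ValueError):
        pair_count(0)


def test_differential_probability_examples():
    draws = np.ones((1000, 2, 2))
    draws[:, 0, 1] = draws[:, 1, 0] = 1.0
    assert differential_probability(draws)[0, 1] == 1.0
    draws[:500, 0, 1] = draws[:500, 1, 0] = -1.0
    assert differential_probability(draws)[0, 1] == 0.0
    draws[:250, 0, 1] = draws[:250, 1, 0] = 1.0  # 750 of 1000 positive
    assert differential_probability(draws)[0, 1] == pytest.approx(0.5)


def test_differential_probability_strict_inequality_and_diagonal():
    draws = np.zeros((10, 2, 2))  # draws exactly zero count as not-positive
    P = differential_probability(draws)
    assert P[0, 1] == 1.0  # Prob(>0) = 0 -> |2*0 - 1| = 1
    assert P[0, 0] == P[1, 1] == 0.0  # diagonal ignored


def test_posterior_fdr_hand_examples():
    P = upper_to_matrix([1.0, 1.0, 1.0])
    assert posterior_fdr(P, 0.5) == 0.0
    P = upper_to_matrix([0.99, 0.98, 0.6])
    assert posterior_fdr(P, 0.9) == pytest.approx((0.01 + 0.02) / 2)
    assert posterior_fdr(P, 0.999) is None  # empty selection


def test_fdr_threshold_all_certain():
    P = upper_to_matrix([1.0] * pair_count(4))
    report = fdr_threshold(P, 0.05)
    assert report.lambda_star == 0.0
    assert len(report.selected_pairs) == pair_count(4)
    assert report.fdr_achieved == 0.0


def test_fdr_threshold_excludes_weak_pair():
    P = upper_to_matrix([0.99, 0.98, 0.6])
    report = fdr_threshold(P, 0.05)
    assert report.fdr_achieved == pytest.approx(0.015)
    selected_values = sorted(P[i, j] for i, j in report.selected_pairs)
    assert selected_values == [0.98, 0.99]


def test_fdr_threshold_no_qualifying_grid_point():
    P = upper_to_matrix([0.3, 0.2, 0.1])
    report = fdr_threshold(P, 0.01)
    assert report.lambda_star == 1.0
    assert report.selected_pairs == ()
    assert np.isnan(report.fdr_achieved)


def test_selection_monotone_in_lambda():
    rng = np.random.default_rng(0)
    P = upper_to_matrix(rng.uniform(size=pair_count(6)))
    rows, cols = tri_index(6)
    sizes = [np.sum(P[rows, cols] > lam) for lam in np.arange(0, 1, 0.05)]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_fdr_bound_below_one_minus_lambda(seed):
    # whenever the selection is nonempty, every selected P exceeds lambda so
    # the mean of (1 - P) is strictly below 1 - lambda
    rng = np.random.default_rng(seed)
    P = upper_to_matrix(rng.uniform(size=pair_count(int(rng.integers(3, 8)))))
    lam = float(rng.uniform(0, 0.99))
    fdr = posterior_fdr(P, lam)
    if fdr is not None:
        assert fdr < 1 - lam


def test_wishart_terms_match_scipy():
    rng = np.random.default_rng(1)
    p, nu = 3, 17.5
    A = rng.standard_normal((p, p))
    V = A @ A.T + p * np.eye(p)
    scatters = [wishart.rvs(df=20, scale=V, random_state=rng) for _ in range(4)]
    sum_ld = float(sum(np.linalg.slogdet(s)[1] for s in scatters))
    s_sum = np.sum(scatters, axis=0)
    ours = wishart_logpdf_terms(
        np.array([nu]), V[None], len(scatters), sum_ld, s_sum, p
    )[0]
    ref = sum(wishart.logpdf(s, df=nu, scale=V) for s in scatters)
    assert ours == pytest.approx(ref, rel=1e-10)


def test_two_group_fit_flags_coupled_pair(fullcov_two_group_fit):
    post, _, _ = fullcov_two_group_fit
    P = differential_probability(post.omega2)
    assert P[0, 1] > 0.9  # truly coupled pair
    assert P[2, 3] < 0.5  # null pair
    np.testing.assert_allclose(P, P.T)
    assert np.all((P >= 0) & (P <= 1))


def test_posterior_sigma_matrices_positive_definite(fullcov_two_group_fit):
    post, _, _ = fullcov_two_group_fit
    for term in (1, 2):
        draws = post.sigma_matrix(term).reshape(-1, 5, 5)[:: 97]
        for sig in draws:
            assert np.linalg.eigvalsh(sig).min() > 0


def test_nu_posterior_within_prior_support(fullcov_two_group_fit):
    post, _, _ = fullcov_two_group_fit
    lo, hi = post.nu_bounds
    assert np.all((post.nu > lo) & (post.nu < hi))


def test_ar1_dependence_deflates_degrees_of_freedom():
    rng = np.random.default_rng(2)
    A = rng.standard_normal((4, 4))
    sigma = A @ A.T / 4 + np.eye(4)
    scatters = simulate_scatter(sigma, None, [((1.0,), 40)], N=100, ar_coeff=0.5, seed=21)
    subjects = pd.DataFrame(
        {"subject_id": [s.subject_id for s in scatters], "group": "g", "path": ""}
    )
    X = build_design(subjects, "g")
    config = SamplerConfig(seed=4, chains=2, iterations=300, burnin=300)
    post = fit_fullcov(scatters, X, config)
    assert float(np.median(post.nu)) < 100


def test_fit_input_validation():
    with pytest.raises(ValueError, match="at least one"):
        fit_fullcov(
            [],
            build_design(
                pd.DataFrame({"subject_id": ["a"], "group": "g", "path": ""}), "g"
            ),
            SamplerConfig(seed=1),
        )
    # singular scatter (N < p) is rejected by the Wishart density requirement
    rng = np.random.default_rng(3)
    y = rng.standard_normal((2, 3))
    singular = ScatterMatrix(values=y.T @ y, n_timepoints=2)
    subjects = pd.DataFrame({"subject_id": ["a"], "group": "g", "path": ""})
    with pytest.raises(ValueError, match="singular|positive|N > p"):
        fit_fullcov([singular], build_design(subjects, "g"), SamplerConfig(seed=1))


def test_fit_rejects_non_binary_contrast():
    rng = np.random.default_rng(4)
    scatters = simulate_scatter(np.eye(2), None, [((1.0,), 3)], N=20, seed=5)
    from hetconn import DesignMatrix

    X = DesignMatrix(
        values=np.column_stack([np.ones(3), [-1.0, 0.0, 1.0]]),
        column_names=("intercept", "contrast"),
    )
    with pytest.raises(ValueError, match="0/1"):
        fit_fullcov(scatters, X, SamplerConfig(seed=1))
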