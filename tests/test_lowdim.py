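import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from hetconn import (
    DesignMatrix,
    SamplerConfig,
    align_signs,
    expected_covariance,
    fit_lowdim,
    marginal_loglik,
    simulate_lowdim,
    summarize_coefficients,
)
from hetconn.lowdim import LowDimParams, LowDimPosterior
from hetconn.simulate import GroupSpec, SimulationSpec

from conftest import B1_TRUE, B2_TRUE, stack_population


def test_expected_covariance_hand_example():
    params = LowDimParams(B=np.array([[1.0], [1.0]]), sigma=np.array([1.0, 1.0]))
    np.testing.assert_allclose(
        expected_covariance(params, [1.0]), [[2.0, 1.0], [1.0, 2.0]]
    )


def test_expected_covariance_zero_coefficients():
    params = LowDimParams(B=np.zeros((3, 2)), sigma=np.array([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(
        expected_covariance(params, [1.0, 0.0]), np.diag([1.0, 4.0, 9.0])
    )


def test_coefficient_sign_pattern_controls_correlation_signs():
    # contrast column (-1, 3, 0, 2): parcels 1&2 and 1&4 negatively related,
    # 2&4 positively, parcel 3 uncorrelated
    b2 = np.array([-1.0, 3.0, 0.0, 2.0])
    params = LowDimParams(B=b2[:, None], sigma=np.ones(4))
    cov = expected_covariance(params, [1.0])
    assert cov[0, 1] < 0 and cov[0, 3] < 0 and cov[1, 3] > 0
    assert cov[2, 0] == cov[2, 1] == cov[2, 3] == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_expected_covariance_is_symmetric_psd(seed):
    rng = np.random.default_rng(seed)
    p, J = int(rng.integers(1, 7)), int(rng.integers(1, 4))
    params = LowDimParams(
        B=rng.standard_normal((p, J)), sigma=np.exp(rng.standard_normal(p))
    )
    cov = expected_covariance(params, rng.standard_normal(J))
    np.testing.assert_allclose(cov, cov.T, atol=1e-12)
    assert np.linalg.eigvalsh(cov).min() >= -1e-10


def test_loglik_standard_normal_point():
    params = LowDimParams(B=np.array([[0.0]]), sigma=np.array([1.0]))
    value = marginal_loglik(params, np.array([[1.0]]), np.array([[0.0]]))
    assert value == pytest.approx(-0.5 * np.log(2 * np.pi))


def test_loglik_matches_dense_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p, J, n = int(rng.integers(1, 7)), int(rng.integers(1, 3)), 5
        params = LowDimParams(
            B=rng.standard_normal((p, J)), sigma=np.exp(0.3 * rng.standard_normal(p))
        )
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])[:, :J]
        X[:, 0] = 1.0
        Y = rng.standard_normal((n, p))
        dense = sum(
            multivariate_normal.logpdf(
                Y[i],
                mean=np.zeros(p),
                cov=np.outer(params.B @ X[i], params.B @ X[i])
                + np.diag(params.sigma**2),
            )
            for i in range(n)
        )
        assert marginal_loglik(params, X, Y) == pytest.approx(dense, abs=1e-8)


def test_loglik_scaling_identity():
    rng = np.random.default_rng(2)
    p, J, n = 3, 2, 8
    params = LowDimParams(B=rng.standard_normal((p, J)), sigma=np.ones(p))
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
    Y = rng.standard_normal((n, p))
    base = marginal_loglik(params, X, Y)
    c = 2.5
    scaled = LowDimParams(B=c * params.B, sigma=c * params.sigma)
    shifted = marginal_loglik(scaled, X, c * Y)
    assert shifted - base == pytest.approx(-n * p * np.log(c), rel=1e-9)


def _toy_posterior(B_chains, sigma=None, aligned=False):
    chains, iters, p, J = B_chains.shape
    sigma = sigma if sigma is not None else np.ones((chains, iters, p))
    return LowDimPosterior(
        B=B_chains,
        sigma=sigma,
        column_names=tuple(f"c{j}" for j in range(J)),
        parcel_labels=tuple(f"R{i + 1}" for i in range(p)),
        seed=0,
        aligned=aligned,
        diagnostics={},
    )


def test_align_signs_flips_mirrored_chain():
    rng = np.random.default_rng(3)
    base = rng.standard_normal((1, 50, 4, 2)) + 2.0
    posterior = _toy_posterior(np.concatenate([base, -base]))
    aligned = align_signs(posterior)
    np.testing.assert_allclose(aligned.B[0].mean(axis=0), aligned.B[1].mean(axis=0))
    assert aligned.aligned


def test_align_signs_idempotent_and_preserves_magnitudes():
    rng = np.random.default_rng(4)
    B = rng.standard_normal((3, 40, 5, 2))
    posterior = _toy_posterior(B)
    once = align_signs(posterior)
    twice = align_signs(once)
    np.testing.assert_array_equal(once.B, twice.B)
    np.testing.assert_allclose(np.abs(once.B), np.abs(B))
    np.testing.assert_array_equal(once.sigma, posterior.sigma)


def test_align_signs_recovers_all_sign_patterns():
    rng = np.random.default_rng(5)
    ref = rng.standard_normal((1, 30, 4, 3)) + 1.5
    chains = [ref[0]]
    for pattern in range(1, 2**3):
        signs = np.array([(-1.0 if pattern >> j & 1 else 1.0) for j in range(3)])
        chains.append(ref[0] * signs[None, None, :])
    posterior = _toy_posterior(np.stack(chains))
    aligned = align_signs(posterior, reference=0)
    for c in range(len(chains)):
        np.testing.assert_allclose(aligned.B[c], ref[0], atol=1e-12)


def test_summarize_requires_alignment():
    posterior = _toy_posterior(np.ones((2, 10, 3, 2)))
    with pytest.raises(ValueError, match="align"):
        summarize_coefficients(posterior)


def test_summarize_set_assignment():
    draws = np.zeros((1, 400, 3, 2))
    rng = np.random.default_rng(6)
    draws[0, :, 0, 1] = rng.normal(2.0, 0.1, 400)  # strictly positive -> set2
    draws[0, :, 1, 1] = rng.normal(-2.0, 0.1, 400)  # strictly negative -> set1
    draws[0, :, 2, 1] = rng.normal(0.0, 1.0, 400)  # symmetric -> undecided
    summary = summarize_coefficients(_toy_posterior(draws, aligned=True), column=1)
    assert list(summary["set"]) == ["set2", "set1", "undecided"]
    assert (summary["lower"] <= summary["median"]).all()
    assert (summary["median"] <= summary["upper"]).all()
    undecided = summary["set"] == "undecided"
    contains_zero = (summary["lower"] <= 0) & (summary["upper"] >= 0)
    assert (undecided == contains_zero).all()


def test_summarize_invariant_to_global_flip():
    rng = np.random.default_rng(7)
    draws = rng.standard_normal((2, 200, 4, 2)) + np.array([2.0, -2.0, 0.0, 1.5])[
        None, None, :, None
    ]
    a = summarize_coefficients(_toy_posterior(draws, aligned=True), column=1)
    b = summarize_coefficients(_toy_posterior(-draws, aligned=True), column=1)
    swap = {"set1": "set2", "set2": "set1", "undecided": "undecided"}
    assert [swap[s] for s in a["set"]] == list(b["set"])


def test_bonferroni_quantile_pair():
    # alpha=0.05, m=15 puts the endpoints at the 0.003333 / 0.996667 quantiles
    draws = np.random.default_rng(8).standard_normal((1, 20_000, 1, 2))
    summary = summarize_coefficients(
        _toy_posterior(draws, aligned=True), column=1, alpha=0.05, m=15
    )
    pooled = draws[0, :, 0, 1]
    assert summary["lower"][0] == pytest.approx(
        np.quantile(pooled, 0.05 / 15), abs=1e-12
    )
    assert summary["upper"][0] == pytest.approx(
        np.quantile(pooled, 1 - 0.05 / 15), abs=1e-12
    )


def test_fit_recovers_truth_within_posterior_uncertainty(lowdim_posterior):
    post = lowdim_posterior
    truth = np.column_stack([B1_TRUE, B2_TRUE])
    draws = post.B.reshape(-1, 5, 2)
    z = np.abs((draws.mean(axis=0) - truth) / draws.std(axis=0))
    assert np.mean(z < 3.0) >= 0.9
    assert post.diagnostics["rhat_max"] < 1.2


def test_fit_posterior_predictive_covariance(lowdim_posterior):
    post = lowdim_posterior
    draws_B = post.B.reshape(-1, 5, 2).mean(axis=0)
    draws_s = post.sigma.reshape(-1, 5).mean(axis=0)
    params = LowDimParams(B=draws_B, sigma=draws_s)
    for x in ([1.0, 0.0], [1.0, 1.0]):
        spec = SimulationSpec(
            p=5,
            groups=(GroupSpec("g", 1, tuple(x)),),
            B_true=draws_B,
            sigma_true=draws_s,
            N_per_subject=50_000,
            seed=123,
        )
        series, _, _ = simulate_lowdim(spec)
        sample_cov = np.cov(series[0].values.T, bias=True)
        expected = expected_covariance(params, x)
        rel = np.linalg.norm(sample_cov - expected) / np.linalg.norm(expected)
        assert rel < 0.10


def test_fit_is_deterministic_given_seed(lowdim_population):
    series, subjects, _ = lowdim_population
    Y, X = stack_population(series, subjects)
    config = SamplerConfig(seed=31, chains=2, iterations=100, burnin=100)
    a = fit_lowdim(Y, X, config)
    b = fit_lowdim(Y, X, config)
    np.testing.assert_array_equal(a.B, b.B)
    np.testing.assert_array_equal(a.sigma, b.sigma)


def test_fit_univariate_matches_method_of_moments():
    rng = np.random.default_rng(9)
    b, sigma = 1.3, 0.7
    y = (rng.standard_normal(2000) * b + rng.standard_normal(2000) * sigma)[:, None]
    X = DesignMatrix(values=np.ones((2000, 1)), column_names=("intercept",))
    post = fit_lowdim(y, X, SamplerConfig(seed=12, chains=2, iterations=200, burnin=200))
    second_moment = float(np.mean(post.B[..., 0, 0] ** 2 + post.sigma[..., 0] ** 2))
    assert second_moment == pytest.approx(float(np.mean(y**2)), rel=0.10)


def test_null_data_leaves_parcels_undecided():
    # with B = 0 the Bonferroni-corrected intervals should almost always
    # straddle zero for every parcel
    all_undecided = 0
    n_rep = 20
    for rep in range(n_rep):
        spec = SimulationSpec(
            p=3,
            groups=(GroupSpec("a", 1, (1.0, 0.0)), GroupSpec("b", 1, (1.0, 1.0))),
            B_true=np.zeros((3, 2)),
            sigma_true=np.ones(3),
            N_per_subject=100,
            seed=1000 + rep,
        )
        series, subjects, _ = simulate_lowdim(spec)
        Y, X = stack_population(series, subjects, reference_group="a")
        config = SamplerConfig(seed=rep, chains=2, iterations=150, burnin=150)
        post = align_signs(fit_lowdim(Y, X, config))
        summary = summarize_coefficients(post, column=1, alpha=0.05)
        if (summary["set"] == "undecided").all():
            all_undecided += 1
    assert all_undecided >= 0.8 * n_rep


def test_fit_input_validation(lowdim_population):
    series, subjects, _ = lowdim_population
    Y, X = stack_population(series, subjects)
    with pytest.raises(ValueError, match="design rows"):
        fit_lowdim(Y[:-1], X, SamplerConfig(seed=1))
    with pytest.raises(ValueError):
        fit_lowdim(np.empty((0, 5)), X, SamplerConfig(seed=1))
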