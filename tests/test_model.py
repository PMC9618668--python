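"""Model construction, posterior density and MCMC engine."""

import numpy as np
import pandas as pd
import pytest

from mixedstock import (
    BaselineTable,
    MixedStockTable,
    build_model,
    fit,
    fit_many_to_one,
    log_posterior,
    run_chain,
    theta_from_phi,
    transport_alpha,
)
from mixedstock.hapio import ValidationError

from _oracles import log_posterior_mp


class TestBuildModel:
    def test_variant1_uniform_prior(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed, variant=1, c=1.0)
        np.testing.assert_allclose(spec.alpha, 1 / 3)
        assert spec.excluded == []
        assert not spec.use_transport

    def test_transport_residual_rule(self):
        np.testing.assert_allclose(transport_alpha(np.array([0.2, 0.3]), c=1.0),
                                   [0.2, 0.3, 0.5])
        # floor keeps every destination strictly positive
        a = transport_alpha(np.array([0.0, 1.0]), c=1.0)
        assert np.all(a > 0)
        assert a.sum() == pytest.approx(1.0)

    def test_variant2_excludes_zero_transport_rookery(self, toy_tables):
        baseline, mixed = toy_tables
        baseline.p[1] = 0.0  # BBB unreachable from both stocks
        spec = build_model(baseline, mixed, variant=2)
        assert spec.rookery_codes == ["AAA", "CCC"]
        assert spec.excluded == ["BBB"]
        np.testing.assert_allclose(spec.alpha.sum(axis=1), 1.0)

    def test_transport_required_for_variant2(self, toy_tables):
        baseline, mixed = toy_tables
        baseline = BaselineTable(baseline.rookery_codes, baseline.haplotype_names,
                                 baseline.X, baseline.N)
        with pytest.raises(ValidationError, match="transport"):
            build_model(baseline, mixed, variant=2)

    def test_all_rookeries_excluded_is_error(self, toy_tables):
        baseline, mixed = toy_tables
        baseline.p[:] = 0.0
        with pytest.raises(ValidationError, match="zero transport"):
            build_model(baseline, mixed, variant=2)

    def test_beta_defaults_to_one_over_h(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed)
        np.testing.assert_allclose(spec.beta, 1 / 4)

    def test_use_sizes_off_equals_equal_sizes(self, toy_tables):
        baseline, mixed = toy_tables
        no_sizes = build_model(baseline, mixed, use_sizes=False)
        equal_N = BaselineTable(baseline.rookery_codes, baseline.haplotype_names,
                                baseline.X, np.ones(baseline.R))
        with_sizes = build_model(equal_N, mixed)
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.ones(3), 3)
        f = rng.dirichlet(np.ones(4), 3)
        a = log_posterior(no_sizes, baseline, mixed, phi, f)
        b = log_posterior(with_sizes, equal_N, mixed, phi, f)
        assert a == pytest.approx(b, abs=1e-9)

    def test_unharmonized_axes_rejected(self, toy_tables):
        baseline, mixed = toy_tables
        mixed2 = MixedStockTable(mixed.stock_codes, ["h4", "h3", "h2", "h1"], mixed.Y)
        with pytest.raises(ValidationError, match="harmonize"):
            build_model(baseline, mixed2)


class TestThetaFromPhi:
    def test_single_rookery_is_one(self):
        theta = theta_from_phi(np.array([[0.3, 0.5, 0.2]]), np.array([123.0]))
        np.testing.assert_array_equal(theta, np.ones((2, 1)))

    def test_symmetric_system_is_uniform(self):
        phi = np.full((4, 3), 1 / 3)
        theta = theta_from_phi(phi, np.full(4, 250.0))
        np.testing.assert_allclose(theta, 0.25)

    def test_size_weighting(self):
        phi = np.array([[0.2, 0.8], [0.1, 0.9]])  # M = 1
        theta = theta_from_phi(phi, np.array([100.0, 300.0]))
        np.testing.assert_allclose(theta, [[0.4, 0.6]])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            theta_from_phi(np.ones((2, 3)) / 3, np.array([1.0, 2.0, 3.0]))

    def test_zero_denominator_fallback(self, caplog):
        phi = np.array([[0.0, 1.0], [0.0, 1.0]])  # nobody sends to the stock
        alpha = np.array([[0.5, 0.5], [0.5, 0.5]])
        with caplog.at_level("WARNING", logger="mixedstock"):
            theta = theta_from_phi(phi, np.array([100.0, 300.0]), alpha)
        assert "fallback" in caplog.text
        np.testing.assert_allclose(theta, [[0.25, 0.75]])  # N-weighted prior mean


class TestLogPosterior:
    def _tiny(self):
        baseline = BaselineTable(["a", "b"], ["h1", "h2"],
                                 np.array([[3, 1], [0, 4]]), np.array([10.0, 30.0]))
        mixed = MixedStockTable(["S"], ["h1", "h2"], np.array([[2, 3]]))
        return baseline, mixed, build_model(baseline, mixed, variant=1)

    def test_matches_arbitrary_precision_oracle(self):
        baseline, mixed, spec = self._tiny()
        rng = np.random.default_rng(7)
        for _ in range(20):
            phi = rng.dirichlet([1, 1], 2)
            f = rng.dirichlet([1, 1], 2)
            ours = log_posterior(spec, baseline, mixed, phi, f)
            oracle = log_posterior_mp(spec.alpha, spec.beta, baseline.X, mixed.Y,
                                      baseline.N, phi, f)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_zero_mixed_counts_reduce_to_prior_and_baseline(self):
        baseline, _, spec = self._tiny()
        empty = MixedStockTable(["S"], ["h1", "h2"], np.array([[0, 0]]), validate=False)
        rng = np.random.default_rng(8)
        phi = rng.dirichlet([1, 1], 2)
        f = rng.dirichlet([1, 1], 2)
        ours = log_posterior(spec, baseline, empty, phi, f)
        oracle = log_posterior_mp(spec.alpha, spec.beta, baseline.X,
                                  np.array([[0, 0]]), baseline.N, phi, f)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_single_rookery_mixture_is_multinomial(self):
        baseline = BaselineTable(["a"], ["h1", "h2"], np.array([[5, 5]]), np.array([10.0]))
        mixed = MixedStockTable(["S"], ["h1", "h2"], np.array([[2, 3]]))
        spec = build_model(baseline, mixed)
        phi = np.array([[0.6, 0.4]])
        f = np.array([[0.3, 0.7]])
        full = log_posterior(spec, baseline, mixed, phi, f)
        empty = MixedStockTable(["S"], ["h1", "h2"], np.array([[0, 0]]), validate=False)
        base_only = log_posterior(spec, baseline, empty, phi, f)
        assert full - base_only == pytest.approx(2 * np.log(0.3) + 3 * np.log(0.7))

    def test_boundary_zero_probability_is_neg_inf(self):
        baseline, mixed, spec = self._tiny()
        phi = np.full((2, 2), 0.5)
        f = np.array([[0.0, 1.0], [0.0, 1.0]])  # h1 impossible but observed
        assert log_posterior(spec, baseline, mixed, phi, f) == -np.inf


def _separated_system(R=3, H=4, n_mixed=60, seed=0):
    """Near-disjoint baselines so the mixture is informative."""
    rng = np.random.default_rng(seed)
    X = np.full((R, H), 0)
    for r in range(R):
        X[r, r % H] = 40
        X[r, (r + 1) % H] = 10
    f_true = (X + 0.5) / (X + 0.5).sum(axis=1, keepdims=True)
    w = rng.dirichlet(np.ones(R))
    Y = np.zeros((1, H), dtype=int)
    for r, k in enumerate(rng.multinomial(n_mixed, w)):
        Y[0] += rng.multinomial(k, f_true[r])
    baseline = BaselineTable([f"r{i}" for i in range(R)], [f"h{j}" for j in range(H)],
                             X, np.full(R, 500.0))
    mixed = MixedStockTable(["S"], list(baseline.haplotype_names), Y)
    return baseline, mixed


class TestRunChain:
    def test_single_rookery_theta_is_exactly_one(self):
        baseline = BaselineTable(["only"], ["h1", "h2"], np.array([[7, 3]]), np.array([50.0]))
        mixed = MixedStockTable(["N", "E"], ["h1", "h2"], np.array([[4, 1], [2, 2]]))
        spec = build_model(baseline, mixed)
        draws = run_chain(spec, baseline, mixed, iterations=800, burn_in=300, seed=1)
        assert np.all(draws.theta == 1.0)

    def test_bitwise_determinism(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed, variant=2)
        a = run_chain(spec, baseline, mixed, iterations=1500, burn_in=500, seed=11)
        b = run_chain(spec, baseline, mixed, iterations=1500, burn_in=500, seed=11)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.f, b.f)

    def test_simplex_invariants(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed, variant=1)
        d = run_chain(spec, baseline, mixed, iterations=1500, burn_in=500, seed=2)
        np.testing.assert_allclose(d.phi.sum(axis=2), 1.0, atol=1e-9)
        np.testing.assert_allclose(d.theta.sum(axis=2), 1.0, atol=1e-9)
        np.testing.assert_allclose(d.f.sum(axis=2), 1.0, atol=1e-9)

    def test_label_equivariance_is_exact(self):
        baseline, mixed = _separated_system()
        perm = [2, 0, 1]
        baseline_p = BaselineTable(
            [baseline.rookery_codes[i] for i in perm],
            list(baseline.haplotype_names),
            baseline.X[perm],
            baseline.N[perm],
        )
        spec = build_model(baseline, mixed, variant=1)
        spec_p = build_model(baseline_p, mixed, variant=1)
        a = run_chain(spec, baseline, mixed, iterations=600, burn_in=200, seed=5)
        b = run_chain(spec_p, baseline_p, mixed, iterations=600, burn_in=200, seed=5)
        np.testing.assert_array_equal(b.theta, a.theta[:, :, perm])
        np.testing.assert_array_equal(b.phi, a.phi[:, perm, :])
        np.testing.assert_array_equal(b.f, a.f[:, perm, :])

    def test_orphan_haplotype_rejected(self):
        baseline = BaselineTable(["a"], ["h1", "h2"], np.array([[5, 0]]), np.array([10.0]))
        mixed = MixedStockTable(["S"], ["h1", "h2"], np.array([[2, 3]]))
        spec = build_model(baseline, mixed)
        with pytest.raises(ValidationError, match="orphan"):
            run_chain(spec, baseline, mixed, iterations=100, burn_in=10, seed=0)

    def test_prior_dominance_without_mixed_data(self):
        """With no mixed individuals the theta means revert to the
        size-and-transport-weighted prior means implied by alpha and N."""
        rng = np.random.default_rng(0)
        baseline = BaselineTable(
            ["a", "b", "c"], ["h1", "h2"],
            np.array([[8, 2], [5, 5], [1, 9]]), np.array([200.0, 1000.0, 50.0]),
            p=np.array([[0.4, 0.1], [0.05, 0.2], [0.3, 0.3]]), p_stocks=["N", "E"],
        )
        empty = MixedStockTable(["N", "E"], ["h1", "h2"],
                                np.zeros((2, 2), dtype=int), validate=False)
        spec = build_model(baseline, empty, variant=2)
        draws = run_chain(spec, baseline, empty, iterations=30_000, burn_in=5_000, seed=3)
        phi_mc = np.stack([rng.dirichlet(a, 100_000) for a in spec.alpha], axis=1)
        prior_means = np.stack([theta_from_phi(p, baseline.N) for p in phi_mc[::20]]).mean(axis=0)
        np.testing.assert_allclose(draws.theta.mean(axis=0), prior_means, atol=0.04)

    def test_invalid_iteration_counts(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed)
        with pytest.raises(ValueError):
            run_chain(spec, baseline, mixed, iterations=100, burn_in=100)


class TestFit:
    def test_identical_seed_identical_summary(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed, variant=1)
        r1 = fit(spec, baseline, mixed, chains=2, iterations=1200, burn_in=600, seed=21)
        r2 = fit(spec, baseline, mixed, chains=2, iterations=1200, burn_in=600, seed=21)
        pd.testing.assert_frame_equal(r1.summary.theta, r2.summary.theta)
        pd.testing.assert_frame_equal(r1.convergence.table, r2.convergence.table)

    def test_posterior_mass_conservation(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed, variant=1)
        res = fit(spec, baseline, mixed, chains=2, iterations=1500, burn_in=500, seed=4)
        sums = res.summary.theta.groupby("stock")["mean"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_requires_two_chains(self, toy_tables):
        baseline, mixed = toy_tables
        spec = build_model(baseline, mixed)
        with pytest.raises(ValueError, match="chains"):
            fit(spec, baseline, mixed, chains=1, iterations=200, burn_in=100)


class TestManyToOne:
    def test_single_rookery(self):
        baseline = BaselineTable(["only"], ["h1", "h2"], np.array([[7, 3]]), np.array([50.0]))
        mixed = MixedStockTable(["S"], ["h1", "h2"], np.array([[4, 1]]))
        res = fit_many_to_one(baseline, mixed, chains=2, iterations=600, burn_in=200, seed=0)
        np.testing.assert_array_equal(res.draws.theta, 1.0)

    def test_requires_single_stock(self, toy_tables):
        baseline, mixed = toy_tables
        with pytest.raises(ValueError, match="one mixed stock"):
            fit_many_to_one(baseline, mixed)

    def test_agrees_with_many_to_many_in_m1_limit(self):
        """With one stock, equal rookery sizes and matched flat priors the two
        parameterizations target nearly the same posterior."""
        baseline, mixed = _separated_system(n_mixed=80, seed=3)
        spec = build_model(baseline, mixed, variant=1)
        m2m = fit(spec, baseline, mixed, chains=2, iterations=9_000, burn_in=3_000, seed=12)
        m21 = fit_many_to_one(baseline, mixed, chains=2, iterations=9_000, burn_in=3_000, seed=13)
        a = m2m.summary.theta.set_index("rookery")["mean"]
        b = m21.summary.theta.set_index("rookery")["mean"]
        assert float((a - b).abs().max()) < 0.02
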