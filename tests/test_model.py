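import math

import numpy as np
import pytest
from scipy import integrate, stats

from motifact.model import (
    ModelConfig,
    StepLikelihood,
    activity_score,
    beta_shapes,
    exact_cell_probabilities,
    exact_log_likelihood,
    fit_two_param,
    laplace_posterior,
    log_bayes_factor,
    log_marginal_likelihood,
    log_posterior_kernel,
    make_kernel,
    posterior_summary,
    ppc_envelope,
    sample_posterior,
    simulate_counts,
    step_log_likelihood,
)
from motifact.partition import IntervalPartition, MotifCountVector


def quadrature_moments(counts, part, config, lo=-60, hi=60):
    """Independent oracle: posterior mean/sd by normalized grid quadrature."""
    kernel = make_kernel(counts, part, config)
    grid = np.linspace(lo, hi, 20001)
    lk = np.array([kernel(a) for a in grid])
    w = np.exp(lk - lk.max())
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid)
    var = np.trapezoid(w * (grid - mean) ** 2, grid)
    return float(mean), float(math.sqrt(var))


class TestBetaShapes:
    @pytest.mark.parametrize("a,alpha,beta", [
        (0.0, 1.0, 1.0),  # uniform null Beta(1,1)
        (2.0, 3.0, 1.0),
        (-1.0, 1.0, 2.0),
        (0.5, 1.5, 1.0),
    ])
    def test_mapping(self, a, alpha, beta):
        sh = beta_shapes(a)
        assert (sh.alpha, sh.beta) == (alpha, beta)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            beta_shapes(float("nan"))


class TestLikelihoods:
    def test_null_two_halves_hand_value(self):
        part = IntervalPartition.from_lengths([0.5, 0.5])
        nv = MotifCountVector([1, 1])
        assert step_log_likelihood(nv, part, 0.0) == pytest.approx(2 * math.log(0.5))
        assert exact_log_likelihood(nv, part, 0.0) == pytest.approx(2 * math.log(0.5))

    def test_zero_counts_likelihood_is_zero_for_any_a(self, equal_partition):
        nv = MotifCountVector(np.zeros(1000))
        for a in (-3.0, 0.0, 2.5):
            assert step_log_likelihood(nv, equal_partition, a) == 0.0
            assert exact_log_likelihood(nv, equal_partition, a) == 0.0

    def test_exact_incomplete_beta_hand_example(self):
        # (alpha, beta) = (2, 1): I(x; 2, 1) = x^2 -> p = (0.25, 0.75)
        part = IntervalPartition.from_lengths([0.5, 0.5])
        nv = MotifCountVector([1, 1])
        got = exact_log_likelihood(nv, part, 1.0)
        assert got == pytest.approx(math.log(0.25) + math.log(0.75))
        assert exact_cell_probabilities(part, 1.0) == pytest.approx([0.25, 0.75])

    def test_exact_probabilities_sum_to_one(self, rng):
        lengths = rng.dirichlet(np.ones(50))
        part = IntervalPartition.from_lengths(lengths)
        for a in (-4.0, -0.5, 0.0, 1.3, 6.0):
            assert exact_cell_probabilities(part, a).sum() == pytest.approx(
                1.0, abs=1e-10)

    def test_step_matches_exact_on_fine_equal_partition(self, rng):
        part = IntervalPartition.equal(10_000)
        nv = simulate_counts(part, 3.0, 400, seed=rng)
        step = step_log_likelihood(nv, part, 3.0)
        exact = exact_log_likelihood(nv, part, 3.0)
        assert step == pytest.approx(exact, abs=1e-3)

    def test_refinement_error_shrinks_as_partition_doubles(self):
        # fix occurrence positions; count vectors refine with the partition
        positions = np.linspace(0.012, 0.988, 37)
        a = 2.0
        errs = []
        for n_int in (50, 100, 200, 400):
            part = IntervalPartition.equal(n_int)
            counts = np.histogram(positions, bins=part.boundaries)[0]
            nv = MotifCountVector(counts)
            errs.append(abs(step_log_likelihood(nv, part, a)
                            - exact_log_likelihood(nv, part, a)))
        assert errs[-1] < errs[0]
        # empirical order >= 1: error roughly halves per doubling
        assert errs[-1] <= errs[0] / 4

    def test_unnormalized_form_differs_by_a_dependent_constant(self):
        part = IntervalPartition.equal(20)
        nv = MotifCountVector(np.arange(20) % 3)
        norm = step_log_likelihood(nv, part, 1.5, normalize=True)
        raw = step_log_likelihood(nv, part, 1.5, normalize=False)
        lik = StepLikelihood(nv, part)
        z = np.dot(part.lengths, 2.5 * part.midpoints**1.5)
        assert raw - norm == pytest.approx(nv.total * math.log(z), abs=1e-9)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            step_log_likelihood(MotifCountVector([1]), IntervalPartition.equal(3), 0.0)


class TestKernel:
    def test_zero_counts_kernel_equals_prior(self, equal_partition):
        cfg = ModelConfig()
        nv = MotifCountVector(np.zeros(1000))
        for a in (-2.0, 0.0, 3.0):
            got = log_posterior_kernel(nv, equal_partition, a, cfg)
            assert got == pytest.approx(stats.norm.logpdf(a, 0, 10))

    def test_kernel_difference_decomposes(self, equal_partition, rng):
        cfg = ModelConfig()
        nv = simulate_counts(equal_partition, 1.0, 100, seed=rng)
        dk = (log_posterior_kernel(nv, equal_partition, 1.0, cfg)
              - log_posterior_kernel(nv, equal_partition, 0.0, cfg))
        dl = (step_log_likelihood(nv, equal_partition, 1.0)
              - step_log_likelihood(nv, equal_partition, 0.0))
        dp = stats.norm.logpdf(1.0, 0, 10) - stats.norm.logpdf(0.0, 0, 10)
        assert dk == pytest.approx(dl + dp)


class TestActivityScore:
    def test_zero_mean_is_zero(self):
        for sd in (0.1, 1.0, 50.0):
            assert activity_score(0.0, sd) == 0.0

    def test_five_sigma_hand_value(self):
        # tail = Phi(-5) = 2.8665e-7; score = -ln(tail) - ln 2
        expected = -math.log(2.866516e-7) - math.log(2)
        assert activity_score(5.0, 1.0) == pytest.approx(expected, rel=1e-5)
        assert activity_score(-5.0, 1.0) == pytest.approx(-expected, rel=1e-5)

    def test_no_underflow_for_extreme_means(self):
        val = activity_score(40.0, 1.0)
        assert np.isfinite(val) and val > 700

    def test_strictly_increasing_in_mean(self):
        means = np.linspace(-8, 8, 81)
        scores = [activity_score(m, 1.7) for m in means]
        assert np.all(np.diff(scores) > 0)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            activity_score(1.0, 0.0)


class TestEmpiricalActivityScore:
    def test_agrees_with_normal_tail_in_the_bulk(self, rng):
        from motifact.model import empirical_activity_score

        draws = rng.normal(1.0, 1.0, size=20_000)
        emp = empirical_activity_score(draws)
        approx = activity_score(float(draws.mean()), float(draws.std(ddof=1)))
        assert emp == pytest.approx(approx, abs=0.1)

    def test_tail_floored_at_one_draw(self, rng):
        from motifact.model import empirical_activity_score

        draws = rng.normal(50.0, 1.0, size=1000)  # no draws cross zero
        assert empirical_activity_score(draws) == pytest.approx(
            math.log(1000) - math.log(2))


class TestPosteriorSummary:
    def test_identical_chains_have_rhat_one(self):
        # zero between-chain variance; the split/rank-normalized statistic
        # still compares chain halves, so equality is to ~1e-2, not exact
        draws = np.tile(np.random.default_rng(0).normal(size=500), (3, 1))
        *_, rhat, _ = posterior_summary(draws)
        assert rhat == pytest.approx(1.0, abs=0.01)

    def test_iid_normal_ess_near_sample_size(self, rng):
        n = 8000
        draws = rng.normal(size=(4, n // 4))
        *_, ess = posterior_summary(draws)
        assert 0.8 * n <= ess <= 1.2 * n

    def test_median_interval_quantile_convention(self):
        draws = np.array([[1.0, 2.0, 3.0, 4.0]])
        _, _, ci, rhat, _ = posterior_summary(draws, level=0.5)
        assert ci == pytest.approx((1.75, 3.25))
        assert math.isnan(rhat)  # single chain


class TestSampling:
    def test_no_data_posterior_matches_prior(self, equal_partition):
        nv = MotifCountVector(np.zeros(1000))
        res = sample_posterior(nv, equal_partition, ModelConfig(seed=11))
        assert abs(res.mean) < 0.5
        assert 9.0 <= res.sd <= 11.0
        assert res.backend_used == "mcmc"

    def test_reproducible_given_seed(self, equal_partition, fast_config):
        nv = simulate_counts(equal_partition, 2.0, 200, seed=5)
        r1 = sample_posterior(nv, equal_partition, fast_config)
        r2 = sample_posterior(nv, equal_partition, fast_config)
        assert np.array_equal(r1.samples, r2.samples)
        assert r1.activity == r2.activity

    def test_mirror_antisymmetry_of_posterior(self, fast_config):
        lengths = np.random.default_rng(3).dirichlet(np.ones(400))
        part = IntervalPartition.from_lengths(lengths)
        nv = simulate_counts(part, 1.5, 300, seed=9)
        fwd = sample_posterior(nv, part, fast_config)
        rev = sample_posterior(nv.reversed(), part.reversed(), fast_config)
        # mirrored data flips the sign of the activity posterior
        assert rev.mean == pytest.approx(-fwd.mean, abs=4 * fwd.sd / 10)
        assert rev.activity == pytest.approx(-fwd.activity, rel=0.15)

    def test_quadrature_moments_match_mcmc(self, fast_config, rng):
        part = IntervalPartition.equal(500)
        for a_true, n_tot in [(0.0, 50), (2.0, 300), (-1.0, 150)]:
            nv = simulate_counts(part, a_true, n_tot, seed=rng)
            res = sample_posterior(nv, part, fast_config)
            qm, qs = quadrature_moments(nv, part, fast_config)
            mc_se = qs / math.sqrt(max(res.ess, 1.0))
            assert res.mean == pytest.approx(qm, abs=3 * mc_se + 1e-3)
            assert res.sd == pytest.approx(qs, rel=0.12)


class TestLaplace:
    def test_no_data_recovers_the_prior(self, equal_partition):
        nv = MotifCountVector(np.zeros(1000))
        res = laplace_posterior(nv, equal_partition, ModelConfig())
        assert res.mean == pytest.approx(0.0, abs=1e-4)
        assert res.sd == pytest.approx(10.0, rel=1e-3)
        assert res.samples is None and math.isnan(res.rhat)

    def test_mode_matches_grid_argmax(self, rng):
        part = IntervalPartition.equal(400)
        cfg = ModelConfig()
        for i in range(10):
            a_true = float(rng.uniform(-3, 3))
            nv = simulate_counts(part, a_true, int(rng.integers(50, 500)), seed=rng)
            kernel = make_kernel(nv, part, cfg)
            grid = np.linspace(-8, 8, 3201)
            amax = grid[np.argmax([kernel(a) for a in grid])]
            res = laplace_posterior(nv, part, cfg)
            assert res.mean == pytest.approx(amax, abs=1e-2)


class TestMarginalLikelihood:
    def test_zero_counts_bf_is_zero(self, equal_partition):
        nv = MotifCountVector(np.zeros(1000))
        assert log_bayes_factor(nv, equal_partition, ModelConfig()) == 0.0

    def test_bridge_agrees_with_quadrature(self, fast_config, rng):
        part = IntervalPartition.equal(300)
        for i in range(10):
            a_true = float(rng.uniform(-2.5, 2.5))
            nv = simulate_counts(part, a_true, int(rng.integers(30, 400)), seed=rng)
            post = sample_posterior(nv, part, fast_config)
            q = log_marginal_likelihood(nv, part, fast_config, method="quadrature")
            b = log_marginal_likelihood(nv, part, fast_config, method="bridge",
                                        posterior=post)
            assert abs(q - b) < 0.1

    def test_signal_data_has_positive_log_bf(self, rng):
        part = IntervalPartition.equal(500)
        nv = simulate_counts(part, 3.0, 500, seed=rng)
        assert log_bayes_factor(nv, part, ModelConfig()) > 0


class TestTwoParam:
    def test_symmetric_counts_give_tau_half(self, fast_config):
        part = IntervalPartition.equal(100)
        counts = np.zeros(100, dtype=int)
        counts[10] = counts[89] = 5
        counts[30] = counts[69] = 3
        res = fit_two_param(MotifCountVector(counts), part, fast_config)
        assert res.tau_mean == pytest.approx(0.5, abs=0.05)
        assert abs(res.activity) < 3.0

    def test_beta_3_1_positions_recover_tau(self, fast_config, rng):
        part = IntervalPartition.equal(500)
        nv = simulate_counts(part, 2.0, 1000, seed=rng)  # Beta(3,1), mean 0.75
        res = fit_two_param(nv, part, fast_config)
        assert res.tau_mean == pytest.approx(0.75, abs=0.03)
        assert np.all((res.tau_samples > 0) & (res.tau_samples < 1))

    def test_sign_agreement_with_one_param_model(self, fast_config, rng):
        part = IntervalPartition.equal(300)
        agree = 0
        cases = [(-3.0, 400), (-1.5, 300), (1.5, 300), (3.0, 400), (2.0, 150),
                 (-2.0, 150)]
        for a_true, n_tot in cases:
            nv = simulate_counts(part, a_true, n_tot, seed=rng)
            one = sample_posterior(nv, part, fast_config)
            two = fit_two_param(nv, part, fast_config)
            agree += int(np.sign(one.activity) == np.sign(two.activity))
        assert agree == len(cases)


class TestSimulation:
    def test_fixed_seed_is_deterministic(self, equal_partition):
        n1 = simulate_counts(equal_partition, 1.0, 500, seed=7)
        n2 = simulate_counts(equal_partition, 1.0, 500, seed=7)
        assert np.array_equal(n1.counts, n2.counts)

    def test_null_frequencies_match_lengths(self, rng):
        lengths = rng.dirichlet(np.ones(20))
        part = IntervalPartition.from_lengths(lengths)
        nv = simulate_counts(part, 0.0, 100_000, seed=rng)
        chi2 = stats.chisquare(nv.counts, f_exp=100_000 * part.lengths)
        assert chi2.pvalue > 0.001

    def test_fair_split_expectation(self):
        part = IntervalPartition.from_lengths([0.5, 0.5])
        totals = [simulate_counts(part, 0.0, 10_000, seed=s).counts[0]
                  for s in range(20)]
        assert np.mean(totals) == pytest.approx(5000, abs=100)

    def test_negative_total_rejected(self, equal_partition):
        with pytest.raises(ValueError):
            simulate_counts(equal_partition, 0.0, -1)


class TestPPC:
    def test_self_consistent_data_lies_in_envelope(self, fast_config):
        part = IntervalPartition.equal(400)
        nv = simulate_counts(part, 1.0, 400, seed=2)
        post = sample_posterior(nv, part, fast_config)
        env = ppc_envelope(nv, part, post, draws=300, seed=4)
        assert env["inside_fraction"] > 0.8

    def test_mismatched_posterior_fails_envelope(self, equal_partition):
        nv = simulate_counts(equal_partition, 0.0, 800, seed=3)  # uniform data
        sharp = laplace_posterior(
            simulate_counts(equal_partition, 5.0, 2000, seed=4),
            equal_partition, ModelConfig())
        env = ppc_envelope(nv, equal_partition, sharp, draws=200, seed=5)
        assert env["inside_fraction"] < 0.2

    def test_zero_draws_rejected(self, equal_partition, fast_config):
        nv = simulate_counts(equal_partition, 0.0, 100, seed=1)
        post = sample_posterior(nv, equal_partition, fast_config)
        with pytest.raises(ValueError):
            ppc_envelope(nv, equal_partition, post, draws=0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"warmup": 3000, "iterations": 3000},
        {"chains": 0},
        {"prior_sd": 0.0},
        {"backend": "nuts"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)
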