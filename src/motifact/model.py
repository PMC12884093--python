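"""Bayesian activity model on ranked-sequence motif counts.

The generative model: a latent motif occurrence position k on the combined
unit interval follows Beta(alpha(a), beta(a)), where a is a real-valued
activity parameter,

    alpha(a) = 1 + a, beta(a) = 1        for a >= 0,
    alpha(a) = 1,     beta(a) = 1 - a    for a < 0,

so a = 0 recovers the uniform null Beta(1, 1). Counts per ranked sequence
are multinomial with cell probabilities given by the beta mass on each
sub-interval (exact incomplete-beta differences, or the step approximation
length x density-at-midpoint). The prior on a is Normal(0, 100).

Inference backends: a univariate slice sampler (asymptotically exact MCMC;
tuning-free for this one-dimensional, near-Gaussian posterior) and a Laplace
approximation at the posterior mode. The activity score is the signed log
posterior tail probability of the opposite-sign activity, offset by log 2 so
it is continuous (and zero) at a posterior mean of zero; tails use a normal
approximation of the posterior (Bernstein-von Mises), which keeps resolution
for highly active motifs where empirical tails underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from scipy import optimize, special, stats

from . import _fast
from .partition import IntervalPartition, MotifCountVector

__all__ = [
    "ModelConfig",
    "BetaShapes",
    "PosteriorResult",
    "TwoParamResult",
    "beta_shapes",
    "step_log_likelihood",
    "exact_log_likelihood",
    "log_posterior_kernel",
    "sample_posterior",
    "laplace_posterior",
    "activity_score",
    "posterior_summary",
    "log_marginal_likelihood",
    "log_bayes_factor",
    "fit_two_param",
    "simulate_counts",
    "ppc_envelope",
]


@dataclass
class ModelConfig:
    """Inference settings (prior, sampler, backend)."""

    prior_mean: float = 0.0
    prior_sd: float = 10.0  # variance 100
    chains: int = 3
    iterations: int = 3000
    warmup: int = 500
    seed: int = 0
    use_exact_likelihood: bool = False
    backend: str = "mcmc"  # "mcmc" | "laplace"
    ci_level: float = 0.99
    compute_bf: bool = False

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.backend not in ("mcmc", "laplace"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True)
class BetaShapes:
    alpha: float
    beta: float


def beta_shapes(a: float) -> BetaShapes:
    """Map the activity parameter to Beta shape parameters.

    a >= 0 -> (1 + a, 1); a < 0 -> (1, 1 - a); a = 0 gives the uniform
    Beta(1, 1) null.
    """
    if not np.isfinite(a):
        raise ValueError("activity parameter must be finite")
    if a >= 0:
        return BetaShapes(alpha=1.0 + a, beta=1.0)
    return BetaShapes(alpha=1.0, beta=1.0 - a)


@dataclass
class PosteriorResult:
    """Posterior summary of the activity parameter for one fit."""

    mean: float
    sd: float
    ci: Tuple[float, float]
    ci_level: float
    activity: float
    backend_used: str
    samples: Optional[np.ndarray] = None  # (chains, draws) post-warmup
    rhat: float = math.nan
    ess: float = math.nan
    log_bf10: Optional[float] = None
    diagnostics: Dict = field(default_factory=dict)


@dataclass
class TwoParamResult:
    """Posterior of the free (alpha, beta) model via the beta mean tau."""

    alpha_samples: np.ndarray  # (chains, draws)
    beta_samples: np.ndarray
    tau_samples: np.ndarray
    tau_mean: float
    tau_sd: float
    activity: float
    rhat: float = math.nan
    ess: float = math.nan


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


class StepLikelihood:
    """Step-function log-likelihood with precomputed sufficient statistics.

    Precomputes sum_s n_s log l_s, sum_s n_s log r_s and
    sum_s n_s log(1 - r_s) once per (counts, partition), so each evaluation
    costs one log-sum-exp over the normalization term only.
    """

    def __init__(self, counts: MotifCountVector, part: IntervalPartition):
        if len(counts) != len(part):
            raise ValueError(
                f"counts ({len(counts)}) and partition ({len(part)}) misaligned"
            )
        n = counts.counts.astype(float)
        self.n_total = counts.total
        self.log_l = np.ascontiguousarray(np.log(part.lengths))
        self.log_r = np.ascontiguousarray(np.log(part.midpoints))
        self.log_1mr = np.ascontiguousarray(np.log1p(-part.midpoints))
        self.const = float(n @ self.log_l)  # sum n_s log l_s, precomputed
        self.sum_n_log_r = float(n @ self.log_r)
        self.sum_n_log_1mr = float(n @ self.log_1mr)

    @property
    def _args(self):
        return (self.log_l, self.log_r, self.log_1mr, self.const,
                self.sum_n_log_r, self.sum_n_log_1mr, self.n_total)

    def __call__(self, a: float, normalize: bool = True) -> float:
        if self.n_total == 0:
            return 0.0
        if normalize:
            return float(_fast.step_loglik(float(a), *self._args))
        if a >= 0:
            return self.const + a * self.sum_n_log_r + self.n_total * math.log1p(a)
        return (self.const + (-a) * self.sum_n_log_1mr
                + self.n_total * math.log1p(-a))


def step_log_likelihood(
    counts: MotifCountVector,
    part: IntervalPartition,
    a: float,
    normalize: bool = True,
) -> float:
    """Log-likelihood under the step (midpoint) approximation.

    With ``normalize`` the multinomial cell probabilities
    l_s f(r_s; a) / sum_t l_t f(r_t; a) are proper for every a; without it,
    the proportional product form is returned.
    """
    return StepLikelihood(counts, part)(float(a), normalize=normalize)


def exact_cell_probabilities(part: IntervalPartition, a: float) -> np.ndarray:
    """Exact multinomial cell probabilities: incomplete-beta differences."""
    sh = beta_shapes(a)
    cdf = special.betainc(sh.alpha, sh.beta, part.boundaries)
    p = np.diff(cdf)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def exact_log_likelihood(
    counts: MotifCountVector, part: IntervalPartition, a: float
) -> float:
    """Exact log-likelihood using beta-CDF integrals per sub-interval."""
    if len(counts) != len(part):
        raise ValueError("counts and partition misaligned")
    if counts.total == 0:
        return 0.0
    p = exact_cell_probabilities(part, float(a))
    n = counts.counts
    nz = n > 0
    if np.any(p[nz] == 0):
        return -math.inf
    return float(n[nz] @ np.log(p[nz]))


def _prior_logpdf(a: float, config: ModelConfig) -> float:
    z = (a - config.prior_mean) / config.prior_sd
    return -0.5 * z * z - math.log(config.prior_sd) - 0.5 * math.log(2 * math.pi)


def make_kernel(
    counts: MotifCountVector, part: IntervalPartition, config: ModelConfig
) -> Callable[[float], float]:
    """Unnormalized log-posterior log P(n|a) + log P(a) as a closure."""
    if config.use_exact_likelihood:
        def kernel(a: float) -> float:
            return exact_log_likelihood(counts, part, a) + _prior_logpdf(a, config)
        return kernel
    lik = StepLikelihood(counts, part)

    def kernel(a: float) -> float:
        return lik(a) + _prior_logpdf(a, config)

    return kernel


def log_posterior_kernel(
    counts: MotifCountVector, part: IntervalPartition, a: float, config: ModelConfig
) -> float:
    """Evaluate the unnormalized log posterior at a single point."""
    return make_kernel(counts, part, config)(float(a))


# ---------------------------------------------------------------------------
# Scores and summaries
# ---------------------------------------------------------------------------


def activity_score(mean: float, sd: float) -> float:
    """Signed log posterior tail probability of the opposite-sign activity.

    Computed from a Normal(mean, sd^2) approximation in log space; the log 2
    offset makes the score continuous (zero) at mean = 0. Positive scores
    indicate motif clustering among down-regulated sequences.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if mean == 0:
        return 0.0
    log_tail = stats.norm.logcdf(-abs(mean) / sd)
    return float(np.sign(mean) * (-log_tail - math.log(2.0)))


def empirical_activity_score(samples: np.ndarray) -> float:
    """Activity score from empirical (rather than normal-approximate) tails.

    Diagnostic alternative to :func:`activity_score`: the opposite-sign tail
    probability is the fraction of pooled draws beyond 0, floored at 1/n
    (an empirical tail cannot resolve probabilities below one draw, which
    is why the normal approximation is the default).
    """
    pooled = np.asarray(samples, dtype=float).ravel()
    if pooled.size < 2:
        raise ValueError("need at least 2 draws")
    mean = pooled.mean()
    if mean == 0:
        return 0.0
    opposite = (pooled <= 0) if mean > 0 else (pooled >= 0)
    tail = max(opposite.mean(), 1.0 / pooled.size)
    return float(np.sign(mean) * (-math.log(tail) - math.log(2.0)))


def posterior_summary(
    samples: np.ndarray, level: float = 0.99
) -> Tuple[float, float, Tuple[float, float], float, float]:
    """Pooled mean/sd, equal-tailed CI, split R-hat and bulk ESS.

    ``samples`` has shape (chains, draws). CI uses linear-interpolation
    empirical quantiles of the pooled draws. R-hat is the rank-normalized
    split statistic; with a single chain it is reported as NaN.
    """
    import arviz as az

    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size < 4:
        raise ValueError("need at least 4 draws")
    pooled = samples.ravel()
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(pooled, [alpha, 1.0 - alpha])
    if samples.shape[0] >= 2:
        rhat = float(az.rhat(samples, method="rank"))
    else:
        rhat = math.nan
    ess = float(az.ess(samples, method="bulk"))
    return mean, sd, (float(lo), float(hi)), rhat, ess


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def _slice_chain(
    kernel: Callable[[float], float],
    x0: float,
    n_iter: int,
    rng: np.random.Generator,
    w: float = 2.5,
    max_stepout: int = 200,
) -> np.ndarray:
    """Univariate slice sampling with stepping-out and shrinkage."""
    x = float(x0)
    lp = kernel(x)
    if not np.isfinite(lp):
        x = 0.0
        lp = kernel(x)
    out = np.empty(n_iter)
    for i in range(n_iter):
        log_y = lp + math.log(rng.random())
        u = rng.random()
        left = x - w * u
        right = left + w
        j = 0
        while kernel(left) > log_y and j < max_stepout:
            left -= w
            j += 1
        j = 0
        while kernel(right) > log_y and j < max_stepout:
            right += w
            j += 1
        while True:
            x_new = rng.uniform(left, right)
            lp_new = kernel(x_new)
            if lp_new > log_y:
                x, lp = x_new, lp_new
                break
            if x_new < x:
                left = x_new
            else:
                right = x_new
        out[i] = x
    return out


def _chain_rngs(config: ModelConfig, n: int) -> list:
    """Deterministic per-chain generators from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]


def sample_posterior(
    counts: MotifCountVector, part: IntervalPartition, config: ModelConfig
) -> PosteriorResult:
    """MCMC posterior of the activity parameter (slice sampler).

    Runs ``config.chains`` independent chains for ``config.iterations``
    draws each, discards ``config.warmup``, pools the rest, and fills the
    summary, convergence diagnostics (split R-hat, bulk ESS) and the
    activity score. Reproducible for a fixed ``config.seed``.
    """
    n_keep = config.iterations - config.warmup
    draws = np.empty((config.chains, n_keep))
    if _fast.HAVE_NUMBA and not config.use_exact_likelihood:
        lik = StepLikelihood(counts, part)
        seeds = np.random.SeedSequence(config.seed).generate_state(config.chains)
        for c in range(config.chains):
            chain = _fast.slice_chain_1p(
                int(seeds[c]), config.iterations, 2.5, 200, *lik._args,
                config.prior_mean, config.prior_sd,
            )
            draws[c] = chain[config.warmup:]
    else:
        kernel = make_kernel(counts, part, config)
        rngs = _chain_rngs(config, config.chains)
        for c, rng in enumerate(rngs):
            x0 = float(rng.normal(0.0, 2.0))  # overdispersed chain inits
            chain = _slice_chain(kernel, x0, config.iterations, rng)
            draws[c] = chain[config.warmup:]
    mean, sd, ci, rhat, ess = posterior_summary(draws, level=config.ci_level)
    diagnostics = {"converged": (math.isnan(rhat) or rhat < 1.05)}
    result = PosteriorResult(
        mean=mean,
        sd=sd,
        ci=ci,
        ci_level=config.ci_level,
        activity=activity_score(mean, sd),
        backend_used="mcmc",
        samples=draws,
        rhat=rhat,
        ess=ess,
        diagnostics=diagnostics,
    )
    if config.compute_bf:
        result.log_bf10 = log_bayes_factor(counts, part, config)
    return result


def laplace_posterior(
    counts: MotifCountVector, part: IntervalPartition, config: ModelConfig
) -> PosteriorResult:
    """Laplace approximation: posterior mode and curvature-based sd.

    Faster than MCMC at the expense of less accurate uncertainty; sampling
    diagnostics are not applicable and reported as NaN.
    """
    kernel = make_kernel(counts, part, config)
    res = optimize.minimize_scalar(
        lambda a: -kernel(a), bounds=(-200.0, 200.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"Laplace mode search failed: {res.message}")
    mode = float(res.x)
    h = 1e-4 * max(1.0, abs(mode))
    d2 = (kernel(mode + h) - 2.0 * kernel(mode) + kernel(mode - h)) / (h * h)
    if d2 >= 0:
        raise RuntimeError("non-concave kernel at mode; Laplace approximation failed")
    sd = float(1.0 / math.sqrt(-d2))
    z = stats.norm.ppf(1.0 - (1.0 - config.ci_level) / 2.0)
    result = PosteriorResult(
        mean=mode,
        sd=sd,
        ci=(mode - z * sd, mode + z * sd),
        ci_level=config.ci_level,
        activity=activity_score(mode, sd),
        backend_used="laplace",
        samples=None,
        diagnostics={"mode_neg_curvature": -d2},
    )
    if config.compute_bf:
        result.log_bf10 = log_bayes_factor(counts, part, config)
    return result


def fit_activity(
    counts: MotifCountVector, part: IntervalPartition, config: ModelConfig
) -> PosteriorResult:
    """Dispatch to the configured backend (``mcmc`` or ``laplace``)."""
    if config.backend == "laplace":
        return laplace_posterior(counts, part, config)
    return sample_posterior(counts, part, config)


# ---------------------------------------------------------------------------
# Marginal likelihood and Bayes factor
# ---------------------------------------------------------------------------


def log_marginal_likelihood(
    counts: MotifCountVector,
    part: IntervalPartition,
    config: ModelConfig,
    method: str = "quadrature",
    posterior: Optional[PosteriorResult] = None,
) -> float:
    """log P(n | M1) = log integral of P(n|a) N(a; 0, 100) da.

    ``quadrature`` (default) integrates the one-dimensional kernel
    adaptively in log space and is treated as exact. ``bridge`` implements
    iterative bridge sampling from posterior draws with a normal proposal.
    """
    if counts.total == 0:
        return 0.0
    kernel = make_kernel(counts, part, config)
    if method == "quadrature":
        lap = laplace_posterior(counts, part, config)
        k0 = kernel(lap.mean)
        lo = min(lap.mean - 12 * lap.sd, -8 * config.prior_sd)
        hi = max(lap.mean + 12 * lap.sd, 8 * config.prior_sd)
        val, _ = _quad_exp(kernel, k0, lo, hi, points=(0.0, lap.mean))
        return float(math.log(val) + k0)
    if method == "bridge":
        if posterior is None or posterior.samples is None:
            posterior = sample_posterior(counts, part, config)
        return _bridge_sample(kernel, posterior.samples.ravel(), config)
    raise ValueError(f"unknown marginal-likelihood method {method!r}")


def _quad_exp(kernel, k0, lo, hi, points=()):
    from scipy.integrate import quad

    pts = sorted(p for p in points if lo < p < hi)
    val, err = quad(
        lambda a: math.exp(kernel(a) - k0), lo, hi, points=pts or None, limit=200
    )
    if val <= 0:
        raise RuntimeError("quadrature of the posterior kernel collapsed to zero")
    return val, err


def _bridge_sample(
    kernel: Callable[[float], float],
    post_draws: np.ndarray,
    config: ModelConfig,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """Iterative (optimal-bridge) estimate of the log marginal likelihood."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed + 1)))
    n1 = post_draws.size
    n2 = n1
    mu, s = float(post_draws.mean()), float(post_draws.std(ddof=1))
    prop = rng.normal(mu, s, size=n2)
    log_q1 = np.array([kernel(a) for a in post_draws])
    log_q2 = np.array([kernel(a) for a in prop])
    log_g1 = stats.norm.logpdf(post_draws, mu, s)
    log_g2 = stats.norm.logpdf(prop, mu, s)
    l1 = log_q1 - log_g1
    l2 = log_q2 - log_g2
    lstar = float(np.median(l1))
    q1 = np.exp(l1 - lstar)
    q2 = np.exp(l2 - lstar)
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    r = 1.0
    for _ in range(max_iter):
        num = np.mean(q2 / (s1 * q2 + s2 * r))
        den = np.mean(1.0 / (s1 * q1 + s2 * r))
        r_new = num / den
        if not np.isfinite(r_new) or r_new <= 0:
            raise RuntimeError("bridge sampling iteration diverged")
        if abs(math.log(r_new) - math.log(r)) < tol:
            return math.log(r_new) + lstar
        r = r_new
    raise RuntimeError("bridge sampling did not converge")


def log_bayes_factor(
    counts: MotifCountVector,
    part: IntervalPartition,
    config: ModelConfig,
    method: str = "quadrature",
    posterior: Optional[PosteriorResult] = None,
) -> float:
    """log BF10: activity model marginal minus null (a = 0) log-likelihood."""
    if counts.total == 0:
        return 0.0
    log_m1 = log_marginal_likelihood(counts, part, config, method=method,
                                     posterior=posterior)
    if config.use_exact_likelihood:
        log_m0 = exact_log_likelihood(counts, part, 0.0)
    else:
        log_m0 = step_log_likelihood(counts, part, 0.0)
    return float(log_m1 - log_m0)


# ---------------------------------------------------------------------------
# Two-parameter (free alpha, beta) variant
# ---------------------------------------------------------------------------


class _TwoParamKernel:
    """Log posterior in (log alpha, log beta) with Normal(0,1) priors."""

    def __init__(self, counts: MotifCountVector, part: IntervalPartition):
        self.lik = StepLikelihood(counts, part)

    def __call__(self, log_alpha: float, log_beta: float) -> float:
        lik = self.lik
        if lik.n_total == 0:
            data = 0.0
        else:
            alpha = math.exp(log_alpha)
            beta = math.exp(log_beta)
            data = (
                lik.const
                + (alpha - 1.0) * lik.sum_n_log_r
                + (beta - 1.0) * lik.sum_n_log_1mr
                - lik.n_total
                * special.logsumexp(
                    lik.log_l + (alpha - 1.0) * lik.log_r + (beta - 1.0) * lik.log_1mr
                )
            )
        return data - 0.5 * (log_alpha**2 + log_beta**2)


def fit_two_param(
    counts: MotifCountVector, part: IntervalPartition, config: ModelConfig
) -> TwoParamResult:
    """Fit the flexible model with free Beta shapes (slice-within-Gibbs).

    The activity is scored on the posterior of the beta mean
    tau = alpha / (alpha + beta) relative to the interval midpoint 0.5,
    mirroring the one-parameter tail treatment.
    """
    n_keep = config.iterations - config.warmup
    la = np.empty((config.chains, n_keep))
    lb = np.empty((config.chains, n_keep))
    if _fast.HAVE_NUMBA:
        lik = StepLikelihood(counts, part)
        seeds = np.random.SeedSequence(config.seed).generate_state(config.chains)
        for c in range(config.chains):
            la[c], lb[c] = _fast.slice_chain_2p(
                int(seeds[c]), config.iterations, config.warmup, 1.0, 100,
                *lik._args,
            )
    else:
        kern = _TwoParamKernel(counts, part)
        rngs = _chain_rngs(config, config.chains)
        for c, rng in enumerate(rngs):
            x = float(rng.normal(0.0, 0.5))
            y = float(rng.normal(0.0, 0.5))
            keep = 0
            for it in range(config.iterations):
                x = _slice_update(lambda v: kern(v, y), x, rng)
                y = _slice_update(lambda v: kern(x, v), y, rng)
                if it >= config.warmup:
                    la[c, keep] = x
                    lb[c, keep] = y
                    keep += 1
    alpha = np.exp(la)
    beta = np.exp(lb)
    tau = alpha / (alpha + beta)
    tau_mean, tau_sd, _, rhat, ess = posterior_summary(tau, level=config.ci_level)
    act = activity_score(tau_mean - 0.5, tau_sd) if tau_sd > 0 else 0.0
    return TwoParamResult(
        alpha_samples=alpha,
        beta_samples=beta,
        tau_samples=tau,
        tau_mean=tau_mean,
        tau_sd=tau_sd,
        activity=act,
        rhat=rhat,
        ess=ess,
    )


def _slice_update(
    kernel: Callable[[float], float], x: float, rng: np.random.Generator,
    w: float = 1.0, max_stepout: int = 100,
) -> float:
    """One slice-sampling update of a single coordinate."""
    lp = kernel(x)
    log_y = lp + math.log(rng.random())
    u = rng.random()
    left = x - w * u
    right = left + w
    j = 0
    while kernel(left) > log_y and j < max_stepout:
        left -= w
        j += 1
    j = 0
    while kernel(right) > log_y and j < max_stepout:
        right += w
        j += 1
    while True:
        x_new = rng.uniform(left, right)
        if kernel(x_new) > log_y:
            return x_new
        if x_new < x:
            left = x_new
        else:
            right = x_new


# ---------------------------------------------------------------------------
# Generative simulation and predictive checks
# ---------------------------------------------------------------------------


def simulate_counts(
    part: IntervalPartition,
    a: float,
    n_total: int,
    seed=None,
) -> MotifCountVector:
    """Draw counts from the generative model at activity ``a``.

    Cell probabilities are exact incomplete-beta differences; counts are a
    single multinomial draw of size ``n_total``. ``seed`` may be an int,
    SeedSequence, or Generator.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = exact_cell_probabilities(part, float(a))
    return MotifCountVector(counts=rng.multinomial(n_total, p))


def ppc_envelope(
    n_obs: MotifCountVector,
    part: IntervalPartition,
    posterior: PosteriorResult,
    draws: int = 200,
    seed=None,
    band: float = 0.95,
) -> Dict:
    """Posterior predictive envelope of the cumulative motif distribution.

    For each posterior draw of a, counts are simulated and their cumulative
    distribution over [0, 1] recorded at the partition boundaries; the
    pointwise central ``band`` envelope is compared with the observed curve.

    Returns a dict with the boundary grid, envelope quantiles, the observed
    cumulative curve, and ``inside_fraction`` (share of positions where the
    observed curve lies inside the envelope).
    """
    if draws <= 0:
        raise ValueError("draws must be positive")
    if n_obs.total == 0:
        raise ValueError("cannot form a cumulative distribution from zero counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if posterior.samples is not None:
        pool = posterior.samples.ravel()
        a_draws = rng.choice(pool, size=draws, replace=True)
    else:
        # Laplace backend: draw from the normal approximation
        a_draws = rng.normal(posterior.mean, posterior.sd, size=draws)
    total = n_obs.total
    cum = np.empty((draws, len(part)))
    for i, a in enumerate(a_draws):
        sim = simulate_counts(part, float(a), total, seed=rng)
        cum[i] = np.cumsum(sim.counts) / total
    lo_q = (1.0 - band) / 2.0
    lo, hi = np.quantile(cum, [lo_q, 1.0 - lo_q], axis=0)
    obs = np.cumsum(n_obs.counts) / total
    inside = float(np.mean((obs >= lo) & (obs <= hi)))
    return {
        "grid": part.boundaries[1:],
        "lower": lo,
        "upper": hi,
        "observed": obs,
        "inside_fraction": inside,
        "band": band,
    }
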