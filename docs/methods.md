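# Methods

## Model

Let `S_1..S_N` be the sequences of one condition, ranked by decreasing
fold-change score. Each sequence occupies a sub-interval of [0, 1] with
length `l_s ∝ SSP_s`, its sequence-specific probability of containing the
motif, so that sequence length and base composition are factored out: under
the null, a motif occurrence falls uniformly on [0, 1], and the count
vector is `n | n_m ~ Multinom(n_m, l)`.

Activity is a real parameter `a` mapped to Beta shapes
`α = 1 + max(a, 0)`, `β = 1 + max(−a, 0)`; the occurrence position follows
`Beta(α, β)` (a = 0 recovers Beta(1,1) = Unif(0,1); a > 0 concentrates
occurrences among down-regulated sequences, the repressor signature).
Counts are multinomial with cell probabilities equal to the beta mass on
each sub-interval:

- **exact**: `p_s = I(b_s; α, β) − I(b_{s−1}; α, β)` (regularized
  incomplete beta at the interval boundaries);
- **step approximation** (default): `p_s ≈ l_s · f(r_s; a)` at the interval
  midpoint `r_s`, renormalized over s. Because the beta density here is a
  pure power of `r` or `1 − r`, the log-likelihood reduces to three
  precomputed sufficient statistics (`Σ n_s log l_s`, `Σ n_s log r_s`,
  `Σ n_s log(1−r_s)`) plus one log-sum-exp for the normalizer per
  evaluation. We include the normalizer by default: it depends on `a`
  (though not on `n`), and omitting it would distort both the posterior and
  any marginal likelihood. The unnormalized product form is available via
  `normalize=False` for inspection.

The prior is `a ~ N(0, 100)`. The posterior is one-dimensional and, by
Bernstein–von Mises, close to Gaussian for informative data.

### Activity score

`activity = sgn(ā) · (−log P(a on the opposite side of 0 | n) − log 2)`,
with the tail computed from a Normal(ā, sd²) approximation of the posterior
through the log survival function (stable to |ā|/sd ≈ 40, i.e. scores of
~800 before any underflow). The `log 2` offset makes the score continuous
and zero at ā = 0. The sign convention makes repressor-like activity
(occurrences among down-regulated genes) positive; empirical-tail scoring
is intentionally not the default because MCMC cannot resolve tail
probabilities below ~1/draws.

### Inference backends

- **MCMC** (default): univariate slice sampling (stepping-out width 2.5,
  shrinkage), 3 chains × 3000 iterations with 500 warm-up discarded,
  overdispersed N(0, 2²) chain initializations. Slice sampling was chosen
  over gradient-based samplers because the parameter is one-dimensional and
  the kernel has a derivative kink at a = 0 (the α/β switch), which a
  tuning-free, rejection-free sampler handles without divergences. Chains
  are seeded from independent `SeedSequence` spawns of the master seed.
  Diagnostics: rank-normalized split R-hat and bulk ESS (arviz).
- **Laplace**: bounded 1-D mode search on the kernel, curvature by central
  finite differences (h = 10⁻⁴·max(1, |mode|)), sd = (−k″)^(−1/2). With no
  data the Gaussian prior is recovered exactly. When the mode sits exactly
  at the a = 0 kink the quadratic approximation averages the one-sided
  curvatures; this only occurs for near-null data where both backends agree
  the score is ≈ 0.

Per-(condition, motif) work-unit seeds in the screening pipeline are
spawned deterministically from the run seed by unit index, so results are
bit-identical regardless of worker count or scheduling.

### Bayes factor

`log BF₁₀ = log ∫ P(n|a) N(a; 0, 100) da − log P(n|a=0)`. The integral is
computed by adaptive quadrature over the Laplace-located mode (deterministic
and effectively exact in 1-D; the default and the oracle) or by iterative
optimal bridge sampling from posterior draws with a moment-matched normal
proposal (retained for fidelity; cross-validated against quadrature to
|Δ| < 0.1 in the tests).

### Two-parameter variant

`(log α, log β)` are sampled by slice-within-Gibbs with independent
N(0, 1) priors (weakly informative around Beta(1,1); the model itself does
not identify a scale prior, so this is a design choice). Activity is scored
on τ = α/(α+β) against 0.5 using the same normal-tail treatment.

## Preprocessing

- **log₂ pseudo-TPM**: per condition j, `y_ij = log₂(x_ij / L_j · M + 1)`
  with `L_j` the library size and `M = median_j L_j`. The rescale factor is
  the *median library size* rather than the per-condition median entry: the
  latter is 0 for sparse single-cell data and would destroy the transform;
  it remains available via `scale="median_entry"`. The pseudocount (+1)
  handles zeros and is configurable. Scaling a condition by a constant
  leaves its output unchanged as long as the median library is not
  reordered (M itself is data-dependent).
- **Fold change**: `fc = y − control`, with the pseudo-normal control
  (per-gene median across conditions) as default.
- **Ranking**: descending fold change, ties broken stably by input order
  (deterministic; the convention is otherwise arbitrary).
- **Sequence filters**: 3' UTRs with length in [20, 10000] nt (inclusive),
  longest isoform per gene, U→T, first whitespace-delimited header token as
  gene id (regex override available). Ambiguous bases are normalized to N,
  excluded from composition counts, and never match a motif.

## SSP (sequence-specific probability)

The motif (plain k-mer or finite regular expression: literals, `.`,
character classes, alternation, grouping; unbounded quantifiers rejected)
is expanded to its word set and compiled to an Aho–Corasick automaton whose
match states are collapsed into one absorbing state. Under the sequence's
i.i.d. composition the chain's transition matrix is raised to the sequence
length (binary powering); the absorbed mass is P(≥ 1 occurrence). This is
the default meaning of `l_s`. An `expected_count` mode
(`Σ_words (L−k+1)·Π p_base`) is exposed as an alternative because the
expected count and the occurrence probability diverge for high-probability
motifs; the occurrence-probability definition is the default since it is
what the absorbing-chain construction defines and stays in [0, 1]. The SSP
is validated against exact weighted enumeration of all 4^L sequences for
L ≤ 8.

## Damping thresholds

The partition floor `l_floor = 10⁻⁶` (sub-intervals below it are raised,
then the vector is renormalized once) and the per-sequence count cap
`n_cap = 2` damp the influence of individual sequences. Both are read as
damping rather than sequence exclusion; flooring is applied once — a fixed
point iteration would change values by < l_floor·N and is unnecessary at
the defaults. The floor guarantees midpoints strictly inside (0, 1), which
the step likelihood requires.

## Synthetic data generator

`generate_synthetic_dataset` emulates the intended use: i.i.d. sequences
(default composition mildly AT-rich: A 0.29, C 0.21, G 0.20, T 0.30,
typical of 3' UTRs; lengths uniform in 100–2000 nt), log-normal baseline
expression (log-mean 5, log-sd 1.5; condition noise log-sd 0.25), an active
motif planted into 25% of genes, and a multiplicative repression factor
(default 0.25) applied to motif genes in active conditions. Ground-truth
activity is thus coupled to expression through ranking — the whole pipeline
is exercised — while `simulate_counts` covers the model in isolation.
What the generator does **not** emulate: UMI chemistry, cell-type
structure, batch effects, 3' UTR isoform complexity, or correlated motif
co-occurrence; passing tests demonstrate method correctness under the
stated generative assumptions, not performance on any real dataset. Note
that when exactly half the conditions are active, the pseudo-normal control
falls midway between regimes and inactive conditions mirror the signal with
negative activity; sign-recovery checks therefore plant a minority of
active conditions.

`downsample_counts` emulates single-cell sparsity by multinomial resampling
of each condition to a fixed library size with probabilities proportional
to expression.

## Permutation null

For an activity matrix over all candidate motifs and a regulator expression
matrix, random motif-to-regulator assignments (without replacement, drawn
from motifs that are not true targets) generate null distributions of the
mean and 90th percentile of per-regulator Pearson and Spearman correlations
(Spearman uses average ranks for ties). The observed statistics are
compared with the empirical 99th percentile; both summaries are reported
rather than privileging one. Internally the regulator × candidate
correlation matrices are precomputed once, so each permutation is a gather.

## Problem sizes used in validation

The backend-agreement battery uses 200 fits on a 1000-interval equal
partition with activities uniform in [−4, 4] and totals log-uniform in
[20, 2000]. Posterior-moment and marginal-likelihood cross-checks use
20 and 10 instances on 500- and 300-interval partitions; parameter-recovery
and CI-coverage checks use 100 replicates at N = 2000 intervals and 2000
occurrences; recovery bias is measured on the deterministic quadrature
posterior mean (the same oracle used to validate the sampler's moments).
These sizes give stable statistics while keeping the validation suite a
desk-scale computation.

## Known limitations

- Activities are fit independently per (condition, motif); no hierarchical
  sharing across cells or conditions.
- Ranking uncertainty is ignored: the fold-change ordering enters as data.
- The step approximation degrades for very coarse partitions (N in the
  tens) combined with extreme |a|; the exact likelihood is available via
  `use_exact_likelihood` at higher cost.
- The restricted regex subset excludes unbounded repetition by design
  (the absorbing-chain construction requires a finite word set here).
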