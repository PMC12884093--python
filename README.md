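# motifact

Bayesian inference of condition-specific regulatory-motif activity from
expression-ranked sequence lists — e.g., microRNA target repression read out
of bulk or single-cell RNA-seq plus 3' UTR sequences.

## The problem and the model

A regulator (such as a miRNA) typically represses many target transcripts
that share a short sequence motif (for miRNAs, the reverse complement of
seed positions 2–8). When the regulator is active in a condition, its
motif-bearing transcripts sink toward the down-regulated end of the
condition's fold-change–ranked gene list. `motifact` quantifies this signal
with a generative model:

- Genes are ranked per condition by fold-change score (log₂ pseudo-TPM
  expression minus a pseudo-normal control — each gene's median across
  conditions).
- Ranked sequences are laid out on [0, 1] as sub-intervals with lengths
  `l_s` proportional to each sequence's probability of containing the motif
  (SSP), computed from an absorbing Markov chain over the motif automaton
  under the sequence's length and nucleotide composition. Under the null,
  motif occurrences are then uniform on [0, 1].
- A latent occurrence position follows Beta(α(a), β(a)) with
  α(a) = 1 + max(a, 0), β(a) = 1 + max(−a, 0), so the activity parameter
  a ∈ ℝ tilts occurrences toward the top (a < 0) or bottom (a > 0) of the
  ranking; a = 0 is the uniform null. Observed per-sequence counts `n_s`
  are multinomial with cell probabilities given by the beta mass per
  sub-interval (or the step approximation `l_s · f(r_s; a)` at midpoints
  `r_s`).
- With prior a ~ N(0, 100), the posterior is explored by MCMC (slice
  sampling, 3 chains × 3000 iterations, 500 warm-up) or a Laplace
  approximation. The reported **activity score** is the signed log
  posterior tail probability of the opposite-sign activity,
  `sgn(ā) · (−log P(sign flip) − log 2)`, computed from a normal
  approximation of the posterior; Bayes factors against the a = 0 null are
  available by 1-D quadrature or bridge sampling, and a two-parameter
  variant with free Beta shapes scores the posterior of the beta mean
  τ = α/(α+β) against 0.5.

## Worked example

Generate a synthetic dataset with one planted repressor motif (`ACACTCC`,
the miR-122-5p target site) active in the first half of 6 conditions, and
screen it:

```
motifact fixtures --out demo --n-genes 400 --n-conditions 6 --seed 7
motifact run --expression demo/expression.tsv --fasta demo/utrs.fa \
             --motifs demo/motifs.txt --out demo/run --seed 1
cat demo/run/summary.tsv
```

```
condition  motif    status  mean      sd        ci_low    ci_high   activity  rhat      ess
c00        ACACTCC  ok      2.4979    0.32516   1.71728   3.33937   31.7881   1.00046   6960.93
c01        ACACTCC  ok      3.52898   0.417317  2.52097   4.66742   38.1292   1.00064   7729.42
c02        ACACTCC  ok      2.68134   0.342176  1.8882    3.63137   33.0028   1.00036   7370.11
c03        ACACTCC  ok      -2.86141  0.362178  -3.86349  -2.01141  -33.5176  0.999875  7240.98
c04        ACACTCC  ok      -3.06751  0.383876  -4.15617  -2.13786  -34.2464  1.00035   6767.74
c05        ACACTCC  ok      -3.03969  0.367283  -4.03596  -2.1668   -36.6007  1.00056   6727.13
```

In the repressed conditions (c00–c02) the posterior mean activity is
strongly positive (motif occurrences pile up among down-regulated genes)
with activity scores of 32–38 — log-scale evidence far beyond chance. This
fixture represses targets in exactly half the conditions, so the
pseudo-normal control sits midway between the two regimes and the inactive
conditions mirror the signal with negative scores (the motif looks enriched
among *up*-regulated genes relative to that control); with a minority of
active conditions, inactive conditions score near zero instead. R-hat ≈ 1
and ESS ≫ 1000 indicate clean sampling.

Other entry points: `motifact preprocess` (normalization + fold-change),
`motifact ssp` (gene × motif probability matrix), `motifact simulate`
(draws from the generative model), `motifact permute` (permutation null for
regulator–motif assignment). The same functionality is available as a
library (`motifact.fit_activity`, `motifact.run_activity_screen`, ...).

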