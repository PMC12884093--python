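"""Synthetic data with known ground truth, sparsity emulation, and nulls.

The end-to-end generator draws random i.i.d. UTR-like sequences, plants
active motifs into a fraction of them, and couples ground-truth activity to
expression by multiplying motif-bearing genes' expression by a repression
factor (< 1) in active conditions. This exercises the whole pipeline,
ranking included: repressed targets sink to the low-fold-change end of the
ranked list, which the model reads as positive activity.

Also here: multinomial downsampling of an expression matrix to a target
library size (emulating single-cell read sparsity) and the permutation null
for regulator-to-motif assignment (empirical 99th-percentile test of
expression-activity correlation summaries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .motifs import MotifSpec
from .sequences import SequenceRecord, SequenceSet

ALPHABET = "ACGT"

#: default composition: mildly AT-rich, as is typical of 3' UTRs
DEFAULT_COMPOSITION = (0.29, 0.21, 0.20, 0.30)


@dataclass
class ActiveMotif:
    """One planted ground-truth signal."""

    motif: str
    active_conditions: List[str]
    repression_factor: float = 0.25  # multiplies expression of motif genes
    planted_fraction: float = 0.25  # fraction of genes carrying the motif

    def __post_init__(self) -> None:
        if self.repression_factor <= 0:
            raise ValueError("repression_factor must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest for a generated dataset."""

    active_motifs: List[ActiveMotif] = field(default_factory=list)
    seed: int = 0
    motif_genes: Dict[str, List[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "active_motifs": [
                {
                    "motif": am.motif,
                    "active_conditions": am.active_conditions,
                    "repression_factor": am.repression_factor,
                    "planted_fraction": am.planted_fraction,
                }
                for am in self.active_motifs
            ],
            "motif_genes": self.motif_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_sequence(rng: np.random.Generator, length: int,
                     composition: Sequence[float]) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length, p=composition))


def generate_synthetic_dataset(
    n_genes: int = 1000,
    n_conditions: int = 12,
    utr_len_range: Tuple[int, int] = (100, 2000),
    composition: Sequence[float] = DEFAULT_COMPOSITION,
    truth: Optional[SyntheticTruth] = None,
    mean_log_expression: float = 5.0,
    sd_log_expression: float = 1.5,
    noise_sd: float = 0.25,
) -> Tuple[SequenceSet, ExpressionMatrix, SyntheticTruth]:
    """Generate sequences + expression with planted motif activities.

    Baseline expression is log-normal per gene (shared across conditions,
    plus condition-level log-normal noise). For each active motif, the motif
    is planted at a random position in ``planted_fraction`` of genes, and in
    the motif's active conditions those genes' expression is multiplied by
    ``repression_factor`` (< 1 emulates miRNA-guided target depletion and
    yields positive true activity).

    Deterministic for a fixed ``truth.seed``.
    """
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(truth.seed)
    lo, hi = utr_len_range
    for am in truth.active_motifs:
        if len(am.motif) > lo:
            raise ValueError(
                f"motif {am.motif!r} is longer than the minimum UTR length {lo}"
            )
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cond_ids = [f"c{j:02d}" for j in range(n_conditions)]
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    seqs = SequenceSet()
    raw = {g: _random_sequence(rng, int(L), composition)
           for g, L in zip(gene_ids, lengths)}
    # plant motifs at random positions
    truth.motif_genes = {}
    for am in truth.active_motifs:
        n_plant = max(1, int(round(am.planted_fraction * n_genes)))
        chosen = rng.choice(gene_ids, size=n_plant, replace=False)
        for g in chosen:
            seq = raw[g]
            pos = int(rng.integers(0, len(seq) - len(am.motif) + 1))
            raw[g] = seq[:pos] + am.motif + seq[pos + len(am.motif):]
        truth.motif_genes[am.motif] = sorted(map(str, chosen))
    for g in gene_ids:
        seqs.add(SequenceRecord(gene_id=g, sequence=raw[g]))
    # expression: per-gene baseline x per-(gene, condition) noise
    base = rng.lognormal(mean_log_expression, sd_log_expression, size=n_genes)
    noise = rng.lognormal(0.0, noise_sd, size=(n_genes, n_conditions))
    expr = base[:, None] * noise
    for am in truth.active_motifs:
        rows = [gene_ids.index(g) for g in truth.motif_genes[am.motif]]
        cols = [cond_ids.index(c) for c in am.active_conditions]
        for c in cols:
            expr[rows, c] *= am.repression_factor
    counts = np.round(expr).astype(np.int64)
    mat = ExpressionMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=cond_ids),
        is_log_scale=False,
    )
    return seqs, mat, truth


def downsample_counts(
    expr: ExpressionMatrix, target_library: int, seed=None
) -> ExpressionMatrix:
    """Multinomial downsampling of each condition to a fixed library size.

    Per condition, reads are resampled with probabilities proportional to
    the (RPKM-like) weights, emulating shallow single-cell sequencing; zero
    genes stay zero and column sums equal ``target_library`` exactly.
    """
    if target_library < 0:
        raise ValueError("target_library must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = expr.values.values.astype(float)
    if (vals < 0).any():
        raise ValueError("weights must be non-negative")
    out = np.zeros_like(vals, dtype=np.int64)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"condition {expr.condition_ids[j]!r} has zero total weight")
        out[:, j] = rng.multinomial(target_library, col / total)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=expr.gene_ids, columns=expr.condition_ids),
        is_log_scale=False,
    )


def correlation_summary(activity_row, expression_row) -> Tuple[float, float]:
    """Pearson and Spearman correlation of an activity and expression profile.

    Returns (NaN, NaN) when either vector is constant (zero variance is
    propagated, never silently zero).
    """
    x = np.asarray(activity_row, dtype=float)
    y = np.asarray(expression_row, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"))
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)  # average ranks for ties
    return pearson, spearman


def activity_backend_battery(
    n_fits: int = 200,
    n_intervals: int = 1000,
    activity_range: Tuple[float, float] = (-4.0, 4.0),
    n_total_range: Tuple[int, int] = (20, 2000),
    seed: int = 0,
    config=None,
) -> pd.DataFrame:
    """Synthetic battery comparing the MCMC and Laplace backends.

    Simulates ``n_fits`` count vectors on an equal partition with true
    activities uniform over ``activity_range`` and totals log-uniform over
    ``n_total_range``, then fits each with both backends. Returns one row
    per fit with true values, both activity scores, and MCMC diagnostics.
    """
    from .model import ModelConfig, laplace_posterior, sample_posterior
    from .partition import IntervalPartition

    if config is None:
        config = ModelConfig()
    part = IntervalPartition.equal(n_intervals)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = ss.generate_state(n_fits) % (2**31 - 1)
    rows = []
    from .model import simulate_counts

    lo, hi = n_total_range
    for i in range(n_fits):
        a_true = float(rng.uniform(*activity_range))
        n_total = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        counts = simulate_counts(part, a_true, n_total, seed=rng)
        cfg_i = ModelConfig(
            prior_mean=config.prior_mean, prior_sd=config.prior_sd,
            chains=config.chains, iterations=config.iterations,
            warmup=config.warmup, seed=int(fit_seeds[i]),
            ci_level=config.ci_level,
        )
        mcmc = sample_posterior(counts, part, cfg_i)
        lap = laplace_posterior(counts, part, cfg_i)
        rows.append({
            "a_true": a_true, "n_total": n_total,
            "mean_mcmc": mcmc.mean, "sd_mcmc": mcmc.sd,
            "activity_mcmc": mcmc.activity,
            "mean_laplace": lap.mean, "sd_laplace": lap.sd,
            "activity_laplace": lap.activity,
            "rhat": mcmc.rhat, "ess": mcmc.ess,
        })
    return pd.DataFrame(rows)


@dataclass
class PermutationNullResult:
    """Null distribution summaries for the motif-assignment permutation test."""

    null_stats: pd.DataFrame  # columns: pearson_mean, pearson_p90, spearman_mean, spearman_p90
    observed_stats: Dict[str, float]
    percentile_99: Dict[str, float]
    exceeds_99th: Dict[str, bool]
    n_perm: int


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, mat)


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise correlation matrix between rows of a and rows of b."""
    a = (a - a.mean(axis=1, keepdims=True))
    b = (b - b.mean(axis=1, keepdims=True))
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a @ b.T) / np.outer(sa, sb)


def permutation_null(
    activity: pd.DataFrame,  # motifs x conditions
    regulator_expression: pd.DataFrame,  # regulators x conditions
    true_assignment: Dict[str, str],  # regulator -> motif
    candidate_motifs: Sequence[str],
    n_perm: int = 10_000,
    seed=None,
) -> PermutationNullResult:
    """Permutation test of regulator-expression vs motif-activity correlation.

    Each permutation assigns a candidate motif's activity profile to each
    regulator without replacement, drawing from motifs *not* among the true
    targets; per-regulator Pearson and Spearman correlations are summarized
    by their mean and 90th percentile. The observed (true-assignment)
    statistics are compared with the empirical 99th percentile of the null;
    values above it are considered extremely surprising (significant).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    regulators = list(regulator_expression.index)
    true_motifs = {true_assignment[r] for r in regulators}
    pool = [m for m in candidate_motifs if m not in true_motifs]
    if len(pool) < len(regulators):
        raise ValueError(
            f"candidate pool ({len(pool)} motifs after excluding true targets) "
            f"is smaller than the number of regulators ({len(regulators)})"
        )
    conds = list(regulator_expression.columns)
    act = activity.loc[:, conds]
    expr_mat = regulator_expression.values.astype(float)
    pool_act = act.loc[pool].values.astype(float)
    true_act = act.loc[[true_assignment[r] for r in regulators]].values.astype(float)
    # precompute regulator x candidate correlation matrices; a permutation
    # then only gathers one entry per regulator
    pearson_rc = _row_corr(expr_mat, pool_act)
    spearman_rc = _row_corr(_rank_rows(expr_mat), _rank_rows(pool_act))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_reg = len(regulators)
    rows = np.arange(n_reg)
    records = np.empty((n_perm, 4))
    for t in range(n_perm):
        perm = rng.choice(len(pool), size=n_reg, replace=False)
        pc = pearson_rc[rows, perm]
        sc = spearman_rc[rows, perm]
        records[t] = (np.nanmean(pc), np.nanquantile(pc, 0.9),
                      np.nanmean(sc), np.nanquantile(sc, 0.9))
    cols = ["pearson_mean", "pearson_p90", "spearman_mean", "spearman_p90"]
    null_stats = pd.DataFrame(records, columns=cols)
    obs_p = np.array([correlation_summary(true_act[i], expr_mat[i])[0]
                      for i in range(n_reg)])
    obs_s = np.array([correlation_summary(true_act[i], expr_mat[i])[1]
                      for i in range(n_reg)])
    observed = {
        "pearson_mean": float(np.nanmean(obs_p)),
        "pearson_p90": float(np.nanquantile(obs_p, 0.9)),
        "spearman_mean": float(np.nanmean(obs_s)),
        "spearman_p90": float(np.nanquantile(obs_s, 0.9)),
    }
    p99 = {c: float(np.quantile(null_stats[c], 0.99)) for c in cols}
    exceeds = {c: bool(observed[c] > p99[c]) for c in cols}
    return PermutationNullResult(
        null_stats=null_stats,
        observed_stats=observed,
        percentile_99=p99,
        exceeds_99th=exceeds,
        n_perm=n_perm,
    )
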