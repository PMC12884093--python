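"""Orchestration of a full activity screen over (condition x motif) units.

Pipeline: expression normalization -> fold-change scoring against the
pseudo-normal control -> per-condition ranking -> per-(gene, motif) SSPs
(cached; condition independent) -> per-(condition, motif) partition/counts
-> Bayesian fit. Results are written as a wide activity matrix, a long
summary table, and a JSON run manifest. Fits are seeded per work unit, so
results are identical regardless of the number of workers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .expression import (
    ExpressionMatrix,
    align_to_sequences,
    fold_change_scores,
    log2_pseudo_tpm,
    rank_genes,
)
from .model import ModelConfig, fit_activity, log_bayes_factor
from .motifs import MotifSpec, count_motif_occurrences, motif_ssp
from .partition import build_count_vector, build_partition
from .sequences import SequenceSet, load_utr_fasta, nucleotide_composition

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one screening run."""

    expression_path: str = ""
    fasta_path: str = ""
    motif_path: str = ""
    output_dir: str = "motifact_out"
    # model settings
    prior_sd: float = 10.0
    chains: int = 3
    iterations: int = 3000
    warmup: int = 500
    seed: int = 0
    backend: str = "mcmc"
    compute_bf: bool = False
    # preprocessing
    pseudocount: float = 1.0
    already_log_scale: bool = False
    control_path: Optional[str] = None
    l_floor: float = 1e-6
    n_cap: int = 2
    ssp_mode: str = "at_least_one"
    workers: int = 1

    def model_config(self, seed: int) -> ModelConfig:
        return ModelConfig(
            prior_sd=self.prior_sd,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=seed,
            backend=self.backend,
        )


def _unit_seed(master: int, unit_index: int) -> int:
    """Deterministic per-unit seed independent of worker scheduling."""
    return int(np.random.SeedSequence(entropy=master,
                                      spawn_key=(unit_index,)).generate_state(1)[0]
               % (2**31 - 1))


def _fit_unit(condition, motif_pattern, counts, part, config, seed):
    mc = config.model_config(seed)
    try:
        res = fit_activity(counts, part, mc)
        row = {
            "condition": condition,
            "motif": motif_pattern,
            "status": "ok",
            "mean": res.mean,
            "sd": res.sd,
            "ci_low": res.ci[0],
            "ci_high": res.ci[1],
            "activity": res.activity,
            "rhat": res.rhat,
            "ess": res.ess,
        }
        if config.compute_bf:
            row["log_bf10"] = log_bayes_factor(counts, part, mc)
        return row
    except Exception as exc:  # fit failures are recorded, not fatal
        logger.warning("fit failed for (%s, %s): %s", condition, motif_pattern, exc)
        return {"condition": condition, "motif": motif_pattern,
                "status": f"failed: {exc}", "mean": np.nan, "sd": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "activity": np.nan,
                "rhat": np.nan, "ess": np.nan}


def run_activity_screen(
    config: RunConfig,
    expression: Optional[ExpressionMatrix] = None,
    sequences: Optional[SequenceSet] = None,
    motifs: Optional[Sequence[MotifSpec]] = None,
) -> pd.DataFrame:
    """Execute the full screen and write outputs to ``config.output_dir``.

    In-memory inputs override the paths in ``config`` (useful for tests and
    programmatic use). Returns the long-format summary table.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"config": asdict(config), "version": __version__}
    try:
        summary = _run(config, expression, sequences, motifs, manifest, out)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return summary


def _run(config, expression, sequences, motifs, manifest, out: Path) -> pd.DataFrame:
    from .expression import read_expression_tsv
    from .motifs import load_motif_list

    if sequences is None:
        sequences = load_utr_fasta(config.fasta_path)
    if expression is None:
        expression = read_expression_tsv(config.expression_path)
    if motifs is None:
        motifs = load_motif_list(config.motif_path)

    n_before = len(expression.gene_ids)
    expression = align_to_sequences(expression, sequences.gene_ids)
    manifest["n_genes_dropped_no_sequence"] = n_before - len(expression.gene_ids)
    manifest["n_genes"] = len(expression.gene_ids)

    if not expression.is_log_scale and not config.already_log_scale:
        norm = log2_pseudo_tpm(expression, pseudocount=config.pseudocount)
    else:
        norm = ExpressionMatrix(values=expression.values, is_log_scale=True)
    control = None
    if config.control_path:
        control = pd.read_csv(config.control_path, sep="\t", index_col=0
                              ).iloc[:, 0].reindex(norm.values.index).values
    fc = fold_change_scores(norm, control=control)
    rankings = {c: rank_genes(fc, c) for c in norm.condition_ids}

    # SSPs and counts are condition independent: compute once per (gene, motif)
    comps = {rec.gene_id: nucleotide_composition(rec) for rec in sequences
             if rec.gene_id in set(expression.gene_ids)}
    ssp_cache: Dict[str, Dict[str, float]] = {}
    count_cache: Dict[str, Dict[str, int]] = {}
    for motif in motifs:
        ssp_cache[motif.pattern] = {
            g: motif_ssp(motif, comps[g], sequences[g].length, mode=config.ssp_mode)
            for g in comps
        }
        count_cache[motif.pattern] = {
            g: count_motif_occurrences(sequences[g], motif) for g in comps
        }

    units = []
    unit_index = 0
    no_occurrence_rows = []
    for motif in motifs:
        total = sum(count_cache[motif.pattern].values())
        for cond in norm.condition_ids:
            if total == 0:
                no_occurrence_rows.append(
                    {"condition": cond, "motif": motif.pattern,
                     "status": "no-occurrence", "mean": np.nan, "sd": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "activity": np.nan,
                     "rhat": np.nan, "ess": np.nan})
                unit_index += 1
                continue
            ranked = rankings[cond]
            part = build_partition(ranked, ssp_cache[motif.pattern],
                                   l_floor=config.l_floor)
            counts = build_count_vector(
                ranked, sequences, motif, n_cap=config.n_cap,
                counts_per_gene=count_cache[motif.pattern])
            units.append((cond, motif.pattern, counts, part,
                          _unit_seed(config.seed, unit_index)))
            unit_index += 1

    rows = Parallel(n_jobs=config.workers)(
        delayed(_fit_unit)(cond, pat, counts, part, config, seed)
        for cond, pat, counts, part, seed in units
    )
    rows = list(rows) + no_occurrence_rows
    summary = pd.DataFrame(rows).sort_values(["motif", "condition"]).reset_index(drop=True)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    wide = summary.pivot(index="motif", columns="condition", values="activity")
    wide.to_csv(out / "activity.tsv", sep="\t", float_format="%.6g")
    manifest["n_units"] = len(summary)
    manifest["n_failed"] = int((~summary["status"].isin(["ok", "no-occurrence"])).sum())
    return summary
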