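"""Expression normalization, fold-change scoring, and per-condition ranking.

The normalization ("log2 pseudo-TPM") divides each condition (column) by its
library size, rescales to a TPM-like magnitude, and log2-transforms with a
pseudocount. Fold-change (FC) scores subtract a control profile from each
condition; by default the control is a pseudo-normal condition defined by
each gene's median normalized expression across conditions. Ranking sorts
genes by decreasing FC score with stable ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x conditions expression values (raw counts or log scale)."""

    values: pd.DataFrame  # index = gene ids, columns = condition ids
    is_log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.is_log_scale and (self.values.values < 0).any():
            raise ValueError("raw expression values must be non-negative")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> List[str]:
        return list(self.values.columns)


@dataclass
class FoldChangeMatrix:
    """Genes x conditions log2 fold-change scores against a control."""

    fc: pd.DataFrame
    control_label: str = "pseudo-normal"


@dataclass
class RankedList:
    """Gene identifiers of one condition, ordered by decreasing FC score."""

    condition_id: str
    ordering: List[str]
    scores: np.ndarray = field(repr=False, default=None)  # FC along ordering

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            raise ValueError("ordering must be a permutation of distinct gene ids")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if np.any(np.diff(self.scores) > 0):
                raise ValueError("scores along the ordering must be non-increasing")

    def __len__(self) -> int:
        return len(self.ordering)


def read_expression_tsv(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes-as-rows TSV/CSV matrix with a condition header row."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, is_log_scale=False)


def read_expression_mtx(mtx_path, gene_ids_path, condition_ids_path) -> ExpressionMatrix:
    """Read a sparse Matrix Market count matrix with separate id files.

    Rows of the MTX file are genes, columns are conditions (cells); id files
    hold one identifier per line.
    """
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = [line.strip() for line in open(gene_ids_path) if line.strip()]
    conds = [line.strip() for line in open(condition_ids_path) if line.strip()]
    if mat.shape != (len(genes), len(conds)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match id files "
            f"({len(genes)} genes, {len(conds)} conditions)"
        )
    df = pd.DataFrame(mat, index=genes, columns=conds)
    return ExpressionMatrix(values=df, is_log_scale=False)


def log2_pseudo_tpm(
    raw: ExpressionMatrix,
    pseudocount: float = 1.0,
    scale: str = "median_library",
) -> ExpressionMatrix:
    """Library-size normalize each condition and log2-transform.

    Per condition j with library size L_j = sum_i x_ij, entries are scaled to
    x_ij / L_j, multiplied by a scale factor M, and transformed as
    log2(x_ij / L_j * M + pseudocount). Conditions with L_j = 0 are dropped
    with a warning.

    Parameters
    ----------
    raw
        Non-negative raw counts (or normalized values on a linear scale).
    pseudocount
        Added inside the log to handle zeros.
    scale
        ``"median_library"`` (default): M is the median library size across
        conditions, giving TPM-like comparable magnitudes.
        ``"median_entry"``: M_j is the median entry of condition j (the
        literal per-condition median; degenerate for sparse data).
    """
    vals = raw.values
    if (vals.values < 0).any():
        raise ValueError("raw expression values must be non-negative")
    lib = vals.sum(axis=0)
    if (lib == 0).all():
        raise ValueError("all conditions have zero library size")
    if (lib == 0).any():
        dropped = list(vals.columns[lib == 0])
        logger.warning("dropping %d all-zero conditions: %s", len(dropped), dropped[:5])
        vals = vals.loc[:, lib > 0]
        lib = lib[lib > 0]
    scaled = vals / lib
    if scale == "median_library":
        m = float(np.median(lib.values))
        scaled = scaled * m
    elif scale == "median_entry":
        scaled = scaled * vals.median(axis=0)
    else:
        raise ValueError(f"unknown scale mode {scale!r}")
    out = np.log2(scaled + pseudocount)
    return ExpressionMatrix(values=out, is_log_scale=True)


def fold_change_scores(
    norm: ExpressionMatrix,
    control: Optional[Sequence[float]] = None,
    control_label: Optional[str] = None,
) -> FoldChangeMatrix:
    """FC score: log expression minus a control (pseudo-normal) profile.

    The default control is each gene's median log expression across all
    conditions; a user-supplied per-gene vector overrides it.
    """
    if not norm.is_log_scale:
        raise ValueError("fold_change_scores expects log-scale expression")
    vals = norm.values
    if control is None:
        ctrl = vals.median(axis=1)
        label = "pseudo-normal"
    else:
        ctrl = np.asarray(control, dtype=float)
        if ctrl.shape[0] != vals.shape[0]:
            raise ValueError(
                f"control length {ctrl.shape[0]} != number of genes {vals.shape[0]}"
            )
        ctrl = pd.Series(ctrl, index=vals.index)
        label = control_label or "user-control"
    fc = vals.sub(ctrl, axis=0)
    if not np.isfinite(fc.values).all():
        raise ValueError("non-finite fold-change scores")
    return FoldChangeMatrix(fc=fc, control_label=label)


def rank_genes(fc: FoldChangeMatrix, condition: str) -> RankedList:
    """Rank genes by decreasing FC score (stable ties by input order)."""
    if condition not in fc.fc.columns:
        raise KeyError(f"condition {condition!r} not in fold-change matrix")
    col = fc.fc[condition]
    # stable sort on negated scores keeps input order within ties
    order = np.argsort(-col.values, kind="stable")
    genes = [col.index[i] for i in order]
    return RankedList(condition_id=condition, ordering=genes, scores=col.values[order])


def align_to_sequences(expr: ExpressionMatrix, gene_ids_with_sequence) -> ExpressionMatrix:
    """Restrict an expression matrix to genes that also have a sequence."""
    keep = [g for g in expr.gene_ids if g in set(gene_ids_with_sequence)]
    n_drop = len(expr.gene_ids) - len(keep)
    if n_drop:
        logger.info("dropping %d genes without sequence", n_drop)
    if len(keep) < 2:
        raise ValueError("fewer than 2 genes shared between expression and sequences")
    return ExpressionMatrix(values=expr.values.loc[keep], is_log_scale=expr.is_log_scale)
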