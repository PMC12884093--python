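"""Unit-interval partition and motif-count vector for a ranked list.

Each ranked sequence occupies a sub-interval of [0, 1] with length
proportional to its sequence-specific probability (SSP) of the motif, so
that under the null model motif occurrences fall uniformly on [0, 1]. The
observed per-sequence motif counts (condition-independent) are aligned to
the same rank order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .expression import RankedList
from .motifs import MotifSpec, count_motif_occurrences
from .sequences import SequenceSet


@dataclass
class IntervalPartition:
    """Rank-ordered sub-interval lengths summing to one, with midpoints."""

    lengths: np.ndarray  # l_s > 0, sum 1
    boundaries: np.ndarray  # b_0 = 0 < ... < b_N = 1
    midpoints: np.ndarray  # r_s = b_{s-1} + l_s / 2

    @classmethod
    def from_lengths(cls, lengths: np.ndarray) -> "IntervalPartition":
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths <= 0):
            raise ValueError("all sub-interval lengths must be positive")
        total = lengths.sum()
        if not np.isclose(total, 1.0, atol=1e-10, rtol=0):
            raise ValueError(f"lengths must sum to 1 (got {total})")
        boundaries = np.concatenate([[0.0], np.cumsum(lengths)])
        boundaries[-1] = 1.0
        midpoints = boundaries[:-1] + lengths / 2
        return cls(lengths=lengths, boundaries=boundaries, midpoints=midpoints)

    @classmethod
    def equal(cls, n: int) -> "IntervalPartition":
        """Equal-length partition into n sub-intervals."""
        return cls.from_lengths(np.full(n, 1.0 / n))

    def __len__(self) -> int:
        return len(self.lengths)

    def reversed(self) -> "IntervalPartition":
        """Mirror the partition around 0.5 (rank order reversed)."""
        return IntervalPartition.from_lengths(self.lengths[::-1].copy())


@dataclass
class MotifCountVector:
    """Per-rank motif occurrence counts with their total."""

    counts: np.ndarray  # nonnegative integers, rank order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)

    def reversed(self) -> "MotifCountVector":
        return MotifCountVector(counts=self.counts[::-1].copy())


def build_partition(
    ranked: RankedList,
    ssp_per_gene: Mapping[str, float],
    l_floor: float = 1e-6,
) -> IntervalPartition:
    """Normalize per-gene SSPs (in rank order) into an interval partition.

    Lengths are proportional to SSPs; any normalized length below ``l_floor``
    is raised to the floor, followed by a single renormalization. The floor
    damps the influence of sequences where the motif is (nearly) impossible.
    """
    if len(ranked) < 2:
        raise ValueError("need at least 2 ranked genes")
    missing = [g for g in ranked.ordering if g not in ssp_per_gene]
    if missing:
        raise KeyError(f"missing SSP for {len(missing)} ranked genes, e.g. {missing[:3]}")
    ssp = np.array([ssp_per_gene[g] for g in ranked.ordering], dtype=float)
    if np.any(ssp < 0):
        raise ValueError("SSPs must be nonnegative")
    total = ssp.sum()
    if total == 0:
        raise ValueError("all SSPs are zero: the motif cannot occur in any sequence")
    lengths = ssp / total
    low = lengths < l_floor
    if low.any():
        lengths[low] = l_floor
        lengths = lengths / lengths.sum()
    return IntervalPartition.from_lengths(lengths)


def build_count_vector(
    ranked: RankedList,
    sequences: SequenceSet,
    motif: MotifSpec,
    n_cap: Optional[int] = 2,
    counts_per_gene: Optional[Mapping[str, int]] = None,
) -> MotifCountVector:
    """Observed motif counts per ranked sequence, capped at ``n_cap``.

    The cap damps the influence of individual motif-dense sequences. Raw
    counts do not depend on condition, so ``counts_per_gene`` may carry
    precomputed counts reused across conditions.
    """
    if counts_per_gene is None:
        counts_per_gene = {}
        for g in ranked.ordering:
            if g not in sequences:
                raise KeyError(f"no sequence for ranked gene {g!r}")
            counts_per_gene[g] = count_motif_occurrences(sequences[g], motif)
    else:
        missing = [g for g in ranked.ordering if g not in counts_per_gene]
        if missing:
            raise KeyError(f"missing counts for ranked genes, e.g. {missing[:3]}")
    counts = np.array([counts_per_gene[g] for g in ranked.ordering], dtype=np.int64)
    if n_cap is not None:
        counts = np.minimum(counts, n_cap)
    return MotifCountVector(counts=counts)


def partition_table(
    ranked: RankedList,
    part: IntervalPartition,
    counts: MotifCountVector,
) -> pd.DataFrame:
    """Long-format inspection table: rank, gene_id, l, r, n."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(part) + 1),
            "gene_id": ranked.ordering,
            "l": part.lengths,
            "r": part.midpoints,
            "n": counts.counts,
        }
    )
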