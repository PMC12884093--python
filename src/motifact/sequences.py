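"""Sequence handling: 3' UTR FASTA input, filtering, and base composition.

Sequences are stored as cDNA (uracil replaced by thymine) and uppercased.
Ambiguous bases are normalized to ``N``; they are excluded from composition
counts and never match a motif.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


def sanitize_sequence(seq: str) -> str:
    """Uppercase, replace U with T, and map any non-ACGT character to N."""
    seq = seq.upper().replace("U", "T")
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


@dataclass(frozen=True)
class SequenceRecord:
    """A single gene's (3' UTR) sequence."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NucleotideComposition:
    """Mononucleotide frequencies of a sequence (A, C, G, T)."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")

    def as_tuple(self) -> tuple:
        return (self.freq_A, self.freq_C, self.freq_G, self.freq_T)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip("ACGT", self.as_tuple()))


@dataclass
class SequenceSet:
    """Identifier-keyed collection of sequence records."""

    records: Dict[str, SequenceRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> SequenceRecord:
        return self.records[gene_id]

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records.values())

    @property
    def gene_ids(self) -> list:
        return list(self.records.keys())

    def add(self, record: SequenceRecord) -> None:
        self.records[record.gene_id] = record


def nucleotide_composition(record: SequenceRecord) -> NucleotideComposition:
    """Base frequencies of a record, ignoring ambiguous (N) positions.

    Raises
    ------
    ValueError
        If the sequence is empty or consists only of ambiguous bases.
    """
    seq = record.sequence
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"sequence {record.gene_id!r} has no unambiguous bases")
    return NucleotideComposition(*(counts[b] / total for b in "ACGT"))


def load_utr_fasta(
    path,
    min_len: int = 20,
    max_len: int = 10_000,
    longest_isoform_per_gene: bool = True,
    id_regex: Optional[str] = None,
) -> SequenceSet:
    """Read 3' UTR sequences from FASTA with the standard filtering rules.

    Records with length outside ``[min_len, max_len]`` (inclusive bounds) are
    removed, and when several records share a gene identifier only the longest
    is retained. Sequences are uppercased and U is replaced by T.

    Parameters
    ----------
    path
        FASTA file (wrapped or unwrapped lines).
    min_len, max_len
        Inclusive length bounds in nucleotides.
    longest_isoform_per_gene
        Keep only the longest record per gene identifier.
    id_regex
        Optional regular expression applied to the full header; its first
        group is used as the gene identifier. Default: first
        whitespace-delimited token.

    Raises
    ------
    ValueError
        If the file contains no records.
    """
    pattern = re.compile(id_regex) if id_regex else None
    seqs = SequenceSet()
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        header = rec.description or rec.id
        if pattern is not None:
            m = pattern.search(header)
            if m is None or not m.group(1):
                logger.warning("skipping record with unparsable header: %r", header)
                continue
            gene_id = m.group(1)
        else:
            gene_id = rec.id
            if not gene_id:
                logger.warning("skipping record with empty header")
                continue
        seq = sanitize_sequence(str(rec.seq))
        if not (min_len <= len(seq) <= max_len):
            continue
        if gene_id in seqs and longest_isoform_per_gene:
            if len(seq) <= seqs[gene_id].length:
                continue
        seqs.add(SequenceRecord(gene_id=gene_id, sequence=seq))
    if n_seen == 0:
        raise ValueError(f"no FASTA records found in {path}")
    logger.info("loaded %d of %d FASTA records after filtering", len(seqs), n_seen)
    return seqs


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    """Write a sequence set to FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")
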