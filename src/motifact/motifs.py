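"""Motif specification, occurrence counting, and sequence-specific probabilities.

A motif is a pattern over the DNA alphabet {A, C, G, T}: either a plain k-mer
or a restricted regular expression (character classes, ``.``, alternation,
grouping). Only finite-language patterns are supported; unbounded quantifiers
(``*``, ``+``) are rejected.

The sequence-specific probability (SSP) of a motif is the probability that it
occurs at least once in a random i.i.d. sequence of a given length and
nucleotide composition. It is computed with an absorbing Markov chain: the
motif's word set is compiled to an Aho-Corasick automaton, match states are
made absorbing, and the chain is run for ``length`` steps under the
composition's emission probabilities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequences import NucleotideComposition, SequenceRecord, SequenceSet

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: refuse to enumerate patterns with more matching words than this
MAX_WORDS = 65_536


class MotifError(ValueError):
    """Invalid or unsupported motif pattern."""


@dataclass(frozen=True)
class MotifSpec:
    """A motif pattern with its plain-k-mer flag and length (if fixed)."""

    pattern: str
    is_plain_kmer: bool
    k: int  # k-mer length when plain, else 0

    @classmethod
    def from_pattern(cls, pattern: str) -> "MotifSpec":
        if not pattern:
            raise MotifError("empty motif pattern")
        pattern = pattern.upper().replace("U", "T")
        if all(c in ALPHABET for c in pattern):
            return cls(pattern=pattern, is_plain_kmer=True, k=len(pattern))
        # validate by enumerating (raises on unsupported syntax)
        enumerate_words(pattern)
        return cls(pattern=pattern, is_plain_kmer=False, k=0)

    @property
    def min_length(self) -> int:
        """Length of the shortest string matching the motif."""
        if self.is_plain_kmer:
            return self.k
        return min(len(w) for w in enumerate_words(self.pattern))


# ---------------------------------------------------------------------------
# Restricted regex parsing and finite-language enumeration
# ---------------------------------------------------------------------------


def _parse_class(pattern: str, i: int) -> Tuple[str, int]:
    """Parse a [...] character class starting at pattern[i] == '['."""
    j = i + 1
    negate = False
    if j < len(pattern) and pattern[j] == "^":
        negate = True
        j += 1
    chars = set()
    while j < len(pattern) and pattern[j] != "]":
        c = pattern[j]
        if c not in ALPHABET:
            raise MotifError(f"unsupported character {c!r} in class at position {j}")
        chars.add(c)
        j += 1
    if j >= len(pattern):
        raise MotifError("unterminated character class")
    if negate:
        chars = set(ALPHABET) - chars
    if not chars:
        raise MotifError("empty character class")
    return "".join(sorted(chars)), j + 1


def _parse_alternation(pattern: str, i: int) -> Tuple[List[List[str]], int]:
    """Parse alternation of concatenations until ')' or end.

    Returns a list of branches, each a list of character-set strings.
    """
    branches: List[List[str]] = []
    current: List[str] = []
    while i < len(pattern):
        c = pattern[i]
        if c == ")":
            break
        if c == "|":
            branches.append(current)
            current = []
            i += 1
        elif c == "(":
            sub, i = _parse_alternation(pattern, i + 1)
            if i >= len(pattern) or pattern[i] != ")":
                raise MotifError("unbalanced parenthesis")
            i += 1
            # expand group alternation into the running concatenation by
            # distributing: represent the group as a single multi-branch slot
            current.append(sub)  # type: ignore[arg-type]
        elif c == "[":
            cls, i = _parse_class(pattern, i)
            current.append(cls)
        elif c == ".":
            current.append(ALPHABET)
            i += 1
        elif c in ALPHABET:
            current.append(c)
            i += 1
        elif c in "*+?{":
            raise MotifError(f"unsupported quantifier {c!r}: only finite patterns allowed")
        else:
            raise MotifError(f"unsupported regex construct {c!r} at position {i}")
    branches.append(current)
    return branches, i


def _expand(items: List) -> List[str]:
    """Expand a concatenation of slots (char-sets or nested branch lists)."""
    words = [""]
    for slot in items:
        if isinstance(slot, list):  # nested group: list of branches
            sub_words: List[str] = []
            for branch in slot:
                sub_words.extend(_expand(branch))
            new = [w + s for w in words for s in sub_words]
        else:
            new = [w + c for w in words for c in slot]
        if len(new) > MAX_WORDS:
            raise MotifError(f"motif expands to more than {MAX_WORDS} words")
        words = new
    return words


@lru_cache(maxsize=4096)
def enumerate_words(pattern: str) -> Tuple[str, ...]:
    """Enumerate the finite set of DNA words matching a restricted regex."""
    branches, i = _parse_alternation(pattern, 0)
    if i != len(pattern):
        raise MotifError("unbalanced parenthesis")
    words: List[str] = []
    for branch in branches:
        if not branch:
            raise MotifError("empty alternation branch")
        words.extend(_expand(branch))
    out = tuple(sorted(set(words)))
    if not out:
        raise MotifError("pattern matches no words")
    return out


# ---------------------------------------------------------------------------
# Occurrence counting
# ---------------------------------------------------------------------------


def _compiled(motif: MotifSpec) -> "re.Pattern":
    # '.' must not match ambiguous N positions; restrict it to ACGT
    pat = motif.pattern.replace(".", "[ACGT]")
    try:
        return re.compile(f"(?=(?:{pat}))")
    except re.error as exc:  # pragma: no cover - parser rejects these earlier
        raise MotifError(f"invalid motif pattern {motif.pattern!r}: {exc}") from exc


def count_motif_occurrences(record: SequenceRecord, motif: MotifSpec) -> int:
    """Number of motif occurrences in a sequence, counting overlaps.

    Every start position at which the motif matches contributes one
    occurrence; the count does not depend on expression or condition.
    """
    if motif.is_plain_kmer:
        seq, pat, k = record.sequence, motif.pattern, motif.k
        count = 0
        start = seq.find(pat)
        while start != -1:
            count += 1
            start = seq.find(pat, start + 1)
        return count
    return sum(1 for _ in _compiled(motif).finditer(record.sequence))


# ---------------------------------------------------------------------------
# Absorbing Markov chain SSP
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _aho_corasick_transitions(words: Tuple[str, ...]) -> np.ndarray:
    """Dense goto table of the Aho-Corasick automaton for a word set.

    Returns an int array of shape (n_states, 4); match states are collapsed
    into a single absorbing state (index ``n_states - 1``).
    """
    # trie construction
    goto: List[Dict[int, int]] = [{}]
    terminal = [False]
    for w in words:
        s = 0
        for c in w:
            ci = _BASE_INDEX[c]
            if ci not in goto[s]:
                goto.append({})
                terminal.append(False)
                goto[s][ci] = len(goto) - 1
            s = goto[s][ci]
        terminal[s] = True
    n = len(goto)
    # classic BFS conversion of the goto trie to a dense automaton with
    # failure links resolved; terminal flags propagate along failures
    fail = [0] * n
    trans = np.zeros((n, 4), dtype=np.int64)
    from collections import deque

    queue: deque = deque()
    for ci in range(4):
        t = goto[0].get(ci, 0)
        trans[0, ci] = t
        if t:
            fail[t] = 0
            queue.append(t)
    while queue:
        s = queue.popleft()
        if terminal[fail[s]]:
            terminal[s] = True
        for ci in range(4):
            if ci in goto[s]:
                t = goto[s][ci]
                fail[t] = trans[fail[s], ci]
                trans[s, ci] = t
                queue.append(t)
            else:
                trans[s, ci] = trans[fail[s], ci]
    # collapse terminal states into one absorbing sink
    sink = n
    remap = {}
    keep = [s for s in range(n) if not terminal[s]]
    for new, s in enumerate(keep):
        remap[s] = new
    dense = np.zeros((len(keep) + 1, 4), dtype=np.int64)
    for s in keep:
        for ci in range(4):
            t = trans[s, ci]
            dense[remap[s], ci] = len(keep) if terminal[t] else remap[t]
    dense[len(keep), :] = len(keep)  # absorbing
    return dense


def motif_ssp(
    motif: MotifSpec,
    comp: NucleotideComposition,
    length: int,
    mode: str = "at_least_one",
) -> float:
    """Probability that a motif occurs in a random i.i.d. sequence.

    Parameters
    ----------
    motif
        The motif (plain k-mer or finite regex).
    comp
        Nucleotide composition of the emitting i.i.d. model.
    length
        Sequence length in nucleotides (>= 0).
    mode
        ``"at_least_one"`` (default): P(>= 1 occurrence) via the absorbing
        chain. ``"expected_count"``: expected number of (overlapping)
        occurrences, Σ_positions Σ_words Π p_base; may exceed 1 and is not
        clipped.

    Returns
    -------
    float
        In [0, 1] for ``at_least_one``; >= 0 for ``expected_count``.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    probs = np.asarray(comp.as_tuple(), dtype=float)
    words = (motif.pattern,) if motif.is_plain_kmer else enumerate_words(motif.pattern)
    if mode == "expected_count":
        total = 0.0
        for w in words:
            k = len(w)
            if length < k:
                continue
            p_word = float(np.prod([probs[_BASE_INDEX[c]] for c in w]))
            total += (length - k + 1) * p_word
        return total
    if mode != "at_least_one":
        raise ValueError(f"unknown SSP mode {mode!r}")
    if length < min(len(w) for w in words):
        return 0.0
    trans = _aho_corasick_transitions(words)
    n_states = trans.shape[0]
    # row-stochastic transition matrix under the composition
    T = np.zeros((n_states, n_states))
    for ci in range(4):
        T[np.arange(n_states), trans[:, ci]] += probs[ci]
    v = np.zeros(n_states)
    v[0] = 1.0
    v = v @ np.linalg.matrix_power(T, length)
    return float(min(1.0, max(0.0, v[-1])))


def ssp_matrix(
    seqs: SequenceSet,
    motifs: Sequence[MotifSpec],
    mode: str = "at_least_one",
) -> pd.DataFrame:
    """SSP for every (gene, motif) pair (rows = genes, columns = patterns)."""
    from .sequences import nucleotide_composition

    data = {}
    for rec in seqs:
        comp = nucleotide_composition(rec)
        data[rec.gene_id] = [motif_ssp(m, comp, rec.length, mode=mode) for m in motifs]
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[m.pattern for m in motifs]
    )


# ---------------------------------------------------------------------------
# miRNA seed handling and motif list IO
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def seed_to_target_motif(mature_mirna: str) -> MotifSpec:
    """Target motif (7-mer) from a mature miRNA sequence.

    The seed site is positions 2-8 (1-based) of the mature sequence; the
    target motif searched in 3' UTRs is its DNA reverse complement.
    """
    seq = mature_mirna.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError("mature miRNA sequence must be at least 8 nt")
    seed = seq[1:8]
    if not all(c in ALPHABET for c in seed):
        raise ValueError(f"seed region contains non-ACGU/T characters: {seed!r}")
    return MotifSpec.from_pattern(reverse_complement(seed))


def load_motif_list(path) -> List[MotifSpec]:
    """Read motifs from a text file, one pattern per line ('#' comments)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(MotifSpec.from_pattern(line))
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out
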