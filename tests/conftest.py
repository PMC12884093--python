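import numpy as np
import pytest

from motifact.partition import IntervalPartition
from motifact.model import ModelConfig
from motifact.sequences import NucleotideComposition


@pytest.fixture
def uniform_comp():
    return NucleotideComposition(0.25, 0.25, 0.25, 0.25)


@pytest.fixture
def skewed_comp():
    return NucleotideComposition(0.4, 0.1, 0.2, 0.3)


@pytest.fixture
def equal_partition():
    return IntervalPartition.equal(1000)


@pytest.fixture
def fast_config():
    """Reduced-draw sampler settings for unit tests."""
    return ModelConfig(chains=2, iterations=1200, warmup=200, seed=42)


@pytest.fixture
def default_config():
    return ModelConfig(seed=42)


def make_fasta(path, records, width=60):
    """Write a simple (optionally wrapped) FASTA file for tests."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(123)
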