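"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from codonuse import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def mutation_dataset():
    """Mutation-pressure-only regime: wide per-gene GC3, no selection."""
    config = SyntheticConfig(n_genes=1000, seed=11)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def selection_dataset():
    """Translational-selection regime with the default planted preferred set."""
    config = SyntheticConfig(n_genes=2000, selection_strength=2.0, seed=7)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def corrupted_dataset():
    """Small clean set plus 5 short, 5 N-rich and 5 multi-stop records."""
    config = SyntheticConfig(
        n_genes=50, n_short=5, n_n_rich=5, n_multi_stop=5, seed=5
    )
    return generate_dataset(config)


def write_fasta_text(path, entries):
    """Helper: write a FASTA file from (id, sequence) pairs."""
    with open(path, "w") as fh:
        for gene_id, seq in entries:
            fh.write(f">{gene_id}\n{seq}\n")
    return path
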