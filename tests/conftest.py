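"""Shared fixtures: small in-memory synthetic datasets and fitted results."""

import pytest

from wordbridge import WordEnrichment, build_ranked_dataset
from wordbridge.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    """A small planted-motif benchmark: 5-mer ACCAA planted in the top 30 of 120 genes."""
    return SyntheticSpec(
        n_genes=120,
        length_range=(150, 300),
        gc_range=(0.3, 0.6),
        planted_word="ACCAA",
        plant_probability=0.9,
        n_top=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    seqs, ranks, _ = generate_dataset(small_spec)
    return build_ranked_dataset(seqs, ranks)


@pytest.fixture(scope="session")
def small_results(small_dataset):
    """Fitted 4/5-mer analysis of the small planted benchmark."""
    return WordEnrichment(small_dataset, lengths=(4, 5)).fit()
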