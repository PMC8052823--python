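"""Shared simulation fixtures (generated at test time, no data files)."""

import numpy as np
import pytest

from censat.gc_normalization import (
    fit_gc_model,
    normalize_profile,
    select_unique_reference_kmers,
)
from censat.kmer_core import count_library, count_sequence
from censat.simulate import (
    ArraySpec,
    ReadSimSpec,
    default_consensus,
    linear_gc_bias,
    scenario_fixtures,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def consensus():
    return default_consensus()


@pytest.fixture(scope="session")
def gc_bias_sim(consensus):
    """100-kb genome + 100-copy array, 20x depth, strong linear GC bias."""
    K = 31
    array = ArraySpec(consensus=consensus, copies=100, seed=101)
    genome, truth = simulate_genome(100_000, [array], seed=102)
    reads, _ = simulate_reads(
        genome,
        ReadSimSpec(
            depth=20, read_length=100, gc_bias=linear_gc_bias(0.2, 1.0), seed=103
        ),
    )
    library = count_library(reads, K, sample_id="gcsim")
    reference = genome[:100_000]
    ref_counts = count_sequence(reference, K)
    panel = select_unique_reference_kmers(ref_counts, n=20_000, seed=104)
    model = fit_gc_model(library, panel)
    return {
        "k": K,
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "library": library,
        "panel": panel,
        "model": model,
        "depth": 20,
        "read_length": 100,
    }


@pytest.fixture(scope="session")
def scenario_bundles():
    return scenario_fixtures(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
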