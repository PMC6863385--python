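from __future__ import annotations

import pytest

import ribopause as rp
from ribopause.io import default_contaminants


@pytest.fixture(scope="session")
def small_spec():
    """A modest library: 30 transcripts, 20k reads, all read classes present."""
    return rp.SimSpec(n_transcripts=30, n_spike_transcripts=5, depth=20_000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    """(transcripts, reads, truth) for the small library, FASTQ emitted."""
    transcripts, truth0 = rp.generate_transcriptome(small_spec)
    reads, truth = rp.simulate_library(transcripts, truth0, small_spec)
    return transcripts, reads, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_sim, small_spec):
    """(alignments, ledger) from the full preprocessing chain."""
    transcripts, reads, _ = small_sim
    return rp.run_preprocess(
        reads, transcripts, default_contaminants(), adapter=small_spec.adapter
    )


@pytest.fixture(scope="session")
def contaminants():
    return default_contaminants()
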