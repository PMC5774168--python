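import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from famexpand.seqio import SequenceRecord
from famexpand.synthetic_data import (GeneratorConfig, generate,
                                      _reverse_translate)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small clean synthetic bundle shared by slower integration tests."""
    cfg = GeneratorConfig(seed=11, n_families=4,
                          genes_per_family=[1, 2, 3, 2],
                          protein_length_range=(220, 260),
                          junk_contigs=5)
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_cds(rng, protein):
    """Random reverse translation of a peptide (ATG..stop when it starts M)."""
    return _reverse_translate(rng, protein)


@pytest.fixture()
def transcripts_from(rng):
    def _make(seqs):
        return [SequenceRecord(id=f"t{i}", seq=s) for i, s in enumerate(seqs)]
    return _make
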