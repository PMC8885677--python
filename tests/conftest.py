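"""Shared fixtures: small synthetic corpora and a session-scoped trained model."""

from __future__ import annotations

import numpy as np
import pytest

from oligomine.corpus import extract_idrs
from oligomine.ngram import NeuralNGramModel
from oligomine.pipeline import PipelineConfig
from oligomine.simulate import CorpusSpec, simulate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """40 proteins with ESSES planted in the disordered blocks (seeded)."""
    spec = CorpusSpec(n_proteins=40, length_range=(120, 240), seed=11)
    return simulate_corpus(spec)


@pytest.fixture(scope="session")
def idr_segments(small_corpus):
    _, tracks, _ = small_corpus
    segments = []
    for track in tracks:
        segments.extend(extract_idrs(track))
    return segments


@pytest.fixture(scope="session")
def trained_model(idr_segments):
    """A model fitted on the small corpus, shared across generation tests."""
    cfg = PipelineConfig(seed=11)
    model = NeuralNGramModel(
        n=4, m=16, hidden_units=128, epochs=30, seed=cfg.ngram.seed
    )
    return model.fit([s.sequence for s in idr_segments])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
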