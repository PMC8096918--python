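"""Shared fixtures: tiny fast extractor configs and small planted datasets."""
from __future__ import annotations

import numpy as np
import pytest

from proptl.datasets import ProteinRecord, SiteAnnotation
from proptl.extractor import ExtractorConfig
from proptl.synthetic import MotifSpec, generate_proteome, plant_sites
from proptl.windows import encode, flank_from_size, segment_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """A deliberately small extractor that trains in a couple of seconds."""
    return ExtractorConfig(
        window_size=11, embedding_dim=4, lstm_units=4, gru_units=3,
        dense_units=8, dropout_rate=0.2, epochs=3, batch_size=64,
        validation_fraction=0.0, patience=0, seed=7,
    )


@pytest.fixture
def toy_proteins():
    return [
        ProteinRecord("p1", "MKKAYKLLNK"),
        ProteinRecord("p2", "KTTRKSPEKAAK"),
        ProteinRecord("p3", "AAAKAAAKAAAK"),
    ]


@pytest.fixture
def toy_sites(toy_proteins):
    return [
        SiteAnnotation("p1", 2, "positive"),
        SiteAnnotation("p1", 6, "negative"),
        SiteAnnotation("p2", 5, "positive"),
        SiteAnnotation("p3", 4, "negative"),
    ]


@pytest.fixture(scope="session")
def planted_batch():
    """Strongly separable encoded windows: a deterministic planted motif."""
    motif = MotifSpec(offsets=(-3, -1, 2, 4), residues=("W", "D", "F", "H"),
                      signal_strength=1.0)
    proteome = generate_proteome(140, seed=11)
    sites, proteome = plant_sites(proteome, motif, 200, 200, seed=11)
    windows = segment_dataset(proteome, sites, flank_from_size(11))
    return encode(windows)
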