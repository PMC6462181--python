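"""Shared fixtures: small synthetic configurations and a quickly trained
reduced-width classifier used by tests that need a working model but not
the full-scale one."""

from __future__ import annotations

import numpy as np
import pytest

from ihcdetect.cnn_model import (
    CNNConfig,
    PatchCNN,
    TrainingConfig,
    build_model,
    train,
)
from ihcdetect.synthetic_histology import SynthConfig, generate_patch_set


#: Reduced-width architecture: same 6-conv/2-pool/2-FC topology, far fewer
#: filters, so unit tests train in seconds.
SMALL_CNN = CNNConfig(conv_channels=(8, 8, 12, 12, 16, 16), fc_sizes=(32, 2))

#: Compact generator conditions for patch corpora in unit tests.
SMALL_SYNTH = SynthConfig(
    image_size_px=(300, 300),
    n_positive_cells=20,
    n_negative_nuclei=12,
    n_pigment_clumps=5,
    n_erythrocytes=5,
    n_stain_traces=2,
    seed=42,
)


@pytest.fixture(scope="session")
def small_patch_corpus():
    """1,000 patches per class from the compact generator conditions."""
    return generate_patch_set(SMALL_SYNTH, 1000)


@pytest.fixture(scope="session")
def quick_model(small_patch_corpus) -> PatchCNN:
    """Reduced-width classifier trained for one epoch on the small corpus."""
    model = build_model(SMALL_CNN, seed=0)
    train(model, small_patch_corpus, TrainingConfig(seed=0))
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
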