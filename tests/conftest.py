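"""Shared fixtures: one synthetic bundle per session, plus cleaned tags."""

from __future__ import annotations

import numpy as np
import pytest

from halomir import preprocess, synthetic


@pytest.fixture(scope="session")
def dataset() -> synthetic.SyntheticDataset:
    return synthetic.generate(synthetic.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def cleaned(dataset):
    clean = {
        lib: preprocess.clean_library(
            reads, dataset.config.adapter, contaminants=dataset.contaminants
        )
        for lib, reads in dataset.raw_reads.items()
    }
    tags, profiles = preprocess.collapse_tags(clean)
    return clean, tags, profiles


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
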