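import dataclasses

import numpy as np
import pytest

from dermlesion.synthdata import HairSpec, SynthParams, generate_dataset, generate_sample


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hairy_sample():
    """One 64x64 synthetic image with five drawn hair strokes."""
    params = dataclasses.replace(SynthParams(seed=7), hairs=HairSpec(count=5))
    return generate_sample(params)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 32x32 labelled samples with masks, for fast training tests."""
    return generate_dataset(8, 0.5, template=SynthParams(size=(32, 32)), seed=11)


@pytest.fixture(scope="session")
def small_seg_dataset():
    """Twenty 48x48 samples for quick segmentation fit checks."""
    return generate_dataset(20, 0.5, template=SynthParams(size=(48, 48)), seed=21)
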