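import numpy as np
import pytest

from ugtshape.contacts import ResidueSelection, build_dataset
from ugtshape.cvae import CvaeConfig, train
from ugtshape.synthetic import (
    EnsembleSpec,
    StateSpec,
    generate_ensemble,
    two_state_anchors,
)


@pytest.fixture(scope="session")
def anchors_pair():
    """Closed/open anchor geometries for 21 pseudo-residues."""
    return two_state_anchors(21)


@pytest.fixture(scope="session")
def two_state_ensemble(anchors_pair):
    """A 50/50 two-state ensemble at 1 Å noise (400 frames, seeded)."""
    closed, open_ = anchors_pair
    spec = EnsembleSpec(
        n_frames=400,
        states=(StateSpec("closed", closed, 0.5), StateSpec("open", open_, 0.5)),
        noise_sigma=1.0,
        seed=123,
        variant_label="toy",
        substrate_label="UDP-Glc",
    )
    return generate_ensemble(spec)


@pytest.fixture(scope="session")
def full_selection():
    return ResidueSelection(tuple(range(1, 22)))


@pytest.fixture(scope="session")
def two_state_dataset(two_state_ensemble, full_selection):
    return build_dataset([(two_state_ensemble, full_selection)], seed=11)


@pytest.fixture(scope="session")
def small_trained_model(two_state_dataset):
    """A briefly-trained CVAE shared by encode/latent tests."""
    config = CvaeConfig(input_size=two_state_dataset.size, seed=3, max_epochs=30)
    return train(two_state_dataset, config)
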