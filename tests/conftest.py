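"""Shared fixtures.

The expensive artifacts — the trained autoencoder, the single-system
diffusion model and the generated ensemble of the two-state toy study —
are built once per session and shared by every test that needs them.
"""

import numpy as np
import pytest

from idpdiff.protocols import (
    single_system_study,
    train_study_autoencoder,
    two_state_datasets,
)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_data():
    return two_state_datasets(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def trained_ae(study_data):
    return train_study_autoencoder(study_data, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(study_data, trained_ae):
    """Full single-system recovery study (trains the DDPM; several minutes)."""
    return single_system_study(
        seed=STUDY_SEED, data=study_data, ae=trained_ae
    )
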