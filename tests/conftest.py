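import numpy as np
import pytest

from bundlesim.mechanics import Filament, NetworkState
from bundlesim.params import ChemistryParams, MechanicalParams


@pytest.fixture
def mech_params():
    return MechanicalParams()


@pytest.fixture
def chem_params():
    return ChemistryParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def straight_filament():
    """5-bead filament along X at equilibrium spacing."""
    beads = np.zeros((5, 3))
    beads[:, 0] = np.arange(5) * 108.0
    beads[:, 1] = 500.0
    beads[:, 2] = 500.0
    return Filament(beads)


def random_bent_filament(rng, n_beads=5, scale=20.0):
    """Random mildly-bent chain with ~l0 spacing (shared helper)."""
    beads = np.zeros((n_beads, 3))
    beads[:, 0] = np.arange(n_beads) * 108.0
    beads += rng.normal(0.0, scale, size=beads.shape)
    beads += 800.0
    return Filament(beads)


@pytest.fixture
def two_filament_state(straight_filament):
    f2 = straight_filament.copy()
    f2.beads[:, 1] += 35.0
    return NetworkState([straight_filament, f2],
                        box=np.array([2000.0, 1000.0, 1000.0]))
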