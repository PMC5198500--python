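import numpy as np
import pytest

from profclust import (Alphabet, ProfileSet, generate_ensemble,
                       generate_profile_set)
from profclust.structio import compact_trace, helix_trace


@pytest.fixture(scope="session")
def binary_alphabet():
    return Alphabet("binary", ("0", "1"))


@pytest.fixture(scope="session")
def tiny_profiles(binary_alphabet):
    """The worked 3-model example: profiles [0,0], [0,0], [0,1]."""
    return ProfileSet.from_matrix(np.array([[0, 0], [0, 0], [0, 1]]),
                                  binary_alphabet, ids=["a", "b", "c"])


@pytest.fixture(scope="session")
def planted_profiles():
    """300 profiles, L=60, S=4, 3 balanced planted clusters, 5% flip noise."""
    return generate_profile_set(300, 60, 4, 3, 0.05, seed=11)


@pytest.fixture(scope="session")
def planted_binary_profiles():
    """Binary planted fixture (contact-map-like alphabet)."""
    return generate_profile_set(300, 60, 2, 3, 0.05, seed=11)


@pytest.fixture(scope="session")
def small_ensemble():
    """3 conformers x 20 noisy copies of a compact 40-residue trace."""
    template = compact_trace(40, seed=3)
    return generate_ensemble(template, n_clusters=3, per_cluster=20,
                             conformer_shift=8.0, noise_sigma=0.5, seed=3)


@pytest.fixture(scope="session")
def helix40():
    return helix_trace(40)


def random_profile_set(rng, n_max=200, l_max=100, s_max=30):
    n = int(rng.integers(2, n_max + 1))
    L = int(rng.integers(2, l_max + 1))
    S = int(rng.integers(2, s_max + 1))
    alphabet = Alphabet("rand", [str(i) for i in range(S)])
    X = rng.integers(0, S, size=(n, L))
    return ProfileSet.from_matrix(X, alphabet)
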