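import numpy as np
import pytest

from ppiddg import (GEEEncoder, GraphFeaturizer, SyntheticSpec,
                    annotate_surface, make_toy_complex)


@pytest.fixture(scope="session")
def small_complex():
    """Annotated 24-residue two-chain toy complex (12 per chain)."""
    cx = make_toy_complex(SyntheticSpec(n_residues=12, seed=42))
    return annotate_surface(cx)


@pytest.fixture(scope="session")
def small_pair(small_complex):
    return GraphFeaturizer().transform([small_complex])[0]


@pytest.fixture(scope="session")
def small_pair_equivariant(small_complex):
    return GraphFeaturizer(equivariant_max=True).transform([small_complex])[0]


@pytest.fixture(scope="session")
def random_encoder():
    return GEEEncoder().initialize()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng):
    """Haar-uniform rotation matrix via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
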