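import numpy as np
import pytest

import alloscope as al

N_RESIDUES = 60
BLOCK = (20, 40)  # internal index range of the planted rigid core (central)
RHO_IN = 0.9
RHO_OUT = 0.05
SIGMA = 0.3
FIRST_RESIDUE = 2


@pytest.fixture(scope="session")
def helix60():
    return al.make_reference_chain(N_RESIDUES)


@pytest.fixture(scope="session")
def block_spec():
    return al.CovarianceSpec(blocks=((BLOCK, RHO_IN),), rho_out=RHO_OUT, sigma=SIGMA)


@pytest.fixture(scope="session")
def make_block_ensemble(helix60, block_spec):
    """Factory: equilibrium ensemble with a planted central correlated core."""

    def factory(seed, n_frames=400):
        return al.sample_equilibrium_ensemble(helix60, block_spec, n_frames, seed=seed)

    return factory


@pytest.fixture(scope="session")
def block_residues():
    """Author residue numbers of the planted core."""
    return set(range(FIRST_RESIDUE + BLOCK[0], FIRST_RESIDUE + BLOCK[1]))


@pytest.fixture(scope="session")
def block_pipeline(make_block_ensemble):
    """One full DF + SPM run on a block ensemble, shared across tests."""
    ens = make_block_ensemble(seed=123)
    dfm = al.df_matrix(ens)
    spm = al.run_spm(ens, max_cluster_frames=100)
    return ens, dfm, spm


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-20, 20, size=3)
    return rot, shift
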