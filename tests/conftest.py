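import numpy as np
import pytest

from demonmd import (PotentialSpec, Structure, ToySpec, make_parkin_like)


@pytest.fixture(scope="session")
def pspec():
    return PotentialSpec()


@pytest.fixture(scope="session")
def small_toy():
    """20-bead two-domain chain: 10 flexible + 10 rigid residues."""
    spec = ToySpec(n_residues=20,
                   domain_plan=(((1, 10), "flexible"), ((11, 20), "rigid")),
                   seed=3)
    return make_parkin_like(spec)


@pytest.fixture(scope="session")
def medium_toy():
    """60-bead two-domain chain used for demon/guidepost unit tests."""
    spec = ToySpec(n_residues=60,
                   domain_plan=(((1, 24), "flexible"), ((25, 60), "rigid")),
                   seed=5)
    return make_parkin_like(spec)


@pytest.fixture(scope="session")
def parkin_toy():
    """The default full-size synthetic Parkin-like system."""
    return make_parkin_like(ToySpec(seed=0))


def make_chain(coords, charges=None, radii=None, labels=None, res_ids=None,
               rigid=None):
    """Hand-rolled Structure helper for small numeric tests."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return Structure(
        serials=np.arange(1, n + 1),
        res_ids=np.arange(1, n + 1) if res_ids is None else res_ids,
        res_names=["GLY"] * n,
        labels=["CA"] * n if labels is None else labels,
        masses=np.full(n, 110.0),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        radii=np.full(n, 1.9) if radii is None else np.asarray(radii, float),
        coords=coords,
        rigid_res_ids=rigid,
    )
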