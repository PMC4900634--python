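import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from permeakit.io_core import Structure
from permeakit.synthetic_system import (
    BathSpec,
    ChannelSpec,
    LigandSpec,
    build_pentamer,
    place_ions_and_slab,
    place_ligand,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_structure(coords, charges=None, radii=None, names=None,
                   resnums=None, monomers=None, resnames=None):
    """Minimal ad-hoc structure for unit fixtures."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return Structure(
        atom_name=np.asarray(names if names is not None
                             else [f"A{i}" for i in range(n)]),
        residue_name=np.asarray(resnames if resnames is not None else ["X"] * n),
        residue_number=np.asarray(resnums if resnums is not None
                                  else np.arange(1, n + 1)),
        monomer_index=np.asarray(monomers if monomers is not None else [-1] * n),
        element=np.asarray(["C"] * n),
        coords=coords,
        charge=np.asarray(charges if charges is not None else np.zeros(n)),
        vdw_radius=np.asarray(radii if radii is not None else np.zeros(n)),
    )


@pytest.fixture(scope="session")
def pentamer():
    return build_pentamer(ChannelSpec())


@pytest.fixture(scope="session")
def demo_system():
    st = build_pentamer(ChannelSpec())
    st = place_ligand(st, LigandSpec(), initial_position=(0.0, 0.0, 10.0))
    return place_ions_and_slab(st, BathSpec(rng_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
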