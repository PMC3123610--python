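import logging

import numpy as np
import pytest

from ncaco.cg_model import place_scm
from ncaco.fixtures import FixtureSpec, gen_ideal_helix, gen_structure_db
from ncaco.potentials import derive_all_tables

logging.getLogger("ncaco").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def micro_db():
    """Seeded micro structure database (helices, sheets, coils, with side chains)."""
    return gen_structure_db(FixtureSpec(n_structures=16, seed=11))


@pytest.fixture(scope="session")
def tables(micro_db):
    """Full table set derived from the micro database."""
    return derive_all_tables(micro_db)


@pytest.fixture(scope="session")
def helix20(tables):
    """20-residue ideal helix with SCM placed from the derived table."""
    return place_scm(gen_ideal_helix(20, id="helix20"), tables.scm)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def rigid_move(structure, seed=7):
    """Apply a random rotation + translation to every atom of a structure copy."""
    from scipy.spatial.transform import Rotation

    g = np.random.default_rng(seed)
    R = Rotation.random(random_state=g).as_matrix()
    t = g.normal(size=3) * 10.0
    out = structure.copy()
    for res in out.residues:
        res.n = R @ res.n + t
        res.ca = R @ res.ca + t
        res.c = R @ res.c + t
        res.o = R @ res.o + t
        if res.scm is not None:
            res.scm = R @ res.scm + t
        if res.sidechain is not None:
            res.sidechain = res.sidechain @ R.T + t
    return out
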