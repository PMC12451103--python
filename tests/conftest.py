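import numpy as np
import pytest

from mvsite import (ModelConfig, MultiViewSiteModel, SyntheticSpec,
                    simulate_structure)
from mvsite.synthetic import DatasetSpec, _simulate_one


PDB_3RES = """\
ATOM      1 P      A A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2 C4'    A A   1       1.000   0.000   0.000  1.00  0.00
ATOM      3 P      U A   2       0.000   5.000   0.000  1.00  0.00
ATOM      4 C4'    U A   2       1.000   5.000   0.000  1.00  0.00
ATOM      5 P      G A   3       0.000  10.000   0.000  1.00  0.00
ATOM      6 C4'    G A   3       1.000  10.000   0.000  1.00  0.00
HETATM    7 C1   LIG X   1       0.000   0.000   3.000  1.00  0.00
HETATM    8 C2   LIG X   1       0.000   0.000   4.500  1.00  0.00
END
"""

HOH_LINE = "HETATM    9 O    HOH X   2       8.000   8.000   8.000  1.00  0.00\n"


@pytest.fixture
def pdb_3res():
    return PDB_3RES


@pytest.fixture
def pdb_3res_with_water():
    return PDB_3RES.replace("END\n", HOH_LINE + "END\n")


@pytest.fixture(scope="session")
def small_structure():
    """A 30-residue synthetic helix with a 5-residue planted pocket."""
    spec = SyntheticSpec(n_residues=30, pocket_size=5, seed=11)
    return simulate_structure(spec)


@pytest.fixture(scope="session")
def small_graph():
    """One fully featurized synthetic RNA (raw, unstandardized features)."""
    dspec = DatasetSpec(d_emb=8, seed=5)
    return _simulate_one(dspec, 0, np.random.default_rng(5))


@pytest.fixture(scope="session")
def small_model(small_graph):
    cfg = ModelConfig(d_init=small_graph.features.d_init, d_hidden=16,
                      d_scale=12, n_heads=2, clf_hidden=8, dropout=0.0,
                      seed=3)
    return MultiViewSiteModel(cfg)
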