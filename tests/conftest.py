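import numpy as np
import pytest

from bondprop.fixtures import (
    MiniPdbSpec,
    RandomGraphSpec,
    make_mini_pdb,
    make_random_graph,
)
from bondprop.graph_construction import assemble_graph
from bondprop.propensity_core import compute_field, source_from_residues
from bondprop.quantile_scoring import score_protein
from bondprop.structure_io import parse_pdb

TOY_ALA = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.005   1.424   0.000  1.00  0.00           C
END
"""

TOY_WITH_WATERS = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.005   1.424   0.000  1.00  0.00           C
HETATM    4  O   HOH A 101      8.000   0.000   0.000  1.00  0.00           O
HETATM    5  O   HOH A 102      9.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def dipeptide():
    text, truth = make_mini_pdb(MiniPdbSpec(sequence="AA", seed=0))
    return text, truth


@pytest.fixture(scope="session")
def pentapeptide_with_ligand():
    text, truth = make_mini_pdb(
        MiniPdbSpec(sequence="AAGAA", seed=0, with_ligand=True)
    )
    return text, truth


@pytest.fixture(scope="session")
def helix_spec():
    return MiniPdbSpec(
        sequence="AAGAAAGAAAGAAAAA",
        seed=0,
        conformation="helix",
        with_ligand=True,
        ligand_donor_residue=2,
    )


@pytest.fixture(scope="session")
def helix_model(helix_spec):
    text, _ = make_mini_pdb(helix_spec)
    return parse_pdb(text, source="helix16")


@pytest.fixture(scope="session")
def helix_graph(helix_model):
    return assemble_graph(helix_model)


@pytest.fixture(scope="session")
def helix_field(helix_graph):
    # source: the two C-terminal residues (far from the planted ligand)
    source = source_from_residues(helix_graph, {14, 15}, "test source")
    return compute_field(helix_graph, source)


@pytest.fixture(scope="session")
def helix_table(helix_field):
    return score_protein(helix_field)


@pytest.fixture()
def random_graph():
    def _make(n=30, seed=0, **kwargs):
        return make_random_graph(RandomGraphSpec(n_nodes=n, seed=seed, **kwargs))

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
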