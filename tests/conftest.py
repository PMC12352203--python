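import gemmi
import numpy as np
import pytest

from disomap.datatypes import PerResidueTrack, ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240315)


def make_track(values, name="t", protein_id="P1"):
    return PerResidueTrack(protein_id, name, np.asarray(values, dtype=float))


def make_sequence(residues, ident="P1"):
    return ProteinSequence(ident, residues)


def build_structure(bfactors, chains=("A",), atoms_per_residue=2,
                    name="toy"):
    """A minimal gemmi structure: len(bfactors) residues per chain, each
    with an N and a CA atom carrying the residue's B-factor."""
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for chain_name in chains:
        chain = gemmi.Chain(chain_name)
        for i, b in enumerate(bfactors, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i, " ")
            for aname, el in [("N", "N"), ("CA", "C")][:atoms_per_residue]:
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(float(i), float(len(chain_name)), 0.0)
                atom.b_iso = float(b)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    build_structure([50.0, 90.0]).write_pdb(str(path))
    return path
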