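import numpy as np
import pytest
from rdkit import Chem

from cugscreen import synthetic
from cugscreen.chemspace import CompoundLibrary, Molecule


@pytest.fixture(scope="session")
def small_library():
    return synthetic.gen_compound_library(n=60, active_fraction=0.25, seed=0)


@pytest.fixture(scope="session")
def duplex():
    return synthetic.gen_rna_duplex(seed=0)


@pytest.fixture(scope="session")
def duplex6():
    return synthetic.gen_rna_duplex(
        synthetic.SyntheticRNASpec(n_repeats=6), seed=1)


def molecule_from_smiles(smiles, mol_id="m", label=None):
    return Molecule(mol=Chem.MolFromSmiles(smiles), id=mol_id, label=label)


def single_atom_molecule(element, xyz, mol_id="atom", charge=None):
    """One-atom molecule with an explicit 3D position (for overlap math)."""
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom(element))
    m = mol.GetMol()
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, [float(v) for v in xyz])
    m.AddConformer(conf)
    charges = None if charge is None else np.array([float(charge)])
    return Molecule(mol=m, id=mol_id, charges=charges)


@pytest.fixture
def library_factory():
    def make(smiles_labels):
        mols = [molecule_from_smiles(s, f"M{i:03d}", lab)
                for i, (s, lab) in enumerate(smiles_labels)]
        return CompoundLibrary(molecules=mols)
    return make
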