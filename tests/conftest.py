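import numpy as np
import pytest

from lssr import (
    FixtureSpec,
    LssrParams,
    enumerate_restraints,
    generate_ncs_fixture,
    match_atoms,
)
from lssr.structure import Atom, Chain, Residue, Structure

THREE_ATOM_PDB = """\
ATOM      1  N   SER A 102      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  SER A 102      10.021   5.201  -6.201  1.00 10.00           C
ATOM      3  C   SER A 102       9.102   4.900  -7.380  1.00 10.00           C
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


def make_atom(chain_id, resnum, resname, name, element, xyz, **kw):
    return Atom(
        chain_id=chain_id,
        residue_number=resnum,
        icode=kw.pop("icode", " "),
        residue_name=resname,
        atom_name=name,
        element=element,
        position=np.asarray(xyz, dtype=float),
        **kw,
    )


def make_structure(chain_specs):
    """chain_specs: {chain_id: [(resnum, resname, [(name, elem, xyz), ...])]}"""
    chains = []
    for cid, residues in chain_specs.items():
        chain = Chain(cid)
        for resnum, resname, atoms in residues:
            res = Residue(resnum, " ", resname, is_hetero=resname in ("HEM", "HOH"))
            for name, elem, xyz in atoms:
                res.atoms.append(
                    make_atom(cid, resnum, resname, name, elem, xyz,
                              is_hetero=res.is_hetero)
                )
            chain.residues.append(res)
        chains.append(chain)
    return Structure(chains)


@pytest.fixture
def two_copy_fixture():
    """Exact duplicate two-chain fixture: every delta is zero."""
    return generate_ncs_fixture(FixtureSpec(n_residues=8, n_chains=2, seed=0))


@pytest.fixture
def noisy_fixture():
    return generate_ncs_fixture(
        FixtureSpec(n_residues=8, n_chains=2, noise_sd=0.05, seed=11)
    )


@pytest.fixture
def outlier_fixture():
    """Residue 4 of the second copy displaced 3 A (deep in the plateau)."""
    return generate_ncs_fixture(
        FixtureSpec(n_residues=8, n_chains=2, noise_sd=0.02,
                    outliers=[(4, 3.0)], seed=3)
    )


@pytest.fixture
def flipped_phe_fixture():
    """Identical copies except the PHE at residue 3 has CD1/CD2 and CE1/CE2
    labels exchanged in chain B."""
    return generate_ncs_fixture(
        FixtureSpec(n_residues=8, n_chains=2, label_flips=[3], seed=2)
    )


def build_pair_list(s, chain_a="A", chain_b="B", params=None):
    params = params or LssrParams()
    corr = match_atoms(s, chain_a, chain_b)
    return enumerate_restraints(corr, s, params)
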