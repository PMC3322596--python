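"""Covalent topology: bond graphs and bond-path separation classes.

Bonds come from standard amino-acid connectivity templates, inter-residue
peptide and disulfide links, and distance-based detection (heavy atoms within
``HETERO_BOND_CUTOFF``) for residues without a template.  The only question
restraint enumeration asks is whether two atoms of the same copy are separated
by fewer than three bonds (1-2 or 1-3: excluded) or by exactly three (1-4).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

logger = logging.getLogger(__name__)

HETERO_BOND_CUTOFF = 1.9  # Angstrom, heavy-atom distance-based bonding
PEPTIDE_BOND_CUTOFF = 2.5  # sanity bound for C(i)-N(i+1)
DISULFIDE_CUTOFF = 2.3  # SG-SG

SEP_EXCLUDED = 0  # 1-2 or 1-3
SEP_ONE_FOUR = 1
SEP_NONBONDED = 2

_BACKBONE = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDECHAIN: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CB", "SG")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CB", "OG")],
    "THR": [("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
}

STANDARD_RESIDUES = frozenset(_SIDECHAIN)


def residue_template(name: str) -> list[tuple[str, str]] | None:
    """Intra-residue heavy-atom bond list for a standard residue, else None."""
    if name not in _SIDECHAIN:
        return None
    bonds = list(_BACKBONE) + list(_SIDECHAIN[name])
    if name != "GLY":
        bonds.append(("CA", "CB"))
    return bonds


class Topology:
    """Bond graph over a structure's flat atom order.

    Exposes, per atom, the set of atoms within one or two bonds (the 1-2/1-3
    exclusion set) and within exactly three bonds (the 1-4 shell).
    """

    def __init__(self, n_atoms: int, bonds: list[tuple[int, int]]):
        self.n_atoms = n_atoms
        self.bonds = sorted({(min(i, j), max(i, j)) for i, j in bonds if i != j})
        adj: list[set[int]] = [set() for _ in range(n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        self.adjacency = adj
        self._excl: list[set[int]] = []
        self._shell3: list[set[int]] = []
        for i in range(n_atoms):
            one = adj[i]
            two = set()
            for j in one:
                two |= adj[j]
            excl = (one | two) - {i}
            three = set()
            for j in two:
                three |= adj[j]
            self._excl.append(excl)
            self._shell3.append(three - excl - {i})

    def separation_class(self, i: int, j: int) -> int:
        if j in self._excl[i]:
            return SEP_EXCLUDED
        if j in self._shell3[i]:
            return SEP_ONE_FOUR
        return SEP_NONBONDED

    def excluded(self, i: int) -> set[int]:
        return self._excl[i]


def build_topology(s: Structure) -> Topology:
    """Derive the covalent bond graph of *s*.

    Standard residues use the connectivity templates; anything else (haems,
    ligands, waters) falls back to distance-based bonding at
    <= ``HETERO_BOND_CUTOFF`` Angstrom between heavy atoms.  Consecutive
    residues in a chain are joined by a peptide C-N bond; disulfides join SG
    pairs within ``DISULFIDE_CUTOFF``.
    """
    atoms = s.atoms()
    index = {id(a): i for i, a in enumerate(atoms)}
    bonds: list[tuple[int, int]] = []
    fallback_atoms: list[int] = []

    for chain in s.chains:
        prev = None
        for res in chain.residues:
            template = residue_template(res.name)
            by_name = {a.atom_name: a for a in res.atoms}
            if template is None:
                if not res.is_water and len(res.atoms) > 1:
                    logger.warning(
                        "no connectivity template for %s %s%s; using "
                        "distance-based bonding",
                        res.name, chain.chain_id, res.number,
                    )
                fallback_atoms.extend(index[id(a)] for a in res.atoms)
            else:
                missing_template_atoms = [
                    a for a in res.atoms
                    if a.atom_name not in {n for b in template for n in b}
                    and a.element not in ("H", "D")
                ]
                if missing_template_atoms:
                    fallback_atoms.extend(
                        index[id(a)] for a in res.atoms if a.element not in ("H", "D")
                    )
                for n1, n2 in template:
                    a1, a2 = by_name.get(n1), by_name.get(n2)
                    if a1 is not None and a2 is not None:
                        bonds.append((index[id(a1)], index[id(a2)]))
            # peptide link between consecutive residues
            if prev is not None:
                c = prev.atom("C")
                n = by_name.get("N")
                if (
                    c is not None
                    and n is not None
                    and float(np.linalg.norm(c.position - n.position))
                    < PEPTIDE_BOND_CUTOFF
                ):
                    bonds.append((index[id(c)], index[id(n)]))
            prev = res

    # disulfides
    sg = [(index[id(a)], a) for a in atoms if a.atom_name == "SG" and a.element == "S"]
    for (i1, a1), (i2, a2) in combinations(sg, 2):
        if float(np.linalg.norm(a1.position - a2.position)) <= DISULFIDE_CUTOFF:
            bonds.append((i1, i2))

    # distance-based bonding for template-less groups (against all heavy atoms,
    # so hetero groups also bond to protein where covalently linked)
    if fallback_atoms:
        heavy = [i for i, a in enumerate(atoms) if a.element not in ("H", "D")]
        pos = np.array([atoms[i].position for i in heavy])
        tree = cKDTree(pos)
        heavy_pos = {i: k for k, i in enumerate(heavy)}
        fb = sorted(set(fallback_atoms))
        fb_pos = np.array([atoms[i].position for i in fb])
        for k, i in enumerate(fb):
            for m in tree.query_ball_point(fb_pos[k], HETERO_BOND_CUTOFF):
                j = heavy[m]
                if j != i:
                    bonds.append((min(i, j), max(i, j)))
        del heavy_pos

    return Topology(len(atoms), bonds)
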