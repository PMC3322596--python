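"""Atom-level correspondences between similar chains or structures.

Covers automatic NCS chain-group detection (the 80% residue-name rule),
name/number-keyed atom matching within a structure and against a fixed
target, and nomenclature resolution by swapping equivalent side-chain atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .structure import Atom, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "AtomCorrespondence",
    "SwapReport",
    "TargetMatchError",
    "detect_ncs_groups",
    "match_atoms",
    "match_target",
    "swap_equivalent_atoms",
    "SWAP_PAIRS_STANDARD",
    "SWAP_PAIRS_PLUS",
]


class TargetMatchError(ValueError):
    """No atom of the refined structure matches the target structure."""


@dataclass
class AtomCorrespondence:
    """One-to-one mapping between equivalent atoms of two copies.

    ``pairs[k] = (atom in copy 1, atom in copy 2)``.  For ``kind='ncs'`` both
    copies live in the same structure and are distinguished by chain id; for
    ``kind='target'`` copy 2 belongs to a separate, immutable structure.
    """

    pairs: list[tuple[Atom, Atom]]
    kind: str  # 'ncs' | 'target'
    label_1: str
    label_2: str
    unmatched_1: list[Atom] = field(default_factory=list)
    unmatched_2: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("ncs", "target"):
            raise ValueError(f"unknown correspondence kind {self.kind!r}")
        left = set(map(id, (a for a, _ in self.pairs)))
        right = set(map(id, (b for _, b in self.pairs)))
        if len(left) != len(self.pairs) or len(right) != len(self.pairs):
            raise ValueError("correspondence is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def target_fixed(self) -> bool:
        return self.kind == "target"


def _residue_names_by_number(chain) -> dict[tuple[int, str], str]:
    return {(r.number, r.icode): r.name for r in chain.residues}


def chain_pair_match_fraction(s: Structure, chain_a: str, chain_b: str) -> float | None:
    """Fraction of shared residue numbers with equal residue names.

    Returns None when the chains share no residue numbers (no vote possible).
    """
    names_a = _residue_names_by_number(s.chain(chain_a))
    names_b = _residue_names_by_number(s.chain(chain_b))
    shared = names_a.keys() & names_b.keys()
    if not shared:
        return None
    same = sum(1 for key in shared if names_a[key] == names_b[key])
    return same / len(shared)


def detect_ncs_groups(
    s: Structure, min_match_fraction: float = 0.8
) -> list[list[str]]:
    """Find groups of NCS-related chains.

    Two chains are NCS-related iff the fraction of residues with matching
    residue numbers that also share the residue name exceeds
    *min_match_fraction* (strictly), with at least one residue overlapping.
    Groups are connected components of the resulting pair graph; chain order
    within a group follows the structure's chain order.
    """
    chain_ids = [c.chain_id for c in s.chains]
    adjacency: dict[str, set[str]] = {cid: set() for cid in chain_ids}
    for a, b in combinations(chain_ids, 2):
        frac = chain_pair_match_fraction(s, a, b)
        if frac is not None and frac > min_match_fraction:
            adjacency[a].add(b)
            adjacency[b].add(a)
    groups: list[list[str]] = []
    seen: set[str] = set()
    for cid in chain_ids:
        if cid in seen or not adjacency[cid]:
            continue
        component = []
        stack = [cid]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            component.append(cur)
            stack.extend(sorted(adjacency[cur] - seen))
        groups.append(sorted(component, key=chain_ids.index))
    return groups


def match_atoms(s: Structure, chain_a: str, chain_b: str) -> AtomCorrespondence:
    """Pair atoms of two chains by (residue_number, icode, atom_name)."""
    ca, cb = s.chain(chain_a), s.chain(chain_b)
    lookup: dict[tuple, Atom] = {}
    for r in cb.residues:
        for a in r.atoms:
            lookup[(r.number, r.icode, a.atom_name)] = a
    pairs: list[tuple[Atom, Atom]] = []
    unmatched_1: list[Atom] = []
    used = set()
    for r in ca.residues:
        for a in r.atoms:
            key = (r.number, r.icode, a.atom_name)
            partner = lookup.get(key)
            if partner is None or id(partner) in used:
                unmatched_1.append(a)
            else:
                pairs.append((a, partner))
                used.add(id(partner))
    unmatched_2 = [a for r in cb.residues for a in r.atoms if id(a) not in used]
    if not pairs:
        logger.warning("no atoms match between chains %s and %s", chain_a, chain_b)
    return AtomCorrespondence(pairs, "ncs", chain_a, chain_b, unmatched_1, unmatched_2)


def match_target(s: Structure, target: Structure) -> AtomCorrespondence:
    """Pair atoms of *s* with target atoms of identical chain/residue/name.

    The target side is fixed: its coordinates never move during
    minimization, and its atoms receive no gradient.
    """
    lookup: dict[tuple, Atom] = {}
    for c in target.chains:
        for r in c.residues:
            for a in r.atoms:
                lookup[(c.chain_id, r.number, r.icode, a.atom_name)] = a
    pairs: list[tuple[Atom, Atom]] = []
    unmatched_1: list[Atom] = []
    used = set()
    for c in s.chains:
        for r in c.residues:
            for a in r.atoms:
                key = (c.chain_id, r.number, r.icode, a.atom_name)
                partner = lookup.get(key)
                if partner is None or id(partner) in used:
                    unmatched_1.append(a)
                else:
                    pairs.append((a, partner))
                    used.add(id(partner))
    if not pairs:
        raise TargetMatchError(
            "no atom of the refined structure matches the target structure "
            "(check chain ids and residue numbering)"
        )
    unmatched_2 = [
        a for c in target.chains for r in c.residues for a in r.atoms
        if id(a) not in used
    ]
    return AtomCorrespondence(
        pairs, "target", "refined", "target", unmatched_1, unmatched_2
    )


# ---------------------------------------------------------------------------
# Equivalent-atom swapping
# ---------------------------------------------------------------------------

# Residue type -> list of atom-name pairs exchanged together (a nomenclature
# flip of the whole side-chain symmetry unit).
SWAP_PAIRS_STANDARD: dict[str, list[tuple[str, str]]] = {
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "ARG": [("NH1", "NH2")],
}

# The plus mode additionally flips quasi-symmetric residues, exchanging
# physically non-equivalent atoms (N<->C, O<->N): HIS imidazole ring flip,
# ASN and GLN amide flips.
SWAP_PAIRS_PLUS: dict[str, list[tuple[str, str]]] = {
    **SWAP_PAIRS_STANDARD,
    "HIS": [("ND1", "CD2"), ("NE2", "CE1")],
    "ASN": [("OD1", "ND2")],
    "GLN": [("OE1", "NE2")],
}


@dataclass
class SwapReport:
    """Record of nomenclature swaps applied to a structure."""

    swaps: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    mode: str = "standard"

    @property
    def n_residues_adjusted(self) -> int:
        return len(self.swaps)

    def to_records(self) -> list[dict]:
        return [dict(rec) for rec in self.swaps]


def _residue_swap_penalty(
    residue, corr: AtomCorrespondence, structure: Structure,
    target: Structure | None, params, swapped: bool, pair_names: list[tuple[str, str]],
) -> float:
    """Summed LSSR penalty of restraints touching the residue's swappable
    atoms, under the current or the exchanged nomenclature.

    A name swap is evaluated as a coordinate exchange between the paired
    atoms: the set of atom names is unchanged, only which physical position
    each name refers to.
    """
    import numpy as np

    from .core import enumerate_restraints, lssr_penalty

    originals = {}
    if swapped:
        for n1, n2 in pair_names:
            a1, a2 = residue.atom(n1), residue.atom(n2)
            originals[n1] = a1.position.copy()
            originals[n2] = a2.position.copy()
            a1.position, a2.position = a2.position.copy(), a1.position.copy()
    try:
        rl = enumerate_restraints(corr, structure, params, target=target)
        swap_atoms = {residue.atom(n) for pair in pair_names for n in pair}
        swap_ids = {id(a) for a in swap_atoms}
        total = 0.0
        for r in rl.restraints:
            if {id(r.atom_i), id(r.atom_j), id(r.atom_ip), id(r.atom_jp)} & swap_ids:
                total += lssr_penalty(r.delta, params)
        return float(total)
    finally:
        for name, pos in originals.items():
            residue.atom(name).position = np.asarray(pos)


def swap_equivalent_atoms(
    s: Structure,
    correspondences: list[AtomCorrespondence],
    mode: str = "standard",
    params=None,
    target: Structure | None = None,
) -> SwapReport:
    """Resolve side-chain nomenclature ambiguity against a reference copy.

    For each correspondence, candidate residues on the copy-2 side (the
    non-reference chain; for target kind, the structure under refinement)
    are evaluated with their symmetric atom names as-is and exchanged; the
    labelling with the lower summed LSSR penalty is kept.  Names are swapped
    in place in *s*; coordinates are never moved.  Callers should rebuild
    correspondences and restraint lists afterwards.
    """
    from .core import LssrParams

    if params is None:
        params = LssrParams()
    table = {"standard": SWAP_PAIRS_STANDARD, "plus": SWAP_PAIRS_PLUS}.get(mode)
    if table is None:
        raise ValueError(f"unknown swap mode {mode!r}")

    report = SwapReport(mode=mode)
    for corr in correspondences:
        if corr.kind == "target":
            if target is None:
                raise ValueError("target structure required for target-kind swaps")
            mutable_chain_label = None
        else:
            mutable_chain_label = corr.label_2
        residues = _candidate_residues(s, corr, mutable_chain_label, table)
        for chain, res, pair_names in residues:
            complete = all(
                res.atom(n1) is not None and res.atom(n2) is not None
                for n1, n2 in pair_names
            )
            if not complete:
                report.skipped.append(
                    {
                        "chain": chain.chain_id,
                        "residue_number": res.number,
                        "residue_name": res.name,
                        "reason": "missing atom of a symmetric pair",
                    }
                )
                logger.warning(
                    "swap skipped for %s %s%d: missing atom of a symmetric pair",
                    res.name, chain.chain_id, res.number,
                )
                continue
            tgt = target if corr.kind == "target" else None
            pen_orig = _residue_swap_penalty(
                res, corr, s, tgt, params, swapped=False, pair_names=pair_names
            )
            pen_swap = _residue_swap_penalty(
                res, corr, s, tgt, params, swapped=True, pair_names=pair_names
            )
            if pen_swap < pen_orig:
                for n1, n2 in pair_names:
                    a1, a2 = res.atom(n1), res.atom(n2)
                    a1.atom_name, a2.atom_name = n2, n1
                    if a1.element != a2.element:
                        # quasi-symmetric (plus-mode) flips exchange names
                        # across elements; composition is unchanged
                        a1.element, a2.element = a2.element, a1.element
                report.swaps.append(
                    {
                        "chain": chain.chain_id,
                        "residue_number": res.number,
                        "residue_name": res.name,
                        "pairs": list(pair_names),
                        "penalty_before": pen_orig,
                        "penalty_after": pen_swap,
                    }
                )
                # renaming invalidates the name-keyed pairing: rebuild
                if corr.kind == "ncs":
                    corr = match_atoms(s, corr.label_1, corr.label_2)
                else:
                    corr = match_target(s, target)
    return report


def _candidate_residues(s, corr, mutable_chain_label, table):
    out = []
    if mutable_chain_label is not None:
        chains = [s.chain(mutable_chain_label)]
    else:
        chains = s.chains
    for chain in chains:
        for res in chain.residues:
            if res.name in table:
                out.append((chain, res, table[res.name]))
    return out
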