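"""Coordinate data model and PDB/mmCIF input/output.

The hierarchy is deliberately flat and explicit: a :class:`Structure` owns
ordered :class:`Chain` objects, which own ordered :class:`Residue` objects,
which own ordered :class:`Atom` objects.  Only the first model of multi-model
files is kept; coordinates are never transformed on input.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "SelectionPolicy",
    "FormatError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "interatomic_distance",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})
HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class FormatError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(eq=False)
class Atom:
    """One atom record (identity-hashed: two reads of the same file give
    distinct objects).

    ``residue_number`` is author numbering; together with ``icode`` it forms
    the residue identity used for equivalence matching.
    """

    chain_id: str
    residue_number: int
    icode: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")

    @property
    def key(self) -> tuple:
        return (
            self.chain_id,
            self.residue_number,
            self.icode,
            self.atom_name,
            self.altloc,
        )

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.icode)

    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain_id}{self.residue_number}{ic} {self.atom_name}"

    def copy(self) -> "Atom":
        return Atom(
            chain_id=self.chain_id,
            residue_number=self.residue_number,
            icode=self.icode,
            residue_name=self.residue_name,
            atom_name=self.atom_name,
            element=self.element,
            position=self.position.copy(),
            occupancy=self.occupancy,
            b_factor=self.b_factor,
            altloc=self.altloc,
            is_hetero=self.is_hetero,
        )


@dataclass
class Residue:
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def id(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(
            self.number,
            self.icode,
            self.name,
            [a.copy() for a in self.atoms],
            self.is_hetero,
        )


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = " ") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


class Structure:
    """Ordered chains of ordered residues of atoms.

    Atom order is the order of construction (file order for parsed files) and
    is the canonical flat order used by coordinate arrays and restraint
    indices.
    """

    def __init__(self, chains: Iterable[Chain] = (), provenance: str = ""):
        self.chains: list[Chain] = list(chains)
        self.provenance = provenance
        seen = set()
        for c in self.chains:
            if c.chain_id in seen:
                raise ValueError(f"duplicate chain identifier {c.chain_id!r}")
            seen.add(c.chain_id)
        self._validate_unique_atoms()
        self._index: dict[int, int] | None = None

    def _validate_unique_atoms(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms():
            if a.key in seen:
                raise ValueError(f"duplicate atom {a.key}")
            seen.add(a.key)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.chain_id == chain_id for c in self.chains)

    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for r in c.residues for a in r.atoms]

    def residues(self) -> list[tuple[Chain, Residue]]:
        return [(c, r) for c in self.chains for r in c.residues]

    def __len__(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def coords(self) -> np.ndarray:
        ats = self.atoms()
        if not ats:
            return np.zeros((0, 3))
        return np.array([a.position for a in ats], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        ats = self.atoms()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(ats), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, xyz in zip(ats, coords):
            a.position = xyz.copy()
        self._index = None

    def atom_index(self, atom: Atom) -> int:
        """Index of *atom* in the flat atom order (identity based)."""
        if self._index is None or id(atom) not in self._index:
            self._index = {id(a): i for i, a in enumerate(self.atoms())}
        return self._index[id(atom)]

    def invalidate_index(self) -> None:
        self._index = None

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains], self.provenance)


@dataclass(frozen=True)
class SelectionPolicy:
    """What :func:`select_atoms` keeps.

    ``altloc`` is ``"first"`` (first-listed conformer per atom name) or
    ``"highest_occupancy"``.
    """

    remove_waters: bool = True
    remove_hydrogens: bool = True
    keep_hetero: bool = True
    altloc: str = "first"

    def __post_init__(self) -> None:
        if self.altloc not in ("first", "highest_occupancy", "all"):
            raise ValueError(f"unknown altloc policy {self.altloc!r}")


DEFAULT_POLICY = SelectionPolicy()


def interatomic_distance(a: Atom, b: Atom) -> float:
    """Euclidean distance between two atoms in Angstrom."""
    return float(np.linalg.norm(a.position - b.position))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _guess_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".cif", ".mmcif")):
        return "mmcif"
    if lower.endswith((".pdb", ".ent")):
        return "pdb"
    with open(path) as fh:
        head = fh.read(4096)
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _from_biopdb(model, provenance: str) -> Structure:
    chains = []
    for bchain in model:
        chain = Chain(str(bchain.id).strip() or " ")
        for bres in bchain:
            hetfield, resseq, icode = bres.id
            res = Residue(
                number=int(resseq),
                icode=icode if icode.strip() else " ",
                name=bres.get_resname().strip(),
                is_hetero=bool(hetfield.strip()),
            )
            for batom in bres.get_unpacked_list():
                altloc = batom.get_altloc()
                res.atoms.append(
                    Atom(
                        chain_id=chain.chain_id,
                        residue_number=res.number,
                        icode=res.icode,
                        residue_name=res.name,
                        atom_name=batom.get_name().strip(),
                        element=(batom.element or "").strip().upper(),
                        position=np.asarray(batom.get_coord(), dtype=float),
                        occupancy=float(batom.get_occupancy() or 0.0),
                        b_factor=float(batom.get_bfactor() or 0.0),
                        altloc=altloc if altloc.strip() else "",
                        is_hetero=res.is_hetero,
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    return Structure(chains, provenance=provenance)


def read_structure(path: str | os.PathLike, format_hint: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (first model only)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = format_hint if format_hint != "auto" else _guess_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format hint {format_hint!r}")
    from Bio.PDB import MMCIFParser, PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    try:
        if fmt == "pdb":
            _preflight_pdb(path)
            parser = PDBParser(PERMISSIVE=False, QUIET=True)
        else:
            parser = MMCIFParser(QUIET=True)
        bstruct = parser.get_structure(os.path.basename(path), path)
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: {exc}") from exc
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    models = list(bstruct)
    if not models:
        raise FormatError(f"{path}: no models found")
    return _from_biopdb(models[0], provenance=f"{path} ({fmt})")


def _preflight_pdb(path: str) -> None:
    """Reject malformed ATOM/HETATM records with the offending line number.

    Bio.PDB silently tolerates truncated records; the contract here is a
    format error that names the line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            stripped = line.rstrip("\n")
            if len(stripped) < 54:
                raise FormatError(
                    f"{path}:{lineno}: truncated {rec} record "
                    f"({len(stripped)} columns, need >= 54)"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
                int(line[22:26])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparseable {rec} record: {exc}"
                ) from exc


def _format_atom_name(name: str, element: str) -> str:
    # wwPDB v3.3: one-letter elements are right-justified into columns 13-16
    # starting at column 14; four-character names fill all of 13-16.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_structure(s: Structure, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write *s* as PDB (ATOM/HETATM/TER records, wwPDB v3.3 columns)."""
    own = False
    if isinstance(path, (str, os.PathLike)):
        fh = open(path, "w")
        own = True
    else:
        fh = path
    try:
        serial = 0
        for chain in s.chains:
            for res in chain.residues:
                for a in res.atoms:
                    serial += 1
                    rec = "HETATM" if a.is_hetero else "ATOM"
                    fh.write(
                        f"{rec:<6s}{serial:>5d} "
                        f"{_format_atom_name(a.atom_name, a.element)}"
                        f"{a.altloc or ' '}"
                        f"{a.residue_name:>3s} {chain.chain_id[:1]}"
                        f"{a.residue_number:>4d}{a.icode[:1]}   "
                        f"{a.position[0]:8.3f}{a.position[1]:8.3f}"
                        f"{a.position[2]:8.3f}{a.occupancy:6.2f}"
                        f"{a.b_factor:6.2f}          {a.element:>2s}\n"
                    )
            serial += 1
            last = chain.residues[-1]
            fh.write(
                f"TER   {serial:>5d}      {last.name:>3s} "
                f"{chain.chain_id[:1]}{last.number:>4d}{last.icode[:1]}\n"
            )
        fh.write("END\n")
    finally:
        if own:
            fh.close()


def select_atoms(s: Structure, policy: SelectionPolicy = DEFAULT_POLICY) -> Structure:
    """Return a new Structure with the policy applied.

    The default removes waters and hydrogens, keeps hetero groups (haems,
    ligands) and keeps one conformer per atom name.
    """
    chains = []
    for chain in s.chains:
        new_chain = Chain(chain.chain_id)
        for res in chain.residues:
            if policy.remove_waters and res.is_water:
                continue
            if res.is_hetero and not res.is_water and not policy.keep_hetero:
                continue
            new_res = Residue(res.number, res.icode, res.name, is_hetero=res.is_hetero)
            by_name: dict[str, Atom] = {}
            for a in res.atoms:
                if policy.remove_hydrogens and a.element in HYDROGEN_ELEMENTS:
                    continue
                if policy.altloc == "all":
                    new_res.atoms.append(a.copy())
                    continue
                if a.atom_name not in by_name:
                    by_name[a.atom_name] = a
                elif (
                    policy.altloc == "highest_occupancy"
                    and a.occupancy > by_name[a.atom_name].occupancy
                ):
                    by_name[a.atom_name] = a
            if policy.altloc != "all":
                kept = set(map(id, by_name.values()))
                for a in res.atoms:
                    if id(a) in kept:
                        new_res.atoms.append(a.copy())
            if new_res.atoms:
                new_chain.residues.append(new_res)
        if new_chain.residues:
            chains.append(new_chain)
    prov = (s.provenance + " | " if s.provenance else "") + f"selected({policy})"
    return Structure(chains, provenance=prov)
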