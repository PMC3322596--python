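"""Restraint construction and evaluation.

A restraint couples one interatomic distance ``r(i,j)`` in a chain (or the
structure under refinement) to the distance between the equivalent atoms
``r(i',j')`` in a related chain (or a fixed target).  The penalty on the
absolute difference ``delta = |r1 - r2|`` is harmonic for small differences,
passes through 1.0 at ``delta = sigma`` and plateaus at ``v_max``:

    V(delta) = v_max * (1 - exp(-alpha * delta**2 / sigma**2))
    alpha    = ln(v_max / (v_max - 1))

so structural differences beyond the plateau carry a fixed, bounded cost.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .equivalence import AtomCorrespondence
from .structure import Atom, Structure
from .topology import (
    SEP_EXCLUDED,
    SEP_ONE_FOUR,
    Topology,
    build_topology,
)

__all__ = [
    "LssrParams",
    "LssrRestraint",
    "RestraintList",
    "delta",
    "lssr_alpha",
    "lssr_penalty",
    "lssr_penalty_derivative",
    "lssr_gradient",
    "enumerate_restraints",
    "total_lssr",
    "total_lssr_gradient",
    "autoncs_weight",
    "restraint_lists_to_records",
    "write_restraints_tsv",
    "read_restraints_tsv",
    "write_restraints_json",
    "read_restraints_json",
]

DEFAULT_SIGMA = 0.2  # Angstrom
DEFAULT_V_MAX = 3.0
DEFAULT_CUTOFF = 5.5  # Angstrom, strict "closer than"


def lssr_alpha(sigma: float, v_max: float) -> float:
    """Normalization constant: the unique alpha with V(sigma) = 1.

    Solving v_max * (1 - exp(-alpha)) = 1 gives
    alpha = ln(v_max / (v_max - 1)).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if v_max <= 1:
        raise ValueError(
            f"v_max must exceed 1 for V(sigma)=1 to be attainable, got {v_max}"
        )
    return math.log(v_max / (v_max - 1.0))


@dataclass(frozen=True)
class LssrParams:
    """Parameters of the penalty and of list construction."""

    sigma: float = DEFAULT_SIGMA
    v_max: float = DEFAULT_V_MAX
    cutoff: float = DEFAULT_CUTOFF
    weight: float = 1.0  # effective per-list weight w_lssr

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.v_max <= 1:
            raise ValueError("v_max must be > 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def alpha(self) -> float:
        return lssr_alpha(self.sigma, self.v_max)

    def with_weight(self, weight: float) -> "LssrParams":
        return replace(self, weight=weight)


def delta(r1: float, r2: float) -> float:
    """Absolute difference between two equivalent interatomic distances."""
    if r1 < 0 or r2 < 0:
        raise ValueError("distances must be nonnegative")
    return abs(r1 - r2)


def lssr_penalty(delta_value, params: LssrParams = LssrParams()):
    """Penalty V(delta); accepts scalars or arrays."""
    d = np.asarray(delta_value, dtype=float)
    if np.any(d < 0):
        raise ValueError("delta must be nonnegative")
    v = params.v_max * (-np.expm1(-params.alpha * d**2 / params.sigma**2))
    return float(v) if np.isscalar(delta_value) else v


def lssr_penalty_derivative(delta_value, params: LssrParams = LssrParams()):
    """dV/d(delta)."""
    d = np.asarray(delta_value, dtype=float)
    a = params.alpha / params.sigma**2
    g = params.v_max * np.exp(-a * d**2) * 2.0 * a * d
    return float(g) if np.isscalar(delta_value) else g


def autoncs_weight(base_weight: float, n_chains: int) -> float:
    """Effective per-list weight for an NCS group of *n_chains* copies.

    Each chain belongs to ``n_chains - 1`` pairwise lists, so dividing the
    base weight by ``n_chains - 1`` keeps the aggregate pull on an atom
    comparable across group sizes; a two-chain group is unadjusted.
    """
    if n_chains < 2:
        raise ValueError(f"an NCS group needs at least 2 chains, got {n_chains}")
    return base_weight / (n_chains - 1)


SEP_CLASS_NAMES = {SEP_ONE_FOUR: "one_four", 2: "nonbonded"}


@dataclass
class LssrRestraint:
    """One four-atom distance-difference restraint.

    ``(atom_i, atom_j)`` live in copy 1, ``(atom_ip, atom_jp)`` are their
    equivalents in copy 2.  The unordered pair identity is
    ``(min(idx_i, idx_j), max(idx_i, idx_j))`` over copy-1 indices.
    """

    atom_i: Atom
    atom_j: Atom
    atom_ip: Atom
    atom_jp: Atom
    idx_i: int
    idx_j: int
    idx_ip: int
    idx_jp: int
    sep_class: str  # 'one_four' | 'nonbonded'
    kind: str  # 'ncs' | 'target'
    r1: float = math.nan
    r2: float = math.nan
    delta: float = math.nan

    @property
    def pair_id(self) -> tuple[int, int]:
        return (min(self.idx_i, self.idx_j), max(self.idx_i, self.idx_j))


class RestraintList:
    """All restraints of one chain pair (or structure/target pair)."""

    def __init__(
        self,
        label: str,
        kind: str,
        restraints: list[LssrRestraint],
        weight: float = 1.0,
    ):
        self.label = label
        self.kind = kind
        self.restraints = restraints
        self.weight = weight
        ids = [r.pair_id for r in restraints]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate unordered (i,j) pairs in list {label}")
        self.idx_i = np.array([r.idx_i for r in restraints], dtype=int)
        self.idx_j = np.array([r.idx_j for r in restraints], dtype=int)
        self.idx_ip = np.array([r.idx_ip for r in restraints], dtype=int)
        self.idx_jp = np.array([r.idx_jp for r in restraints], dtype=int)

    def __len__(self) -> int:
        return len(self.restraints)

    def distances(
        self, coords: np.ndarray, target_coords: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r1, r2, delta) arrays at the given coordinates."""
        if len(self.restraints) == 0:
            z = np.zeros(0)
            return z, z, z
        r1 = np.linalg.norm(coords[self.idx_i] - coords[self.idx_j], axis=1)
        second = coords if self.kind == "ncs" else target_coords
        if second is None:
            raise ValueError("target coordinates required for a target-kind list")
        r2 = np.linalg.norm(second[self.idx_ip] - second[self.idx_jp], axis=1)
        return r1, r2, np.abs(r1 - r2)

    def cache_distances(
        self, coords: np.ndarray, target_coords: np.ndarray | None = None
    ) -> None:
        r1, r2, d = self.distances(coords, target_coords)
        for k, r in enumerate(self.restraints):
            r.r1, r.r2, r.delta = float(r1[k]), float(r2[k]), float(d[k])


def enumerate_restraints(
    corr: AtomCorrespondence,
    structure: Structure,
    params: LssrParams = LssrParams(),
    topology: Topology | None = None,
    target: Structure | None = None,
    weight: float | None = None,
) -> RestraintList:
    """Build the restraint list for one correspondence.

    An unordered copy-1 pair (i, j) is restrained iff both atoms are matched,
    their bond-path separation is at least three bonds (1-4 and beyond), and
    the pair is closer than ``params.cutoff`` in either copy.  Inclusion is
    decided once, here; lists are not re-enumerated during minimization.
    """
    if len(corr.pairs) == 0:
        return RestraintList(
            f"{corr.label_1}:{corr.label_2}", corr.kind, [],
            params.weight if weight is None else weight,
        )
    if corr.kind == "target" and target is None:
        raise ValueError("target structure required for a target-kind correspondence")
    if topology is None:
        topology = build_topology(structure)

    atoms_1 = [a for a, _ in corr.pairs]
    atoms_2 = [b for _, b in corr.pairs]
    idx_1 = np.array([structure.atom_index(a) for a in atoms_1], dtype=int)
    second = structure if corr.kind == "ncs" else target
    idx_2 = np.array([second.atom_index(b) for b in atoms_2], dtype=int)
    pos_1 = np.array([a.position for a in atoms_1])
    pos_2 = np.array([b.position for b in atoms_2])

    candidates: set[tuple[int, int]] = set()
    for pos in (pos_1, pos_2):
        tree = cKDTree(pos)
        candidates |= set(map(tuple, tree.query_pairs(params.cutoff, output_type="set")))

    restraints: list[LssrRestraint] = []
    seen: set[tuple[int, int]] = set()
    for k, l in candidates:
        gi, gj = int(idx_1[k]), int(idx_1[l])
        if gj < gi:
            k, l = l, k
            gi, gj = gj, gi
        if (gi, gj) in seen:
            continue
        sep = topology.separation_class(gi, gj)
        if sep == SEP_EXCLUDED:
            continue
        r1 = float(np.linalg.norm(pos_1[k] - pos_1[l]))
        r2 = float(np.linalg.norm(pos_2[k] - pos_2[l]))
        if not (r1 < params.cutoff or r2 < params.cutoff):
            continue
        seen.add((gi, gj))
        restraints.append(
            LssrRestraint(
                atom_i=atoms_1[k],
                atom_j=atoms_1[l],
                atom_ip=atoms_2[k],
                atom_jp=atoms_2[l],
                idx_i=gi,
                idx_j=gj,
                idx_ip=int(idx_2[k]),
                idx_jp=int(idx_2[l]),
                sep_class=SEP_CLASS_NAMES[SEP_ONE_FOUR] if sep == SEP_ONE_FOUR
                else "nonbonded",
                kind=corr.kind,
                r1=r1,
                r2=r2,
                delta=abs(r1 - r2),
            )
        )
    restraints.sort(key=lambda r: (r.idx_i, r.idx_j))
    return RestraintList(
        f"{corr.label_1}:{corr.label_2}",
        corr.kind,
        restraints,
        params.weight if weight is None else weight,
    )


def lssr_gradient(
    restraint: LssrRestraint,
    coords: np.ndarray,
    params: LssrParams = LssrParams(),
    target_coords: np.ndarray | None = None,
    weight: float = 1.0,
) -> dict[int, np.ndarray]:
    """Analytic gradient of ``weight * V(delta)`` for one restraint.

    Returns a mapping of mobile-atom index to its 3-vector gradient.  For
    NCS restraints all four atoms are mobile and the vectors sum to zero
    (translation invariance); for target restraints only copy-1 atoms move.
    """
    xi, xj = coords[restraint.idx_i], coords[restraint.idx_j]
    second = coords if restraint.kind == "ncs" else target_coords
    if second is None:
        raise ValueError("target coordinates required")
    xip, xjp = second[restraint.idx_ip], second[restraint.idx_jp]
    r1 = float(np.linalg.norm(xi - xj))
    r2 = float(np.linalg.norm(xip - xjp))
    d = abs(r1 - r2)
    dv = weight * lssr_penalty_derivative(d, params)
    s = np.sign(r1 - r2)
    out: dict[int, np.ndarray] = {
        restraint.idx_i: np.zeros(3),
        restraint.idx_j: np.zeros(3),
    }
    if r1 > 0:
        g1 = dv * s * (xi - xj) / r1
        out[restraint.idx_i] += g1
        out[restraint.idx_j] -= g1
    if restraint.kind == "ncs":
        out.setdefault(restraint.idx_ip, np.zeros(3))
        out.setdefault(restraint.idx_jp, np.zeros(3))
        if r2 > 0:
            g2 = -dv * s * (xip - xjp) / r2
            out[restraint.idx_ip] += g2
            out[restraint.idx_jp] -= g2
    return out


def total_lssr(
    lists,
    coords: np.ndarray,
    params: LssrParams = LssrParams(),
    target_coords: np.ndarray | None = None,
):
    """Weighted total penalty and per-restraint breakdown.

    Returns ``(total, breakdown)`` where breakdown maps each list label to a
    dict with the list weight and the per-restraint penalty array (already
    multiplied by the list weight).
    """
    if isinstance(lists, RestraintList):
        lists = [lists]
    total = 0.0
    breakdown: dict[str, dict] = {}
    for rl in lists:
        _, _, d = rl.distances(coords, target_coords)
        v = lssr_penalty(d, params) if len(d) else np.zeros(0)
        contrib = rl.weight * v
        total += float(contrib.sum())
        breakdown[rl.label] = {
            "weight": rl.weight,
            "penalties": contrib,
            "unweighted": v,
            "delta": d,
        }
    return total, breakdown


def total_lssr_gradient(
    lists,
    coords: np.ndarray,
    params: LssrParams = LssrParams(),
    target_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of :func:`total_lssr` with respect to *coords* (vectorized)."""
    if isinstance(lists, RestraintList):
        lists = [lists]
    grad = np.zeros_like(coords)
    for rl in lists:
        if len(rl) == 0:
            continue
        r1, r2, d = rl.distances(coords, target_coords)
        dv = rl.weight * lssr_penalty_derivative(d, params)
        s = np.sign(r1 - r2)
        safe_r1 = np.where(r1 > 0, r1, 1.0)
        g1 = (dv * s / safe_r1 * (r1 > 0))[:, None] * (
            coords[rl.idx_i] - coords[rl.idx_j]
        )
        np.add.at(grad, rl.idx_i, g1)
        np.add.at(grad, rl.idx_j, -g1)
        if rl.kind == "ncs":
            safe_r2 = np.where(r2 > 0, r2, 1.0)
            g2 = (-dv * s / safe_r2 * (r2 > 0))[:, None] * (
                coords[rl.idx_ip] - coords[rl.idx_jp]
            )
            np.add.at(grad, rl.idx_ip, g2)
            np.add.at(grad, rl.idx_jp, -g2)
    return grad


# ---------------------------------------------------------------------------
# Restraint-list serialization (TSV and JSON, bit-exact round trip)
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "chain_pair", "kind",
    "i_chain", "i_resnum", "i_icode", "i_atom",
    "j_chain", "j_resnum", "j_icode", "j_atom",
    "ip_chain", "ip_resnum", "ip_icode", "ip_atom",
    "jp_chain", "jp_resnum", "jp_icode", "jp_atom",
    "class", "r1", "r2", "delta", "penalty", "weight",
]


def restraint_lists_to_records(
    lists, params: LssrParams = LssrParams()
) -> list[dict]:
    if isinstance(lists, RestraintList):
        lists = [lists]
    records = []
    for rl in lists:
        for r in rl.restraints:
            rec = {"chain_pair": rl.label, "kind": rl.kind}
            for prefix, atom in (
                ("i", r.atom_i), ("j", r.atom_j), ("ip", r.atom_ip), ("jp", r.atom_jp)
            ):
                rec[f"{prefix}_chain"] = atom.chain_id
                rec[f"{prefix}_resnum"] = atom.residue_number
                rec[f"{prefix}_icode"] = atom.icode.strip() or "."
                rec[f"{prefix}_atom"] = atom.atom_name
            rec["class"] = r.sep_class
            rec["r1"] = r.r1
            rec["r2"] = r.r2
            rec["delta"] = r.delta
            rec["penalty"] = lssr_penalty(r.delta, params)
            rec["weight"] = rl.weight
            records.append(rec)
    return records


def _records_to_tsv_text(records: list[dict]) -> str:
    lines = ["\t".join(TSV_COLUMNS)]
    for rec in records:
        cells = []
        for col in TSV_COLUMNS:
            val = rec[col]
            cells.append(repr(val) if isinstance(val, float) else str(val))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_restraints_tsv(lists, path, params: LssrParams = LssrParams()) -> None:
    records = lists if isinstance(lists, list) and (
        not lists or isinstance(lists[0], dict)
    ) else restraint_lists_to_records(lists, params)
    with open(path, "w") as fh:
        fh.write(_records_to_tsv_text(records))


_INT_COLS = {"i_resnum", "j_resnum", "ip_resnum", "jp_resnum"}
_FLOAT_COLS = {"r1", "r2", "delta", "penalty", "weight"}


def read_restraints_tsv(path) -> list[dict]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected restraint TSV header in {path}")
        records = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            rec = {}
            for col, cell in zip(TSV_COLUMNS, cells):
                if col in _INT_COLS:
                    rec[col] = int(cell)
                elif col in _FLOAT_COLS:
                    rec[col] = float(cell)
                else:
                    rec[col] = cell
            records.append(rec)
    return records


def write_restraints_json(lists, path, params: LssrParams = LssrParams()) -> None:
    records = lists if isinstance(lists, list) and (
        not lists or isinstance(lists[0], dict)
    ) else restraint_lists_to_records(lists, params)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def read_restraints_json(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
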