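"""Synthetic test structures, a toy restrained minimizer and the
finite-difference gradient oracle.

Fixtures are idealized extended peptide chains duplicated into several
NCS copies with identical numbering, with controlled per-copy coordinate
noise, deliberate outlier displacements and side-chain label flips — enough
to exercise detection, enumeration, pruning, swapping and minimization with
no external files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import LssrParams, total_lssr, total_lssr_gradient
from .equivalence import SWAP_PAIRS_STANDARD
from .structure import Atom, Chain, Residue, Structure
from .topology import Topology, build_topology

__all__ = [
    "FixtureSpec",
    "generate_ncs_fixture",
    "BondedTerm",
    "harmonic_bond_term",
    "minimize_lssr",
    "finite_difference_check",
]

# Idealized internal coordinates for the toy builder (lengths in Angstrom,
# angles/torsions in degrees).  Values are conventional heavy-atom geometry;
# they only need to be realistic enough for template/distance bonding.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

PHI, PSI, OMEGA = -140.0, 135.0, 180.0

SUPPORTED_RESIDUES = ("ALA", "SER", "PHE", "ASP", "VAL", "GLY")
DEFAULT_SEQUENCE_CYCLE = ("ALA", "SER", "PHE", "ASP", "VAL")


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom d bonded to c, with angle b-c-d and torsion
    a-b-c-d."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _sidechain(name: str, n, ca, cb, c) -> list[tuple[str, str, np.ndarray]]:
    """(atom_name, element, position) beyond CB for supported residue types."""
    out = []
    if name == "SER":
        out.append(("OG", "O", _place(n, ca, cb, 1.417, 110.8, -65.0)))
    elif name == "VAL":
        out.append(("CG1", "C", _place(n, ca, cb, 1.521, 110.5, -60.0)))
        out.append(("CG2", "C", _place(n, ca, cb, 1.521, 110.5, 62.0)))
    elif name == "ASP":
        cg = _place(n, ca, cb, 1.516, 112.6, -65.0)
        out.append(("CG", "C", cg))
        out.append(("OD1", "O", _place(ca, cb, cg, 1.249, 118.4, -20.0)))
        out.append(("OD2", "O", _place(ca, cb, cg, 1.249, 118.4, 160.0)))
    elif name == "PHE":
        cg = _place(n, ca, cb, 1.502, 113.8, -65.0)
        cd1 = _place(ca, cb, cg, 1.384, 120.8, 80.0)
        cd2 = _place(ca, cb, cg, 1.384, 120.8, -100.0)
        ce1 = _place(cb, cg, cd1, 1.382, 121.0, 180.0)
        ce2 = _place(cb, cg, cd2, 1.382, 121.0, 180.0)
        cz = _place(cg, cd1, ce1, 1.382, 120.0, 0.0)
        out += [
            ("CG", "C", cg), ("CD1", "C", cd1), ("CD2", "C", cd2),
            ("CE1", "C", ce1), ("CE2", "C", ce2), ("CZ", "C", cz),
        ]
    return out


def _build_template_chain(sequence: list[str]) -> list[list[tuple[str, str, np.ndarray]]]:
    """Build one idealized extended chain; returns per-residue atom tuples."""
    residues = []
    # seed the first three backbone atoms
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    prev_n, prev_ca, prev_c = n0, ca0, c0
    for k, name in enumerate(sequence):
        if name not in SUPPORTED_RESIDUES:
            raise ValueError(f"unsupported residue type {name!r} in fixture")
        if k == 0:
            n, ca, c = n0, ca0, c0
        else:
            n = _place(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, PSI)
            ca = _place(prev_ca, prev_c, n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c = _place(prev_c, n, ca, BOND_CA_C, ANGLE_N_CA_C, PHI)
        o = _place(n, ca, c, BOND_C_O, ANGLE_CA_C_O, PSI + 180.0)
        atoms = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]
        if name != "GLY":
            cb = _place(c, n, ca, BOND_CA_CB, 110.5, 122.5)
            atoms.append(("CB", "C", cb))
            atoms += _sidechain(name, n, ca, cb, c)
        residues.append(atoms)
        prev_n, prev_ca, prev_c = n, ca, c
    return residues


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic NCS fixture."""

    n_residues: int = 10
    n_chains: int = 2
    noise_sd: float = 0.0  # Angstrom, per atom per copy
    outliers: list[tuple[int, float]] = field(default_factory=list)
    label_flips: list[int] = field(default_factory=list)
    sequence: list[str] | None = None
    seed: int = 0
    chain_spacing: float = 30.0  # Angstrom between copies

    def resolved_sequence(self) -> list[str]:
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues:
                raise ValueError("sequence length must equal n_residues")
            return list(self.sequence)
        cyc = DEFAULT_SEQUENCE_CYCLE
        return [cyc[i % len(cyc)] for i in range(self.n_residues)]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            data = json.load(fh)
        data["outliers"] = [tuple(o) for o in data.get("outliers", [])]
        return cls(**data)


def generate_ncs_fixture(spec: FixtureSpec) -> Structure:
    """Build a multi-copy fixture structure; bit-identical for a given spec."""
    sequence = spec.resolved_sequence()
    valid_numbers = set(range(1, spec.n_residues + 1))
    for resnum, _ in spec.outliers:
        if resnum not in valid_numbers:
            raise ValueError(f"outlier displacement on nonexistent residue {resnum}")
    for resnum in spec.label_flips:
        if resnum not in valid_numbers:
            raise ValueError(f"label flip on nonexistent residue {resnum}")

    template = _build_template_chain(sequence)
    rng = np.random.default_rng(spec.seed)
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
    chains = []
    for copy_idx, cid in enumerate(chain_ids):
        offset = np.array([spec.chain_spacing * copy_idx, 0.0, 0.0])
        chain = Chain(cid)
        for resnum, (name, atoms) in enumerate(zip(sequence, template), start=1):
            res = Residue(resnum, " ", name)
            for atom_name, element, pos in atoms:
                res.atoms.append(
                    Atom(
                        chain_id=cid,
                        residue_number=resnum,
                        icode=" ",
                        residue_name=name,
                        atom_name=atom_name,
                        element=element,
                        position=pos + offset,
                    )
                )
            chain.residues.append(res)
        if spec.noise_sd > 0:
            for res in chain.residues:
                for a in res.atoms:
                    a.position = a.position + rng.normal(0.0, spec.noise_sd, 3)
        if copy_idx > 0:
            for resnum, magnitude in spec.outliers:
                res = chain.residue(resnum)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                for a in res.atoms:
                    a.position = a.position + magnitude * direction
            if copy_idx == 1:
                for resnum in spec.label_flips:
                    res = chain.residue(resnum)
                    for n1, n2 in SWAP_PAIRS_STANDARD.get(res.name, []):
                        a1, a2 = res.atom(n1), res.atom(n2)
                        if a1 is not None and a2 is not None:
                            a1.atom_name, a2.atom_name = n2, n1
        chains.append(chain)
    return Structure(chains, provenance=f"synthetic fixture seed={spec.seed}")


# ---------------------------------------------------------------------------
# Toy bonded term and minimizer
# ---------------------------------------------------------------------------

@dataclass
class BondedTerm:
    """Harmonic bond restraints sum(k * (b - b0)**2) over the bond graph."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    ideal: np.ndarray
    force_constant: float = 500.0

    def energy(self, coords: np.ndarray) -> float:
        b = np.linalg.norm(coords[self.idx_a] - coords[self.idx_b], axis=1)
        return float(self.force_constant * np.sum((b - self.ideal) ** 2))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(coords)
        diff = coords[self.idx_a] - coords[self.idx_b]
        b = np.linalg.norm(diff, axis=1)
        safe = np.where(b > 0, b, 1.0)
        g = (2.0 * self.force_constant * (b - self.ideal) / safe)[:, None] * diff
        np.add.at(grad, self.idx_a, g)
        np.add.at(grad, self.idx_b, -g)
        return grad


def harmonic_bond_term(
    s: Structure,
    topology: Topology | None = None,
    force_constant: float = 500.0,
    ideal: str = "current",
) -> BondedTerm:
    """Bonded term over the structure's bond graph.

    Ideal lengths are captured from the current coordinates (keeps covalent
    geometry as-built while LSSR pulls on nonbonded differences).
    """
    if topology is None:
        topology = build_topology(s)
    if ideal != "current":
        raise ValueError("only 'current' ideal lengths are supported")
    coords = s.coords()
    idx_a = np.array([i for i, _ in topology.bonds], dtype=int)
    idx_b = np.array([j for _, j in topology.bonds], dtype=int)
    b0 = np.linalg.norm(coords[idx_a] - coords[idx_b], axis=1)
    return BondedTerm(idx_a, idx_b, b0, force_constant)


def minimize_lssr(
    s: Structure,
    lists,
    params: LssrParams = LssrParams(),
    bonded_term: BondedTerm | None = None,
    steps: int = 200,
    step_size: float = 1e-3,
    target_coords: np.ndarray | None = None,
) -> tuple[Structure, list[float]]:
    """Gradient descent with backtracking on LSSR + optional bonded energy.

    Returns a new structure and the trace of accepted energies (which is
    non-increasing by construction).  Diverging (NaN) energies raise with the
    trace attached.
    """
    if steps < 1:
        raise ValueError("step count must be >= 1")

    def energy(x):
        e, _ = total_lssr(lists, x, params, target_coords)
        if bonded_term is not None:
            e += bonded_term.energy(x)
        return e

    def gradient(x):
        g = total_lssr_gradient(lists, x, params, target_coords)
        if bonded_term is not None:
            g = g + bonded_term.gradient(x)
        return g

    x = s.coords()
    e = energy(x)
    trace = [e]
    step = step_size
    for _ in range(steps):
        g = gradient(x)
        gnorm = float(np.max(np.abs(g)))
        if gnorm < 1e-12:
            break
        accepted = False
        for _try in range(30):
            x_new = x - step * g
            e_new = energy(x_new)
            if np.isnan(e_new):
                err = RuntimeError("minimization diverged (energy is NaN)")
                err.trace = trace  # type: ignore[attr-defined]
                raise err
            if e_new <= e:
                x, e = x_new, e_new
                trace.append(e)
                step = min(step * 1.5, 1.0)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    out = s.copy()
    out.set_coords(x)
    return out, trace


def finite_difference_check(
    lists,
    coords: np.ndarray,
    params: LssrParams = LssrParams(),
    h: float = 1e-5,
    target_coords: np.ndarray | None = None,
) -> float:
    """Worst relative error of the analytic gradient against central
    differences of the total energy, over all mobile coordinates."""

    def energy(x):
        e, _ = total_lssr(lists, x, params, target_coords)
        return e

    analytic = total_lssr_gradient(lists, coords, params, target_coords)
    fd = np.zeros_like(analytic)
    x = coords.copy()
    for i in range(coords.shape[0]):
        for k in range(3):
            orig = x[i, k]
            x[i, k] = orig + h
            e_plus = energy(x)
            x[i, k] = orig - h
            e_minus = energy(x)
            x[i, k] = orig
            fd[i, k] = (e_plus - e_minus) / (2.0 * h)
    scale = max(float(np.max(np.abs(analytic))), 1.0)
    return float(np.max(np.abs(fd - analytic)) / scale)
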