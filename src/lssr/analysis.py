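"""Similarity diagnostics: distance-difference histograms and per-atom
contact comparison tables."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

from .core import LssrParams, RestraintList, enumerate_restraints
from .equivalence import match_atoms
from .structure import Structure
from .topology import Topology

__all__ = ["DeltaHistogram", "delta_histogram", "contact_report", "round_half_even"]


def round_half_even(x: float, ndigits: int) -> float:
    """Banker's rounding on the decimal representation of *x*."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class DeltaHistogram:
    """Histogram of distance differences, first bin [0, bin_width)."""

    bin_width: float
    edges: np.ndarray  # left edges, starting at 0; final bin open
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        assert int(self.counts.sum()) == self.total

    def to_frame(self) -> pd.DataFrame:
        uppers = [
            f"{e + self.bin_width:.3g}" for e in self.edges[:-1]
        ] + ["inf"]
        return pd.DataFrame(
            {
                "bin_lower": self.edges,
                "bin_upper": uppers,
                "count": self.counts,
                "fraction": self.counts / max(self.total, 1),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(self.edges, self.counts, width=self.bin_width * 0.9, align="edge")
        ax.set_xlabel("distance difference (Å)")
        ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def delta_histogram(
    lists,
    coords: np.ndarray,
    bin_width: float = 0.1,
    target_coords: np.ndarray | None = None,
    n_bins: int | None = None,
) -> DeltaHistogram:
    """Histogram of all delta values pooled across the supplied lists.

    With *n_bins* given, the final bin is open (collects everything at or
    above its left edge); otherwise bins extend to cover the maximum value.
    """
    if isinstance(lists, RestraintList):
        lists = [lists]
    lists = list(lists)
    deltas: list[np.ndarray] = []
    for rl in lists:
        _, _, d = rl.distances(coords, target_coords)
        if len(d):
            deltas.append(d)
    if not deltas:
        raise ValueError("no restraints supplied to delta_histogram")
    values = np.concatenate(deltas)
    if n_bins is None:
        n_bins = max(1, int(np.floor(values.max() / bin_width)) + 1)
    idx = np.minimum((values / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins) * bin_width
    return DeltaHistogram(
        bin_width=bin_width, edges=edges, counts=counts, total=len(values)
    )


def _parse_focus(focus) -> tuple[int, str, str]:
    """Focus selector: (resnum, icode, atom_name) or 'A102/OG' style string
    ('102/OG', '102A/OG' with icode)."""
    if isinstance(focus, tuple):
        if len(focus) == 3:
            return int(focus[0]), focus[1] or " ", focus[2]
        return int(focus[0]), " ", focus[1]
    text = str(focus)
    respart, atom = text.split("/")
    respart = respart.strip()
    i = 0
    while i < len(respart) and not respart[i].isdigit():
        i += 1  # tolerate a leading chain letter; chain comes from chain_pair
    digits = ""
    while i < len(respart) and respart[i].isdigit():
        digits += respart[i]
        i += 1
    icode = respart[i:].strip() or " "
    return int(digits), icode, atom.strip()


def contact_report(
    s: Structure,
    chain_pair: tuple[str, str],
    focus,
    cutoff: float = 5.5,
    params: LssrParams | None = None,
    topology: Topology | None = None,
) -> pd.DataFrame:
    """Per-atom contact comparison between two related chains.

    One row per restrained partner of the focus atom: partner label and
    distance in each copy (3 d.p., half-even) and the difference, computed on
    unrounded distances and then rounded to 2 d.p.
    """
    chain_a, chain_b = chain_pair
    resnum, icode, atom_name = _parse_focus(focus)
    res = s.chain(chain_a).residue(resnum, icode)
    if res is None or res.atom(atom_name) is None:
        raise ValueError(
            f"focus atom {chain_a}{resnum}/{atom_name} not found in chain {chain_a}"
        )
    focus_atom = res.atom(atom_name)
    if params is None:
        params = LssrParams(cutoff=cutoff)
    else:
        params = LssrParams(
            sigma=params.sigma, v_max=params.v_max, cutoff=cutoff,
            weight=params.weight,
        )
    corr = match_atoms(s, chain_a, chain_b)
    if not any(id(a) == id(focus_atom) for a, _ in corr.pairs):
        raise ValueError(
            f"focus atom {chain_a}{resnum}/{atom_name} has no equivalent in "
            f"chain {chain_b}"
        )
    rl = enumerate_restraints(corr, s, params, topology=topology)
    rows = []
    fid = id(focus_atom)
    for r in rl.restraints:
        if id(r.atom_i) == fid:
            partner, partner_p = r.atom_j, r.atom_jp
        elif id(r.atom_j) == fid:
            partner, partner_p = r.atom_i, r.atom_ip
        else:
            continue
        rows.append(
            {
                "atom_j": partner.label(),
                "r1": round_half_even(r.r1, 3),
                "atom_jp": partner_p.label(),
                "r2": round_half_even(r.r2, 3),
                "delta": round_half_even(r.delta, 2),
                "class": r.sep_class,
            }
        )
    rows.sort(key=lambda row: row["r1"])
    return pd.DataFrame(
        rows, columns=["atom_j", "r1", "atom_jp", "r2", "delta", "class"]
    )
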