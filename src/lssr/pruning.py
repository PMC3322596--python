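"""Automatic restraint-list pruning.

Residues whose conformations are genuinely distinct between copies are
removed from the lists.  Two rules: the plateau-ratio rule (total residue
penalty compared with the maximum possible if every touching restraint sat in
the plateau; above 0.5 the residue's environments are distinct) and an
optional gradient rule for residues that are distinct but similar, flagged by
an anomalously large mean gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import (
    LssrParams,
    RestraintList,
    lssr_penalty,
    total_lssr_gradient,
)

__all__ = ["PruneReport", "plateau_ratio", "prune"]

DEFAULT_RATIO_THRESHOLD = 0.5
DEFAULT_GRADIENT_K = 5.0

ResidueKey = tuple[str, int, str]  # (chain_id, residue_number, icode)


def _restraint_residues(restraint) -> set[ResidueKey]:
    """Residues a restraint touches.

    For NCS restraints all four atoms live in the structure under refinement;
    for target restraints only the copy-1 atoms do (the target is immutable
    and its residues are never pruned).
    """
    atoms = [restraint.atom_i, restraint.atom_j]
    if restraint.kind == "ncs":
        atoms += [restraint.atom_ip, restraint.atom_jp]
    return {a.residue_key for a in atoms}


def _collect(lists):
    if isinstance(lists, RestraintList):
        lists = [lists]
    return list(lists)


def _residue_tables(lists, coords, params, target_coords):
    """Per-residue penalty sums and restraint counts (unweighted V)."""
    sums: dict[ResidueKey, float] = {}
    counts: dict[ResidueKey, int] = {}
    for rl in lists:
        _, _, d = rl.distances(coords, target_coords)
        v = lssr_penalty(d, params) if len(d) else np.zeros(0)
        for k, r in enumerate(rl.restraints):
            for key in _restraint_residues(r):
                sums[key] = sums.get(key, 0.0) + float(v[k])
                counts[key] = counts.get(key, 0) + 1
    return sums, counts


def plateau_ratio(
    residue_key: ResidueKey,
    lists,
    coords: np.ndarray,
    params: LssrParams = LssrParams(),
    target_coords: np.ndarray | None = None,
) -> float | None:
    """Ratio of the residue's summed penalty to its plateau maximum.

    ``sum(V) / (v_max * n_restraints)`` over restraints touching any atom of
    the residue; in [0, 1].  None when the residue has no restraints.
    """
    lists = _collect(lists)
    sums, counts = _residue_tables(lists, coords, params, target_coords)
    if residue_key not in counts:
        return None
    return sums[residue_key] / (params.v_max * counts[residue_key])


@dataclass
class PruneReport:
    """Every per-residue decision made by :func:`prune`."""

    residues: dict[ResidueKey, dict] = field(default_factory=dict)
    n_restraints_before: int = 0
    n_restraints_after: int = 0
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    gradient_k: float | None = None

    @property
    def n_restraints_removed(self) -> int:
        return self.n_restraints_before - self.n_restraints_after

    def pruned_residues(self) -> list[ResidueKey]:
        return [
            key for key, rec in self.residues.items()
            if rec["decision"] != "kept"
        ]

    def to_records(self) -> list[dict]:
        out = []
        for (chain, num, icode), rec in sorted(self.residues.items()):
            out.append(
                {
                    "chain": chain,
                    "residue_number": num,
                    "icode": icode.strip() or ".",
                    "plateau_ratio": rec["ratio"],
                    "mean_gradient": rec["mean_gradient"],
                    "decision": rec["decision"],
                }
            )
        return out

    def write_tsv(self, path) -> None:
        cols = ["chain", "residue_number", "icode", "plateau_ratio",
                "mean_gradient", "decision"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for rec in self.to_records():
                fh.write(
                    "\t".join(
                        repr(rec[c]) if isinstance(rec[c], float) else str(rec[c])
                        for c in cols
                    )
                    + "\n"
                )

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ratio_threshold": self.ratio_threshold,
                    "gradient_k": self.gradient_k,
                    "n_restraints_before": self.n_restraints_before,
                    "n_restraints_after": self.n_restraints_after,
                    "residues": self.to_records(),
                },
                fh,
                indent=1,
            )
            fh.write("\n")


def _filter_lists(lists, pruned: set[ResidueKey]) -> list[RestraintList]:
    out = []
    for rl in lists:
        kept = [
            r for r in rl.restraints if not (_restraint_residues(r) & pruned)
        ]
        out.append(RestraintList(rl.label, rl.kind, kept, rl.weight))
    return out


def prune(
    lists,
    coords: np.ndarray,
    params: LssrParams = LssrParams(),
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    gradient_k: float | None = None,
    target_coords: np.ndarray | None = None,
) -> tuple[list[RestraintList], PruneReport]:
    """Two-stage pruning; returns new lists and a full report.

    Stage 1 removes every restraint touching a residue whose plateau ratio is
    strictly above *ratio_threshold*.  Stage 2 (enabled by passing
    *gradient_k*) removes surviving residues whose mean per-atom gradient
    magnitude exceeds ``gradient_k`` times the structure-wide median.  The
    decision is evaluated once, at the supplied coordinates.
    """
    lists = _collect(lists)
    report = PruneReport(
        n_restraints_before=sum(len(rl) for rl in lists),
        ratio_threshold=ratio_threshold,
        gradient_k=gradient_k,
    )

    sums, counts = _residue_tables(lists, coords, params, target_coords)
    pruned: set[ResidueKey] = set()
    for key in counts:
        ratio = sums[key] / (params.v_max * counts[key])
        decision = "kept"
        if ratio > ratio_threshold:
            decision = "pruned_ratio"
            pruned.add(key)
        report.residues[key] = {
            "ratio": ratio,
            "mean_gradient": float("nan"),
            "decision": decision,
        }
    stage1 = _filter_lists(lists, pruned)

    if gradient_k is not None:
        grad = total_lssr_gradient(stage1, coords, params, target_coords)
        mags = np.linalg.norm(grad, axis=1)
        # mean over the residue's atoms that still participate in a restraint
        atom_sets: dict[ResidueKey, set[int]] = {}
        for rl in stage1:
            for r in rl.restraints:
                pairs = [(r.atom_i, r.idx_i), (r.atom_j, r.idx_j)]
                if r.kind == "ncs":
                    pairs += [(r.atom_ip, r.idx_ip), (r.atom_jp, r.idx_jp)]
                for atom, idx in pairs:
                    atom_sets.setdefault(atom.residue_key, set()).add(idx)
        mean_grad = {
            key: float(np.mean([mags[i] for i in idxs]))
            for key, idxs in atom_sets.items()
        }
        for key, mg in mean_grad.items():
            if key in report.residues:
                report.residues[key]["mean_gradient"] = mg
        if mean_grad:
            median = float(np.median(list(mean_grad.values())))
            if median > 0:
                for key, mg in mean_grad.items():
                    if mg > gradient_k * median:
                        report.residues[key]["decision"] = "pruned_gradient"
                        pruned.add(key)

    final = _filter_lists(lists, pruned)
    report.n_restraints_after = sum(len(rl) for rl in final)
    return final, report
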