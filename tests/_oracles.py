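"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's vectorized evaluation and shell-based
separation logic: pair enumeration is a plain O(n^2) double loop, bond-path
separations come from networkx breadth-first search, and distances use the
coordinate-wise formula.
"""

import math

import networkx as nx


def brute_force_distance(p, q):
    return math.sqrt(
        (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2
    )


def brute_force_pairs(corr, structure, bonds, cutoff):
    """All unordered matched pairs with bond-path separation >= 3 and
    distance < cutoff in either copy.

    Returns a set of (idx_i, idx_j) over the structure's flat atom order,
    plus the separation class ('one_four' or 'nonbonded') per pair.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(structure.atoms())))
    graph.add_edges_from(bonds)
    # all path lengths up to 3 bonds
    seps = {}
    for node in graph.nodes:
        for other, length in nx.single_source_shortest_path_length(
            graph, node, cutoff=3
        ).items():
            seps[(node, other)] = length

    pairs = {}
    matched = list(corr.pairs)
    for a_idx in range(len(matched)):
        for b_idx in range(a_idx + 1, len(matched)):
            a1, a2 = matched[a_idx]
            b1, b2 = matched[b_idx]
            gi = structure.atom_index(a1)
            gj = structure.atom_index(b1)
            sep = seps.get((min(gi, gj), max(gi, gj)))
            if sep is not None and sep < 3:
                continue
            r1 = brute_force_distance(a1.position, b1.position)
            r2 = brute_force_distance(a2.position, b2.position)
            if not (r1 < cutoff or r2 < cutoff):
                continue
            cls = "one_four" if sep == 3 else "nonbonded"
            pairs[(min(gi, gj), max(gi, gj))] = cls
    return pairs


def brute_force_total(restraints, sigma, v_max, weight=1.0):
    """Scalar re-summation of per-restraint penalties."""
    alpha = math.log(v_max / (v_max - 1.0))
    total = 0.0
    for r in restraints:
        d = abs(r.r1 - r.r2)
        total += weight * v_max * (1.0 - math.exp(-alpha * d * d / (sigma * sigma)))
    return total
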