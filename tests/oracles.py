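"""Independent brute-force oracles.

These deliberately avoid the package's computational paths: the pair
energy is an explicit 9-term double loop over charge sites, the edge
oracle compares every pair without a KD-tree, and the ring oracle
enumerates Hamiltonian cycles over all vertex subsets.  They are slow
and only used on tiny inputs.
"""

from __future__ import annotations

import itertools
import math

# TIP3P constants, written out independently of the package defaults
_A = 582000.0
_C = 595.0
_KE = 332.0636
_Q = {"O": -0.834, "H": 0.417}


def pair_energy_oracle(sites_a, sites_b) -> float:
    """Explicit 9-term Coulomb sum plus the O-O Lennard-Jones term.

    ``sites_a``/``sites_b`` are sequences of (element, (x, y, z))
    with the oxygen first.
    """
    energy = 0.0
    for el_i, pi in sites_a:
        for el_j, pj in sites_b:
            r = math.dist(pi, pj)
            energy += _KE * _Q[el_i] * _Q[el_j] / r
    r_oo = math.dist(sites_a[0][1], sites_b[0][1])
    return energy + _A / r_oo**12 - _C / r_oo**6


def water_sites(water):
    """Package WaterMolecule -> oracle site list."""
    sites = [("O", tuple(water.o_position))]
    sites += [("H", tuple(h)) for h in water.h_positions]
    return sites


def all_pairs_edges(waters, mode="distance", oo_cutoff=3.5, energy_cutoff=-2.25):
    """Naive all-pairs edge set under the requested criterion."""
    edges = set()
    for a, b in itertools.combinations(waters, 2):
        r_oo = math.dist(tuple(a.o_position), tuple(b.o_position))
        if mode == "distance":
            if r_oo < oo_cutoff:
                edges.add(tuple(sorted((a.water_id, b.water_id))))
        else:
            e = pair_energy_oracle(water_sites(a), water_sites(b))
            if e <= energy_cutoff:
                edges.add(tuple(sorted((a.water_id, b.water_id))))
    return edges


def _canonical(cycle):
    n = len(cycle)
    best = None
    for seq in (list(cycle), list(cycle)[::-1]):
        for s in range(n):
            cand = tuple(seq[s:] + seq[:s])
            if best is None or cand < best:
                best = cand
    return best


def brute_force_rings(nodes, edges, sizes=(3, 4, 5, 6), policy="chordless"):
    """All cycles of the requested sizes, by subset + permutation search.

    For every vertex subset of each size, every distinct Hamiltonian
    cycle of the subset is found by fixing the smallest vertex first
    and permuting the rest; duplicates collapse under canonical
    rotation/reflection.  Under the chordless policy a cycle is kept
    only if the subset induces no extra edge.
    """
    edge_set = {tuple(sorted(e)) for e in edges}

    def is_edge(u, v):
        return tuple(sorted((u, v))) in edge_set

    found = set()
    nodes = sorted(nodes)
    for size in sorted(sizes):
        for subset in itertools.combinations(nodes, size):
            induced = sum(
                1 for u, v in itertools.combinations(subset, 2) if is_edge(u, v)
            )
            if induced < size:
                continue  # not enough edges for any Hamiltonian cycle
            if policy == "chordless" and induced != size:
                continue
            first = subset[0]
            rest = subset[1:]
            for perm in itertools.permutations(rest):
                cycle = (first,) + perm
                if all(
                    is_edge(cycle[i], cycle[(i + 1) % size]) for i in range(size)
                ):
                    found.add(_canonical(cycle))
    return found


def random_graph(rng, n, p):
    """Erdos-Renyi style edge list on nodes 0..n-1."""
    nodes = list(range(n))
    edges = [
        (i, j)
        for i, j in itertools.combinations(nodes, 2)
        if rng.random() < p
    ]
    return nodes, edges
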