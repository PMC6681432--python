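"""Water-water hydrogen-bond criteria and the hydrogen-bond graph.

Two criteria are supported:

* **energy** -- the rigid TIP3P pair potential: nine site-site Coulomb
  terms plus one oxygen-oxygen Lennard-Jones term,

  .. math::

     v(a,b) = \\sum_{i \\in a}\\sum_{j \\in b}
              \\frac{k_e\\, q_i q_j}{r_{ij}}
              + \\frac{A}{r_{OO}^{12}} - \\frac{C}{r_{OO}^{6}},

  with a hydrogen bond declared when :math:`v(a,b) \\le -2.25`
  kcal/mol (the minimum of the TIP3P pair-energy distribution).

* **distance** -- for crystal waters, which carry no hydrogens: an
  O-O separation strictly below 3.5 Angstrom.

Under either criterion with default parameters no O-O pair beyond
6 Angstrom can bond, so the all-pairs scan is pruned with a KD-tree
at that radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .exceptions import CriterionUnavailableError, SingularGeometryError
from .io import WaterMolecule

#: Radius beyond which neither criterion can produce an edge
#: (default parameters); used to prune the neighbor search.
PRUNE_RADIUS_A = 6.0

#: O-O separation below which two water records are treated as
#: duplicates of the same molecule.
DUPLICATE_OO_A = 0.5


@dataclass
class TIP3PParams:
    """TIP3P pair-potential parameters and the hydrogen-bond cutoff.

    Units: A in kcal*A^12/mol, C in kcal*A^6/mol, charges in e,
    coulomb_constant in kcal*A/(mol*e^2), energy_cutoff in kcal/mol.
    """

    A: float = 582000.0
    C: float = 595.0
    q_O: float = -0.834
    q_H: float = 0.417
    coulomb_constant: float = 332.0636
    energy_cutoff: float = -2.25

    def __post_init__(self) -> None:
        if self.A <= 0 or self.C <= 0:
            raise ValueError("A and C must be positive")
        if self.energy_cutoff >= 0:
            raise ValueError("energy_cutoff must be negative")
        if abs(self.q_O + 2 * self.q_H) > 1e-9:
            raise ValueError("water must be neutral: q_O + 2*q_H = 0")

    @property
    def site_charges(self) -> np.ndarray:
        return np.array([self.q_O, self.q_H, self.q_H])


@dataclass
class DistanceCriterion:
    """Crystal-water hydrogen-bond criterion: O-O distance strictly
    below ``oo_cutoff_A`` (default 3.5 Angstrom)."""

    oo_cutoff_A: float = 3.5

    def __post_init__(self) -> None:
        if self.oo_cutoff_A <= 0:
            raise ValueError("oo_cutoff_A must be positive")


@dataclass
class HBondGraph:
    """Undirected graph over waters; edges satisfy the active criterion.

    Edge attributes: ``r_oo`` (Angstrom) and, in energy mode,
    ``energy`` (kcal/mol).
    """

    graph: nx.Graph
    criterion_tag: str  # "energy" | "distance"
    collapsed_ids: list[int] = field(default_factory=list)

    @property
    def vertices(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def to_tsv(self, path) -> None:
        """Edge list as TSV: water_id_a, water_id_b, r_oo, energy-or-blank."""
        with open(path, "w") as fh:
            fh.write("water_id_a\twater_id_b\tr_oo_A\tenergy_kcal_mol\n")
            for a, b in self.edges:
                data = self.graph.edges[a, b]
                e = data.get("energy")
                fh.write(
                    f"{a}\t{b}\t{data['r_oo']:.4f}\t"
                    f"{'' if e is None else f'{e:.4f}'}\n"
                )


def _mic_shift(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image lattice shift (orthorhombic box)."""
    if box is None:
        return np.zeros(3)
    return np.round(delta / box) * box


def pair_energy(
    a: WaterMolecule,
    b: WaterMolecule,
    params: TIP3PParams | None = None,
    box: np.ndarray | None = None,
) -> float:
    """TIP3P interaction energy between two waters, kcal/mol.

    The minimum-image convention (orthorhombic boxes only) shifts
    molecule *b* as a rigid unit by the image offset of its oxygen,
    so intramolecular geometry is preserved across the boundary.
    """
    params = params or TIP3PParams()
    if not (a.has_hydrogens and b.has_hydrogens):
        raise CriterionUnavailableError(
            "energy criterion requires two explicit hydrogens per water "
            f"(waters {a.water_id}, {b.water_id})"
        )
    shift = _mic_shift(b.o_position - a.o_position, box)
    sa = a.sites()
    sb = b.sites() - shift
    r_oo = float(np.linalg.norm(sb[0] - sa[0]))
    if r_oo < 1e-6:
        raise SingularGeometryError(
            f"coincident oxygens for waters {a.water_id}, {b.water_id}"
        )
    q = params.site_charges
    diff = sa[:, None, :] - sb[None, :, :]
    rij = np.sqrt((diff**2).sum(axis=2))
    coulomb = params.coulomb_constant * float((np.outer(q, q) / rij).sum())
    lj = params.A / r_oo**12 - params.C / r_oo**6
    return coulomb + lj


def energy_edge(
    a: WaterMolecule,
    b: WaterMolecule,
    params: TIP3PParams | None = None,
    box: np.ndarray | None = None,
) -> bool:
    """True iff the pair energy is at or below the cutoff (inclusive)."""
    params = params or TIP3PParams()
    return pair_energy(a, b, params, box) <= params.energy_cutoff


def distance_edge(
    a: WaterMolecule,
    b: WaterMolecule,
    criterion: DistanceCriterion | None = None,
    box: np.ndarray | None = None,
) -> bool:
    """True iff the O-O separation is strictly below the cutoff."""
    criterion = criterion or DistanceCriterion()
    delta = b.o_position - a.o_position - _mic_shift(b.o_position - a.o_position, box)
    return float(np.linalg.norm(delta)) < criterion.oo_cutoff_A


def _collapse_duplicates(
    waters: list[WaterMolecule], box: np.ndarray | None
) -> tuple[list[WaterMolecule], list[int]]:
    """Collapse water records closer than DUPLICATE_OO_A; keep lowest id."""
    if len(waters) < 2:
        return waters, []
    pos = np.array([w.o_position for w in waters])
    tree = _make_tree(pos, box)
    pairs = tree.query_pairs(DUPLICATE_OO_A)
    if not pairs:
        return waters, []
    order = sorted(range(len(waters)), key=lambda i: waters[i].water_id)
    rank = {i: r for r, i in enumerate(order)}
    dropped: set[int] = set()
    for i, j in pairs:
        dropped.add(i if rank[i] > rank[j] else j)
    dropped_ids = sorted(waters[i].water_id for i in dropped)
    warnings.warn(
        f"collapsed {len(dropped)} duplicate water(s) closer than "
        f"{DUPLICATE_OO_A} A: ids {dropped_ids}",
        stacklevel=3,
    )
    kept = [w for i, w in enumerate(waters) if i not in dropped]
    return kept, dropped_ids


def _make_tree(pos: np.ndarray, box: np.ndarray | None) -> cKDTree:
    if box is None:
        return cKDTree(pos)
    return cKDTree(np.mod(pos, box), boxsize=box)


def build_graph(
    waters: list[WaterMolecule],
    mode: str = "energy",
    params: TIP3PParams | None = None,
    criterion: DistanceCriterion | None = None,
    box: np.ndarray | None = None,
    prune_radius_A: float | None = None,
) -> HBondGraph:
    """Materialize the hydrogen-bond criterion over all water pairs.

    The candidate-pair search is KD-tree pruned; the criterion is then
    evaluated exactly on each candidate pair.

    Parameters
    ----------
    mode : ``"energy"`` (TIP3P pair potential, needs hydrogens) or
        ``"distance"`` (crystal O-O cutoff).
    box : orthorhombic box lengths for minimum-image distances, or
        None (crystal structures are never wrapped).
    prune_radius_A : override the candidate search radius; defaults
        to the distance cutoff in distance mode and 6 A in energy mode.
    """
    if mode not in ("energy", "distance"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or TIP3PParams()
    criterion = criterion or DistanceCriterion()
    if mode == "energy":
        hydrogen_free = [w.water_id for w in waters if not w.has_hydrogens]
        if hydrogen_free:
            raise CriterionUnavailableError(
                "energy criterion requires explicit hydrogens; waters "
                f"without hydrogens: {hydrogen_free[:10]}"
            )
    waters, collapsed = _collapse_duplicates(list(waters), box)
    g = nx.Graph()
    g.add_nodes_from(w.water_id for w in waters)
    if len(waters) >= 2:
        if prune_radius_A is None:
            prune_radius_A = (
                criterion.oo_cutoff_A if mode == "distance" else PRUNE_RADIUS_A
            )
        pos = np.array([w.o_position for w in waters])
        tree = _make_tree(pos, box)
        for i, j in sorted(tree.query_pairs(prune_radius_A)):
            a, b = waters[i], waters[j]
            shift = _mic_shift(b.o_position - a.o_position, box)
            r_oo = float(np.linalg.norm(b.o_position - shift - a.o_position))
            if mode == "distance":
                if r_oo < criterion.oo_cutoff_A:
                    g.add_edge(a.water_id, b.water_id, r_oo=r_oo, energy=None)
            else:
                e = pair_energy(a, b, params, box)
                if e <= params.energy_cutoff:
                    g.add_edge(a.water_id, b.water_id, r_oo=r_oo, energy=e)
    return HBondGraph(graph=g, criterion_tag=mode, collapsed_ids=collapsed)
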