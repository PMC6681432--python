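"""Hydration-shell extraction, ring-to-residue assignment, aggregation.

The hydration shell is every water whose oxygen lies within a fixed
radius (default 10 Angstrom, covering the first and second hydration
shells) of the frame's reference atoms -- the C-alpha atoms by
default, or all residue heavy atoms.

Each detected ring is assigned to exactly one residue heavy atom: the
candidate atom with the smallest Euclidean distance to any of the
ring's oxygen atoms.  Ties break to the lowest atom serial.  The
assignment records the atom's element class (O/N/C/S) and whether it
is a backbone or side-chain atom; aggregating assignments yields the
per-residue count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import AssignmentError, ConfigurationError
from .io import AtomRecord, Frame, WaterMolecule, classify_backbone
from .tables import CountsTable

if TYPE_CHECKING:  # pragma: no cover
    from .rings import TWNRing


@dataclass
class ShellConfig:
    """Hydration-shell definition.

    radius_A : shell radius around the reference atoms (default 10).
    reference : ``"calpha"`` (default) or ``"all_heavy"``.
    include_caps : admit ACE/NME cap atoms as reference / assignment
        candidates (default False; count tables have no cap columns).
    """

    radius_A: float = 10.0
    reference: str = "calpha"
    include_caps: bool = False

    def __post_init__(self) -> None:
        if self.radius_A <= 0:
            raise ValueError("radius_A must be positive")
        if self.reference not in ("calpha", "all_heavy"):
            raise ValueError("reference must be 'calpha' or 'all_heavy'")


def reference_atoms(frame: Frame, config: ShellConfig) -> list[AtomRecord]:
    """The atoms the shell radius is measured from."""
    heavy = frame.heavy_atoms(include_caps=config.include_caps)
    if config.reference == "calpha":
        refs = [a for a in heavy if a.atom_name == "CA"]
    else:
        refs = heavy
    if not refs:
        raise ConfigurationError(
            f"no reference atoms under reference={config.reference!r}"
        )
    return refs


def extract_shell(frame: Frame, config: ShellConfig | None = None) -> list[WaterMolecule]:
    """Waters whose oxygen lies within radius_A of any reference atom."""
    config = config or ShellConfig()
    refs = reference_atoms(frame, config)
    if not frame.waters:
        return []
    wpos = np.array([w.o_position for w in frame.waters])
    rpos = np.array([a.position for a in refs])
    tree = cKDTree(wpos)
    keep: set[int] = set()
    for idx in tree.query_ball_point(rpos, config.radius_A):
        keep.update(idx)
    return [w for i, w in enumerate(frame.waters) if i in keep]


@dataclass(frozen=True)
class RingAssignment:
    """A ring mapped to its nearest residue heavy atom."""

    ring: "TWNRing"
    nearest_atom: AtomRecord
    min_distance_A: float
    atom_class: str  # O | N | C | S
    region: str  # backbone | sidechain
    residue_name: str


def assign_ring(
    ring: "TWNRing",
    frame: Frame,
    config: ShellConfig | None = None,
) -> RingAssignment:
    """Assign a ring to the residue heavy atom nearest any ring oxygen.

    The minimal distance is taken over (ring oxygens x candidate heavy
    atoms); hydrogens are never candidates; exact ties break to the
    lowest atom serial.
    """
    config = config or ShellConfig()
    candidates = frame.heavy_atoms(include_caps=config.include_caps)
    if not candidates:
        raise AssignmentError("no candidate residue heavy atoms in frame")
    by_id = frame.water_by_id()
    try:
        opos = np.array([by_id[i].o_position for i in ring.member_ids])
    except KeyError as exc:
        raise AssignmentError(f"ring member {exc} not present in frame") from exc
    apos = np.array([a.position for a in candidates])
    d = np.linalg.norm(opos[:, None, :] - apos[None, :, :], axis=2)
    per_atom = d.min(axis=0)
    best = min(range(len(candidates)), key=lambda j: (per_atom[j], candidates[j].serial))
    atom = candidates[best]
    return RingAssignment(
        ring=ring,
        nearest_atom=atom,
        min_distance_A=float(per_atom[best]),
        atom_class=atom.element,
        region=classify_backbone(atom),
        residue_name=atom.residue_name,
    )


def assign_rings(
    per_frame: Iterable[tuple[Frame, Sequence["TWNRing"]]],
    config: ShellConfig | None = None,
    max_distance_A: float | None = None,
) -> list[RingAssignment]:
    """Assign every detected ring across frames.

    ``max_distance_A`` (used on the crystal-structure path, where no
    per-residue shell pre-selects waters) drops assignments whose
    minimal distance exceeds the cap.
    """
    out: list[RingAssignment] = []
    for frame, rings in per_frame:
        for ring in rings:
            a = assign_ring(ring, frame, config)
            if max_distance_A is not None and a.min_distance_A > max_distance_A:
                continue
            out.append(a)
    return out


def split_backbone_sidechain(
    assignments: Sequence[RingAssignment],
) -> tuple[list[RingAssignment], list[RingAssignment]]:
    """Disjoint partition of assignments by region."""
    backbone = [a for a in assignments if a.region == "backbone"]
    sidechain = [a for a in assignments if a.region == "sidechain"]
    return backbone, sidechain


def aggregate(
    assignments: Sequence[RingAssignment],
    scope: str = "combined",
    ring_size: int = 3,
    criterion_tag: str | None = None,
    policy: str = "chordless",
) -> CountsTable:
    """Count assignments per residue type x atom class.

    All assignments must share ``ring_size``; ``scope`` restricts to
    backbone or side-chain assignments (``combined`` keeps both).
    """
    sizes = {a.ring.size for a in assignments}
    if sizes and sizes != {ring_size}:
        raise ValueError(
            f"assignments mix ring sizes {sorted(sizes)}; expected {{{ring_size}}}"
        )
    if scope == "backbone":
        assignments = [a for a in assignments if a.region == "backbone"]
    elif scope == "sidechain":
        assignments = [a for a in assignments if a.region == "sidechain"]
    elif scope != "combined":
        raise ValueError(f"unknown scope {scope!r}")
    per_residue: dict[str, dict[str, int]] = {}
    for a in assignments:
        col = per_residue.setdefault(a.residue_name, {})
        col[a.atom_class] = col.get(a.atom_class, 0) + 1
    if criterion_tag is None:
        criterion_tag = assignments[0].ring.criterion_tag if assignments else "energy"
    return CountsTable.from_class_counts(
        per_residue,
        scope=scope,
        ring_size=ring_size,
        criterion_tag=criterion_tag,
        policy=policy,
    )


def assignments_to_tsv(assignments: Sequence[RingAssignment], path) -> None:
    """Assignment-level TSV: frame, size, residue, atom, class, region,
    distance, ring members."""
    with open(path, "w") as fh:
        fh.write(
            "frame_index\tsize\tresidue_name\tresidue_seq\tatom_name\t"
            "atom_class\tregion\tmin_distance_A\tmember_water_ids\n"
        )
        for a in assignments:
            fh.write(
                f"{a.ring.frame_index}\t{a.ring.size}\t{a.residue_name}\t"
                f"{a.nearest_atom.residue_seq}\t{a.nearest_atom.atom_name}\t"
                f"{a.atom_class}\t{a.region}\t{a.min_distance_A:.4f}\t"
                f"{','.join(map(str, a.ring.member_ids))}\n"
            )
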