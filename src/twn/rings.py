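"""Enumeration of cyclic water networks (TWNs) of sizes 3-6.

A TWN is a cycle in the hydrogen-bond graph.  Two reporting policies
are provided:

* ``chordless`` (default): a cycle is reported only if no graph edge
  joins two non-adjacent members.  A 4-cycle with a chord is
  geometrically two triangles; counting it as a square as well would
  inflate larger-ring counts.
* ``all_simple``: every simple cycle of a requested size is reported.

Cycles are deduplicated by canonical form (the lexicographically
smallest rotation/reflection of the member tuple) and returned in a
deterministic order, so repeated runs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .hbond import HBondGraph, TIP3PParams, DistanceCriterion, build_graph

ALLOWED_SIZES = frozenset({3, 4, 5, 6})
POLICIES = ("chordless", "all_simple")


@dataclass(frozen=True)
class TWNRing:
    """One cyclic water network, canonically ordered.

    ``member_ids`` is the rotation/reflection of the cycle that is
    lexicographically smallest; consecutive members (cyclically) are
    hydrogen-bond edges.
    """

    member_ids: tuple[int, ...]
    size: int
    frame_index: int = 0
    criterion_tag: str = "energy"

    def __post_init__(self) -> None:
        if self.size != len(self.member_ids):
            raise ValueError("size must equal the number of members")
        if len(set(self.member_ids)) != self.size:
            raise ValueError("ring members must be distinct")


def canonical_cycle(members: Sequence[int]) -> tuple[int, ...]:
    """Canonical form of a cycle: smallest tuple over all rotations of
    both orientations."""
    m = list(members)
    n = len(m)
    best = None
    for seq in (m, m[::-1]):
        for s in range(n):
            cand = tuple(seq[s:] + seq[:s])
            if best is None or cand < best:
                best = cand
    return best


def _validate_sizes(sizes: Iterable[int]) -> frozenset[int]:
    sizes = frozenset(sizes)
    if not sizes:
        raise ValueError("at least one ring size is required")
    bad = sizes - ALLOWED_SIZES
    if bad:
        raise ValueError(f"ring sizes must be within {sorted(ALLOWED_SIZES)}; got {sorted(bad)}")
    return sizes


def find_rings(
    graph: HBondGraph | nx.Graph,
    sizes: Iterable[int] = (3, 4, 5, 6),
    policy: str = "chordless",
    frame_index: int = 0,
) -> list[TWNRing]:
    """Enumerate each unique cycle of the requested sizes exactly once.

    Returns rings sorted by (size, canonical member tuple).
    """
    sizes = _validate_sizes(sizes)
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}; got {policy!r}")
    if isinstance(graph, HBondGraph):
        g = graph.graph
        tag = graph.criterion_tag
    else:
        g = graph
        tag = "energy"
    bound = max(sizes)
    if policy == "chordless":
        cycles = nx.chordless_cycles(g, length_bound=bound)
    else:
        cycles = nx.simple_cycles(g, length_bound=bound)
    seen: set[tuple[int, ...]] = set()
    rings: list[TWNRing] = []
    for cyc in cycles:
        if len(cyc) not in sizes:
            continue
        canon = canonical_cycle(cyc)
        if canon in seen:
            continue
        seen.add(canon)
        rings.append(
            TWNRing(
                member_ids=canon,
                size=len(canon),
                frame_index=frame_index,
                criterion_tag=tag,
            )
        )
    rings.sort(key=lambda r: (r.size, r.member_ids))
    return rings


def rings_per_frame(
    frames,
    mode: str = "energy",
    sizes: Iterable[int] = (3, 4, 5, 6),
    policy: str = "chordless",
    shell=None,
    params: TIP3PParams | None = None,
    criterion: DistanceCriterion | None = None,
    use_box: bool | None = None,
):
    """Detect rings frame by frame among shell-extracted waters.

    For each frame the hydration shell is extracted (when ``shell`` is
    given), the hydrogen-bond graph is built under ``mode``, and rings
    are enumerated.  Periodic wrapping is applied only in energy
    (MD-frame) mode unless ``use_box`` overrides it.

    Returns a list of (frame, rings) pairs.
    """
    from .shell import extract_shell  # local import: avoids module cycle

    if use_box is None:
        use_box = mode == "energy"
    out = []
    for frame in frames:
        waters = extract_shell(frame, shell) if shell is not None else frame.waters
        g = build_graph(
            waters,
            mode=mode,
            params=params,
            criterion=criterion,
            box=frame.box if use_box else None,
        )
        rings = find_rings(g, sizes=sizes, policy=policy, frame_index=frame.frame_index)
        out.append((frame, rings))
    return out


def rings_to_tsv(per_frame, path) -> None:
    """Rings as TSV: frame_index, size, comma-joined member water_ids."""
    with open(path, "w") as fh:
        fh.write("frame_index\tsize\tmember_water_ids\n")
        for frame, rings in per_frame:
            for r in rings:
                fh.write(
                    f"{frame.frame_index}\t{r.size}\t"
                    f"{','.join(map(str, r.member_ids))}\n"
                )
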