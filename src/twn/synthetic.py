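"""Synthetic structures with known ground truth.

Every stage of the pipeline is testable without external data:

* :func:`make_ring` places water oxygens on a regular polygon and
  orients hydrogens so that each water donates one hydrogen to its
  neighbor around the ring.  The geometry is *certified* at
  generation time against the pair-energy and distance criteria
  (adjacent pairs bond, non-adjacent pairs do not); certification is
  part of generation, not assumed.
* :func:`toy_residue` returns an idealized alanine capped with acetyl
  (ACE) and N-methyl amide (NME) groups -- the single-amino-acid
  context used for per-residue hydration analysis.
* :func:`make_scene` plants rings inside the hydration shell of the
  toy residue, adds well-separated noise waters, and records the
  ground truth (ring memberships and intended nearest atom per ring).
* :func:`make_filter_fixture_set` writes a small directory of crystal
  structures exercising every dataset-filter rule.

All randomness flows from the seed in :class:`PlantSpec`; generated
files are byte-reproducible.

Water internal geometry is the rigid TIP3P one: O-H 0.9572 Angstrom,
H-O-H 104.52 degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import GeometryCertificationError, PlacementError
from .hbond import DistanceCriterion, TIP3PParams, pair_energy
from .io import AtomRecord, Frame, WaterMolecule, write_frames_pdb

OH_BOND_A = 0.9572
HOH_ANGLE_DEG = 104.52

#: Idealized ACE-ALA-NME heavy atoms: (serial, atom_name, element,
#: residue_name, residue_seq, x, y, z).  Bond lengths are plausible
#: (1.2-1.55 A); the geometry is a fixture, not a force-field build.
_TOY_RESIDUE_ATOMS = [
    (1, "CH3", "C", "ACE", 1, -3.17, 1.19, 0.00),
    (2, "C", "C", "ACE", 1, -2.44, -0.10, 0.00),
    (3, "O", "O", "ACE", 1, -3.05, -1.15, 0.00),
    (4, "N", "N", "ALA", 2, -1.11, -0.11, 0.00),
    (5, "CA", "C", "ALA", 2, -0.30, 1.07, 0.00),
    (6, "CB", "C", "ALA", 2, -0.74, 2.12, 1.02),
    (7, "C", "C", "ALA", 2, 1.21, 0.86, 0.00),
    (8, "O", "O", "ALA", 2, 1.73, 1.60, 0.85),
    (9, "N", "N", "NME", 3, 1.91, -0.03, -0.63),
    (10, "CH3", "C", "NME", 3, 3.30, -0.22, -0.77),
]


def toy_residue(offset: np.ndarray | None = None) -> list[AtomRecord]:
    """Idealized capped alanine (heavy atoms only), optionally shifted."""
    offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    return [
        AtomRecord(
            serial=serial,
            atom_name=name,
            element=element,
            residue_name=resname,
            residue_seq=seq,
            chain_id="A",
            position=np.array([x, y, z]) + offset,
        )
        for serial, name, element, resname, seq, x, y, z in _TOY_RESIDUE_ATOMS
    ]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (unit-quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _water_hydrogens(
    o: np.ndarray, h1_dir: np.ndarray, second_dir_hint: np.ndarray
) -> list[np.ndarray]:
    """Rigid-geometry hydrogens: H1 along ``h1_dir``; H2 at the H-O-H
    angle from H1, tilted toward ``second_dir_hint``."""
    u = np.asarray(h1_dir, dtype=float)
    u = u / np.linalg.norm(u)
    s = np.asarray(second_dir_hint, dtype=float)
    w = s - np.dot(s, u) * u
    n = np.linalg.norm(w)
    if n < 1e-9:  # hint parallel to h1_dir: pick any perpendicular
        w = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-9:
            w = np.cross(u, [0.0, 1.0, 0.0])
        n = np.linalg.norm(w)
    w = w / n
    ang = np.deg2rad(HOH_ANGLE_DEG)
    h2_dir = np.cos(ang) * u + np.sin(ang) * w
    return [o + OH_BOND_A * u, o + OH_BOND_A * h2_dir]


def make_ring(
    size: int,
    oo_distance_A: float = 2.8,
    orient_hydrogens: bool = True,
    center: np.ndarray | None = None,
    rotation: np.ndarray | None = None,
    start_id: int = 0,
    params: TIP3PParams | None = None,
    criterion: DistanceCriterion | None = None,
) -> list[WaterMolecule]:
    """A planted water ring: oxygens at the vertices of a regular
    polygon with side ``oo_distance_A``.

    With ``orient_hydrogens`` each water donates one hydrogen toward
    its clockwise neighbor along the O-O axis and points its second
    hydrogen outward, a geometry whose adjacent pairs satisfy the
    energy criterion while non-adjacent pairs satisfy neither
    criterion.  Generation certifies this with the pair-energy /
    distance oracles and raises if the check fails.
    """
    if size not in (3, 4, 5, 6):
        raise ValueError(f"ring size must be 3-6, got {size}")
    if not 2.4 <= oo_distance_A <= 3.4:
        raise ValueError(f"oo_distance_A must be in [2.4, 3.4], got {oo_distance_A}")
    params = params or TIP3PParams()
    criterion = criterion or DistanceCriterion()
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rotation = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    radius = oo_distance_A / (2.0 * np.sin(np.pi / size))
    angles = 2.0 * np.pi * np.arange(size) / size
    local_o = radius * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros(size)]
    )
    waters: list[WaterMolecule] = []
    for k in range(size):
        o = local_o[k]
        if orient_hydrogens:
            donor_dir = local_o[(k + 1) % size] - o
            outward = o / np.linalg.norm(o)  # radial, away from ring center
            h_local = _water_hydrogens(o, donor_dir, outward)
            h_pos = [rotation @ h + center for h in h_local]
        else:
            h_pos = []
        waters.append(
            WaterMolecule(
                water_id=start_id + k,
                o_position=rotation @ o + center,
                h_positions=h_pos,
            )
        )
    _certify_ring(waters, orient_hydrogens, params, criterion)
    return waters


def _certify_ring(
    waters: list[WaterMolecule],
    oriented: bool,
    params: TIP3PParams,
    criterion: DistanceCriterion,
) -> None:
    n = len(waters)
    for i in range(n):
        for j in range(i + 1, n):
            adjacent = (j - i == 1) or (i == 0 and j == n - 1)
            r_oo = float(np.linalg.norm(waters[i].o_position - waters[j].o_position))
            dist_ok = r_oo < criterion.oo_cutoff_A
            if adjacent and not dist_ok:
                raise GeometryCertificationError(
                    f"adjacent pair ({i},{j}) fails distance criterion: r_oo={r_oo:.2f}"
                )
            if not adjacent and dist_ok:
                raise GeometryCertificationError(
                    f"non-adjacent pair ({i},{j}) passes distance criterion: r_oo={r_oo:.2f}"
                )
            if oriented:
                e = pair_energy(waters[i], waters[j], params)
                if adjacent and e > params.energy_cutoff:
                    raise GeometryCertificationError(
                        f"adjacent pair ({i},{j}) fails energy criterion: {e:.2f}"
                    )
                if not adjacent and e <= params.energy_cutoff:
                    raise GeometryCertificationError(
                        f"non-adjacent pair ({i},{j}) passes energy criterion: {e:.2f}"
                    )


@dataclass
class PlantSpec:
    """What to plant in a synthetic scene.

    ``noise_min_separation_A`` must exceed the largest radius at which
    either hydrogen-bond criterion can fire (6 A with default
    parameters), so noise waters can neither join nor bridge planted
    rings.
    """

    ring_sizes: tuple[int, ...] = (3,)
    oo_distance_A: float = 2.8
    n_noise_waters: int = 0
    noise_min_separation_A: float = 6.0
    seed: int = 0
    box_A: float = 40.0

    def __post_init__(self) -> None:
        for s in self.ring_sizes:
            if s not in (3, 4, 5, 6):
                raise ValueError(f"ring size must be 3-6, got {s}")
        if self.noise_min_separation_A < 6.0:
            raise ValueError(
                "noise_min_separation_A must be >= 6.0 so noise cannot "
                "join or bridge rings under either criterion"
            )


@dataclass
class PlantedRing:
    member_ids: tuple[int, ...]
    size: int
    nearest_atom_serial: int
    min_distance_A: float
    margin_A: float  # gap to the second-nearest distinct atom


@dataclass
class SceneTruth:
    """Ground truth for one generated scene."""

    seed: int
    rings: list[PlantedRing] = field(default_factory=list)
    n_noise_waters: int = 0

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"seed": self.seed, "n_noise_waters": self.n_noise_waters}) + "\n")
            for r in self.rings:
                fh.write(
                    json.dumps(
                        {
                            "member_ids": list(r.member_ids),
                            "size": r.size,
                            "nearest_atom_serial": r.nearest_atom_serial,
                            "min_distance_A": round(r.min_distance_A, 4),
                            "margin_A": round(r.margin_A, 4),
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "SceneTruth":
        lines = Path(path).read_text().splitlines()
        head = json.loads(lines[0])
        truth = cls(seed=head["seed"], n_noise_waters=head["n_noise_waters"])
        for line in lines[1:]:
            d = json.loads(line)
            truth.rings.append(
                PlantedRing(
                    member_ids=tuple(d["member_ids"]),
                    size=d["size"],
                    nearest_atom_serial=d["nearest_atom_serial"],
                    min_distance_A=d["min_distance_A"],
                    margin_A=d["margin_A"],
                )
            )
        return truth


def _nearest_atom(
    o_positions: np.ndarray, atoms: list[AtomRecord]
) -> tuple[int, float, float]:
    """Brute-force nearest heavy atom over all ring oxygens.

    Returns (atom serial, min distance, margin to second-best atom)."""
    per_atom = [
        (min(float(np.linalg.norm(o - a.position)) for o in o_positions), a.serial)
        for a in atoms
    ]
    per_atom.sort()
    best_d, best_serial = per_atom[0]
    margin = per_atom[1][0] - best_d if len(per_atom) > 1 else float("inf")
    return best_serial, best_d, margin


def make_scene(
    spec: PlantSpec,
    shell_radius_A: float = 10.0,
    max_attempts: int = 2000,
    max_restarts: int = 20,
) -> tuple[Frame, SceneTruth]:
    """Plant the requested rings within the hydration shell of the toy
    residue, add noise waters, and record ground truth.

    Rings are placed so every ring oxygen lies within
    ``shell_radius_A`` of the residue's C-alpha; waters of different
    rings (and noise waters) stay at least ``noise_min_separation_A``
    apart so the planted edge set is exactly the detected one.  Noise
    waters are scattered in a shell extending 4 A beyond the
    extraction radius, so some fall outside the analyzed shell.

    Placement is stochastic; if one pass runs out of attempts the
    whole scene is retried from a sub-seed derived from ``spec.seed``,
    so generation stays deterministic per seed.
    """
    last_error: PlacementError | None = None
    for restart in range(max_restarts):
        rng = np.random.default_rng([spec.seed, restart])
        try:
            return _place_scene(spec, rng, shell_radius_A, max_attempts)
        except PlacementError as exc:
            last_error = exc
    raise last_error


def _place_scene(
    spec: PlantSpec,
    rng: np.random.Generator,
    shell_radius_A: float,
    max_attempts: int,
) -> tuple[Frame, SceneTruth]:
    box_center = np.full(3, spec.box_A / 2.0)
    atoms = toy_residue(offset=box_center)
    heavy = [a for a in atoms if a.element != "H"]
    # ground-truth nearest atoms use the default assignment candidate
    # set: residue heavy atoms without the ACE/NME caps
    candidates = [a for a in heavy if a.residue_name not in ("ACE", "NME")]
    ca = next(a.position for a in atoms if a.atom_name == "CA")
    placed_o: list[np.ndarray] = []
    waters: list[WaterMolecule] = []
    truth = SceneTruth(seed=spec.seed, n_noise_waters=spec.n_noise_waters)
    sep = spec.noise_min_separation_A
    for size in spec.ring_sizes:
        circum = spec.oo_distance_A / (2.0 * np.sin(np.pi / size))
        max_center_dist = shell_radius_A - circum - 0.1
        for attempt in range(max_attempts):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(3.5 + circum, max_center_dist)
            center = ca + direction * dist
            rot = _random_rotation(rng)
            candidate = make_ring(
                size,
                spec.oo_distance_A,
                orient_hydrogens=True,
                center=center,
                rotation=rot,
                start_id=len(waters),
            )
            opos = np.array([w.o_position for w in candidate])
            if placed_o and np.min(
                np.linalg.norm(opos[:, None, :] - np.array(placed_o)[None, :, :], axis=2)
            ) <= sep:
                continue
            atom_d = np.linalg.norm(
                opos[:, None, :] - np.array([a.position for a in heavy])[None, :, :],
                axis=2,
            )
            if atom_d.min() < 2.5:
                continue
            break
        else:
            raise PlacementError(
                f"could not place a {size}-ring after {max_attempts} attempts"
            )
        member_ids = tuple(w.water_id for w in candidate)
        serial, dmin, margin = _nearest_atom(opos, candidates)
        truth.rings.append(
            PlantedRing(member_ids, size, serial, dmin, margin)
        )
        waters.extend(candidate)
        placed_o.extend(opos)
    # widen the noise field with the count so the minimum-separation
    # packing stays feasible
    noise_field = max(shell_radius_A + 4.0, 6.0 * spec.n_noise_waters ** (1.0 / 3.0))
    for _ in range(spec.n_noise_waters):
        for attempt in range(max_attempts):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = ca + direction * rng.uniform(3.0, noise_field)
            if placed_o and np.min(
                np.linalg.norm(np.array(placed_o) - pos, axis=1)
            ) <= sep:
                continue
            if min(float(np.linalg.norm(pos - a.position)) for a in heavy) < 2.5:
                continue
            break
        else:
            raise PlacementError(
                f"could not place noise water after {max_attempts} attempts"
            )
        h1_dir = rng.normal(size=3)
        hint = rng.normal(size=3)
        waters.append(
            WaterMolecule(
                water_id=len(waters),
                o_position=pos,
                h_positions=_water_hydrogens(pos, h1_dir, hint),
            )
        )
        placed_o.append(pos)
    frame = Frame(
        frame_index=0,
        waters=waters,
        residue_atoms=atoms,
        time_ps=0.0,
        box=np.full(3, spec.box_A),
    )
    return frame, truth


def write_scene(frame: Frame, truth: SceneTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a scene as PDB plus JSON-lines ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = out_dir / f"scene_seed{truth.seed}.pdb"
    jsonl = out_dir / f"scene_seed{truth.seed}.truth.jsonl"
    write_frames_pdb([frame], pdb)
    truth.to_jsonl(jsonl)
    return pdb, jsonl


def make_trajectory(
    n_frames: int,
    base_spec: PlantSpec,
    dt_ps: float = 5.0,
) -> list[Frame]:
    """Independent scenes as consecutive trajectory frames.

    Frame *k* is generated from seed ``base_spec.seed + k`` and gets
    ``frame_index = k`` and ``time_ps = k * dt_ps``.
    """
    frames = []
    for k in range(n_frames):
        spec = PlantSpec(
            ring_sizes=base_spec.ring_sizes,
            oo_distance_A=base_spec.oo_distance_A,
            n_noise_waters=base_spec.n_noise_waters,
            noise_min_separation_A=base_spec.noise_min_separation_A,
            seed=base_spec.seed + k,
            box_A=base_spec.box_A,
        )
        frame, _ = make_scene(spec)
        frame.frame_index = k
        frame.time_ps = k * dt_ps
        frames.append(frame)
    return frames


def make_filter_fixture_set(out_dir: str | Path, seed: int = 0) -> dict[str, str]:
    """Six crystal-structure files exercising every filter rule.

    Returns {filename: expected decision}: two keepers, one
    nucleic-acid-only file, two files without waters, one low-resolution
    file.  Crystal waters are written without hydrogens.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def crystal_frame(with_waters: bool, nucleic: bool, seed: int) -> Frame:
        rng = np.random.default_rng(seed)
        if nucleic:
            atoms = [
                AtomRecord(
                    serial=i + 1,
                    atom_name=name,
                    element="C" if name.startswith("C") else "other",
                    residue_name=resname,
                    residue_seq=i + 1,
                    chain_id="A",
                    position=np.array([3.0 * i, 0.0, 0.0]),
                )
                for i, (resname, name) in enumerate(
                    [("DA", "P"), ("DA", "C1'"), ("DT", "P"), ("DT", "C1'")]
                )
            ]
        else:
            atoms = toy_residue(offset=np.array([10.0, 10.0, 10.0]))
        waters = []
        if with_waters:
            ring = make_ring(
                3, 2.8, orient_hydrogens=False,
                center=np.array([14.0, 14.0, 12.0]),
            )
            waters = list(ring)
            for k in range(3):
                waters.append(
                    WaterMolecule(
                        water_id=3 + k,
                        o_position=np.array([20.0, 20.0, 8.0 + 7.0 * k])
                        + rng.uniform(-0.5, 0.5, size=3),
                    )
                )
        return Frame(frame_index=0, waters=waters, residue_atoms=atoms)

    cases = {
        "keep_a.pdb": ("keep", 1.50, True, False),
        "keep_b.pdb": ("keep", 1.20, True, False),
        "nucleic_only.pdb": ("drop(non-protein)", 1.00, True, True),
        "dry_a.pdb": ("drop(no-water)", 1.40, False, False),
        "dry_b.pdb": ("drop(no-water)", 1.55, False, False),
        "low_res.pdb": ("drop(resolution)", 1.80, True, False),
    }
    expected = {}
    for i, (name, (decision, res, with_waters, nucleic)) in enumerate(cases.items()):
        frame = crystal_frame(with_waters, nucleic, seed + i)
        write_frames_pdb([frame], out_dir / name, resolution_A=res)
        expected[name] = decision
    return expected
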