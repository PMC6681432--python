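"""Structure and trajectory I/O.

Reads protein structures (PDB) and multi-MODEL coordinate files,
separates water molecules from residue atoms, and exposes resolution
and residue metadata.  Parsing is delegated to :mod:`gemmi`; this
module only decides what counts as a water, a residue heavy atom, a
capping-group atom, or a hydrogen.

Conventions
-----------
* PDB serials are 1-based and kept verbatim on :class:`AtomRecord`;
  all internal indices (water ids, frame indices into lists) are
  0-based.  Conversion happens only at the I/O boundary.
* Alternate locations: the blank altloc or conformer ``A`` is kept,
  all other conformers are discarded (single-conformer convention).
* Multi-MODEL files: model 1 is used for crystal structures unless an
  explicit model index is requested; :func:`read_frames` iterates all
  models as trajectory frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .exceptions import (
    ClassificationError,
    EmptyStructureError,
    FormatError,
)

#: Residue names recognized as water.
WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP"}

#: Heavy-atom names forming the peptide backbone.
BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O", "OXT"}

#: Residue names of terminal capping groups (acetyl / N-methyl amide).
CAP_RESNAMES = {"ACE", "NME", "NMA"}

#: The 20 standard amino acids plus common His protonation-state names.
AMINO_ACID_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
    "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL", "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "MSE",
}

NUCLEIC_RESNAMES = {
    "DA", "DT", "DG", "DC", "DU", "DI", "A", "U", "G", "C", "I",
}

_ELEMENTS = {"C", "N", "O", "S", "H"}


def _element_of(atom_name: str, element_hint: str) -> str:
    """Element symbol from the element column, else from the atom name."""
    e = element_hint.strip().upper()
    if e in _ELEMENTS:
        return e
    # strip digits / primes, take the leading alphabetic character(s)
    stripped = re.sub(r"[^A-Za-z]", "", atom_name)
    if not stripped:
        return "other"
    lead = stripped[0].upper()
    # two-letter elements relevant here
    if stripped[:2].upper() in {"SE", "CL", "BR", "FE", "ZN", "MG", "NA"}:
        two = stripped[:2].upper()
        return two if two in _ELEMENTS else "other"
    return lead if lead in _ELEMENTS else "other"


@dataclass(frozen=True)
class AtomRecord:
    """One non-water atom of a structure or frame."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class WaterMolecule:
    """One water: an oxygen position and zero or two hydrogen positions.

    Crystal waters carry only the oxygen; MD-frame waters carry two
    explicit hydrogens (required by the energy criterion).
    """

    water_id: int
    o_position: np.ndarray
    h_positions: list[np.ndarray] = field(default_factory=list)
    source_residue_seq: int = 0
    chain_id: str = ""

    def __post_init__(self) -> None:
        self.o_position = np.asarray(self.o_position, dtype=float)
        self.h_positions = [np.asarray(h, dtype=float) for h in self.h_positions]
        if len(self.h_positions) not in (0, 2):
            raise ValueError(
                f"water {self.water_id}: expected 0 or 2 hydrogens, "
                f"got {len(self.h_positions)}"
            )
        for h in self.h_positions:
            d = float(np.linalg.norm(h - self.o_position))
            if not 0.5 < d < 1.5:
                raise ValueError(
                    f"water {self.water_id}: O-H distance {d:.3f} A outside (0.5, 1.5)"
                )

    @property
    def has_hydrogens(self) -> bool:
        return len(self.h_positions) == 2

    def sites(self) -> np.ndarray:
        """(3, 3) array of O, H1, H2 positions (energy-mode waters only)."""
        return np.vstack([self.o_position, *self.h_positions])


@dataclass
class Frame:
    """One coordinate snapshot: waters plus residue atoms."""

    frame_index: int
    waters: list[WaterMolecule]
    residue_atoms: list[AtomRecord]
    time_ps: float | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [w.water_id for w in self.waters]
        if len(ids) != len(set(ids)):
            raise ValueError("water_ids must be unique within a frame")
        for a in self.residue_atoms:
            if a.residue_name in WATER_RESNAMES:
                raise ValueError("residue_atoms must not contain water residues")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def water_by_id(self) -> dict[int, WaterMolecule]:
        return {w.water_id: w for w in self.waters}

    def heavy_atoms(self, include_caps: bool = False) -> list[AtomRecord]:
        """Residue heavy atoms (C/N/O/S), optionally including cap atoms."""
        out = []
        for a in self.residue_atoms:
            if a.is_hydrogen or a.element not in {"C", "N", "O", "S"}:
                continue
            if not include_caps and a.residue_name in CAP_RESNAMES:
                continue
            out.append(a)
        return out


@dataclass
class StructureMeta:
    """File-level metadata used by the dataset filter."""

    source_path: str
    resolution_A: float | None
    n_waters: int
    has_protein: bool
    has_nucleic_only: bool
    model_count: int


def _iter_kept_atoms(residue: gemmi.Residue) -> Iterator[gemmi.Atom]:
    """Atoms after altloc pruning: keep blank altloc or conformer 'A'."""
    for atom in residue:
        if not atom.has_altloc() or atom.altloc == "A":
            yield atom


def _model_to_frame(
    model: gemmi.Model,
    frame_index: int,
    water_resnames: set[str],
    box: np.ndarray | None,
    time_ps: float | None = None,
) -> Frame:
    waters: list[WaterMolecule] = []
    residue_atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.name in water_resnames:
                o_pos = None
                h_pos: list[np.ndarray] = []
                for atom in _iter_kept_atoms(res):
                    p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    el = _element_of(atom.name, atom.element.name)
                    if el == "O":
                        o_pos = p
                    elif el == "H":
                        h_pos.append(p)
                if o_pos is None:
                    continue  # water record without an oxygen: ignore
                waters.append(
                    WaterMolecule(
                        water_id=len(waters),
                        o_position=o_pos,
                        h_positions=h_pos if len(h_pos) == 2 else [],
                        source_residue_seq=res.seqid.num,
                        chain_id=chain.name,
                    )
                )
            else:
                for atom in _iter_kept_atoms(res):
                    residue_atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            atom_name=atom.name,
                            element=_element_of(atom.name, atom.element.name),
                            residue_name=res.name,
                            residue_seq=res.seqid.num,
                            chain_id=chain.name,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            occupancy=atom.occ,
                            altloc="" if not atom.has_altloc() else atom.altloc,
                        )
                    )
    return Frame(
        frame_index=frame_index,
        waters=waters,
        residue_atoms=residue_atoms,
        time_ps=time_ps,
        box=box,
    )


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0 or all(
        len(res) == 0 for model in st for chain in model for res in chain
    ):
        raise EmptyStructureError(f"{path}: no atoms parsed")
    return st


def _box_of(st: gemmi.Structure) -> np.ndarray | None:
    c = st.cell
    if (
        c.a > 2.0
        and c.b > 2.0
        and c.c > 2.0
        and abs(c.alpha - 90) < 1e-6
        and abs(c.beta - 90) < 1e-6
        and abs(c.gamma - 90) < 1e-6
    ):
        return np.array([c.a, c.b, c.c])
    return None


def _resolution_of(st: gemmi.Structure) -> float | None:
    res = st.resolution
    return float(res) if res and res > 0 else None


def read_structure(
    path: str | Path,
    model_policy: int | str = "first",
    water_resnames: set[str] | None = None,
) -> tuple[Frame, StructureMeta]:
    """Read one structure: model 1 (or the requested model) as a Frame,
    plus file-level metadata.

    Parameters
    ----------
    path : path to a PDB file.
    model_policy : ``"first"`` (default) or a 1-based model number.
    water_resnames : override the recognized water residue names.
    """
    water_resnames = water_resnames or WATER_RESNAMES
    st = _read_gemmi(path)
    if model_policy == "first":
        model = st[0]
    else:
        wanted = int(model_policy)
        by_num = {m.num: m for m in st}
        if wanted not in by_num:
            raise FormatError(f"{path}: no MODEL {wanted}")
        model = by_num[wanted]
    frame = _model_to_frame(
        model, frame_index=0, water_resnames=water_resnames, box=_box_of(st)
    )
    resnames = {
        res.name for chain in st[0] for res in chain if res.name not in water_resnames
    }
    has_protein = bool(resnames & AMINO_ACID_RESNAMES)
    has_nucleic = bool(resnames & NUCLEIC_RESNAMES)
    meta = StructureMeta(
        source_path=str(path),
        resolution_A=_resolution_of(st),
        n_waters=len(frame.waters),
        has_protein=has_protein,
        has_nucleic_only=has_nucleic and not has_protein,
        model_count=len(st),
    )
    return frame, meta


_DT_REMARK = re.compile(r"REMARK\s+6\s+DT_PS\s+([0-9.eE+-]+)")


def read_frames(
    path: str | Path,
    stride: int = 1,
    water_resnames: set[str] | None = None,
) -> list[Frame]:
    """Read a multi-MODEL PDB as trajectory frames.

    Every ``stride``-th model (starting from the first) becomes a
    :class:`Frame`; ``frame_index`` is the 0-based position derived
    from the PDB model number.  A ``REMARK   6 DT_PS <dt>`` header, as
    written by the synthetic trajectory generator, supplies the time
    spacing between consecutive models; frame times are then
    ``(model_number - 1) * dt``.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    water_resnames = water_resnames or WATER_RESNAMES
    st = _read_gemmi(path)
    box = _box_of(st)
    dt_ps: float | None = None
    for line in st.raw_remarks:
        m = _DT_REMARK.search(line)
        if m:
            dt_ps = float(m.group(1))
            break
    frames: list[Frame] = []
    for pos, model in enumerate(st):
        if pos % stride != 0:
            continue
        idx = model.num - 1 if model.num >= 1 else pos
        t = idx * dt_ps if dt_ps is not None else None
        frames.append(
            _model_to_frame(model, idx, water_resnames, box, time_ps=t)
        )
    return frames


def classify_backbone(atom: AtomRecord) -> str:
    """Classify a heavy atom as ``backbone``, ``sidechain`` or ``cap``.

    Backbone = the amide N, C-alpha, carbonyl C and O (plus terminal
    OXT); ACE/NME capping-group atoms are ``cap``; every other heavy
    atom is side chain.  Hydrogens are not classified.
    """
    if atom.is_hydrogen:
        raise ClassificationError(
            f"atom {atom.serial} ({atom.atom_name}): hydrogens are not classified"
        )
    if atom.residue_name in CAP_RESNAMES:
        return "cap"
    if atom.atom_name in BACKBONE_ATOM_NAMES:
        return "backbone"
    return "sidechain"


# ---------------------------------------------------------------------------
# Writing


def _frame_into_model(frame: Frame, model: gemmi.Model) -> None:
    serial = 1
    chains: dict[str, gemmi.Chain] = {}

    def get_chain(name: str) -> gemmi.Chain:
        if name not in chains:
            model.add_chain(gemmi.Chain(name))
            chains[name] = model[len(model) - 1]
        return chains[name]

    for a in frame.residue_atoms:
        chain = get_chain(a.chain_id or "A")
        if len(chain) == 0 or chain[len(chain) - 1].seqid.num != a.residue_seq or chain[
            len(chain) - 1
        ].name != a.residue_name:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq, " ")
            chain.add_residue(res)
        res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element if a.element != "other" else "X")
        atom.pos = gemmi.Position(*a.position)
        atom.occ = a.occupancy
        atom.serial = serial
        serial += 1
        res.add_atom(atom)
    for w in frame.waters:
        chain = get_chain(w.chain_id or "W")
        res = gemmi.Residue()
        res.name = "HOH"
        res.seqid = gemmi.SeqId(w.source_residue_seq or (w.water_id + 1), " ")
        res.het_flag = "H"
        chain.add_residue(res)
        res = chain[len(chain) - 1]
        names = ["O", "H1", "H2"]
        positions = [w.o_position, *w.h_positions]
        for name, pos in zip(names, positions):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*pos)
            atom.serial = serial
            serial += 1
            res.add_atom(atom)


def write_frames_pdb(
    frames: Sequence[Frame],
    path: str | Path,
    dt_ps: float | None = None,
    resolution_A: float | None = None,
) -> None:
    """Write frames as a (multi-MODEL) PDB file.

    Single frames are written without MODEL records.  ``dt_ps`` is
    recorded as a ``REMARK   6 DT_PS`` header so :func:`read_frames`
    can reconstruct frame times.
    """
    st = gemmi.Structure()
    st.name = "twn"
    box = frames[0].box if frames else None
    if box is not None:
        st.cell = gemmi.UnitCell(box[0], box[1], box[2], 90, 90, 90)
        st.spacegroup_hm = "P 1"
    remarks = []
    if resolution_A is not None:
        st.resolution = resolution_A
        remarks.append(f"REMARK   2 RESOLUTION.    {resolution_A:.2f} ANGSTROMS.")
    if dt_ps is not None:
        remarks.append(f"REMARK   6 DT_PS {dt_ps:g}")
    if remarks:
        # gemmi exposes raw_remarks as a copied list; assign, don't append
        st.raw_remarks = remarks
    for frame in frames:
        model = gemmi.Model(frame.frame_index + 1)
        _frame_into_model(frame, model)
        st.add_model(model)
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
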