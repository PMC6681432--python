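import numpy as np
import pytest

from twn.io import AtomRecord, Frame, WaterMolecule
from twn.synthetic import toy_residue, _water_hydrogens

OH = 0.9572


def make_water(water_id, o, h1_dir=None, hint=(0.0, 0.0, 1.0)):
    """Rigid-geometry water; no hydrogens when h1_dir is None."""
    o = np.asarray(o, dtype=float)
    if h1_dir is None:
        return WaterMolecule(water_id=water_id, o_position=o)
    return WaterMolecule(
        water_id=water_id,
        o_position=o,
        h_positions=_water_hydrogens(o, np.asarray(h1_dir, float), np.asarray(hint, float)),
    )


def near_linear_dimer(r_oo=2.75):
    """Donor at origin pointing one H at the acceptor along +x."""
    donor = make_water(0, (0, 0, 0), h1_dir=(1, 0, 0), hint=(0, 1, 0))
    acceptor = make_water(
        1, (r_oo, 0, 0), h1_dir=(0.3, 1, 0), hint=(0, 0, 1)
    )
    return donor, acceptor


@pytest.fixture
def dimer():
    return near_linear_dimer()


@pytest.fixture
def residue_atoms():
    return toy_residue()


@pytest.fixture
def one_residue_frame(residue_atoms):
    """Toy capped alanine with no waters."""
    return Frame(frame_index=0, waters=[], residue_atoms=residue_atoms)


def frame_with_waters(waters, atoms=None, box=None):
    return Frame(
        frame_index=0,
        waters=list(waters),
        residue_atoms=atoms if atoms is not None else toy_residue(),
        box=box,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
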