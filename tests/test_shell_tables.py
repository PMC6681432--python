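"""Hydration-shell extraction, ring assignment, and count-table aggregation."""

import numpy as np
import pytest

from twn.exceptions import AssignmentError, ConfigurationError
from twn.io import AtomRecord, Frame
from twn.rings import TWNRing, find_rings
from twn.hbond import build_graph
from twn.shell import (
    ShellConfig,
    aggregate,
    assign_ring,
    extract_shell,
    split_backbone_sidechain,
)
from twn.synthetic import PlantSpec, make_ring, make_scene, toy_residue
from twn.tables import CountsTable, round_half_up

from conftest import make_water, frame_with_waters


def ca_position():
    return next(a.position for a in toy_residue() if a.atom_name == "CA")


class TestExtractShell:
    @pytest.mark.parametrize("dist,inside", [(9.9, True), (10.1, False)])
    def test_radius_boundary(self, dist, inside):
        ca = ca_position()
        w = make_water(0, ca + np.array([dist, 0, 0]))
        frame = frame_with_waters([w])
        shell = extract_shell(frame, ShellConfig())
        assert (len(shell) == 1) is inside

    def test_matches_all_pairs_distance_oracle(self, rng):
        ca = ca_position()
        waters = [
            make_water(i, ca + rng.uniform(-14, 14, size=3)) for i in range(40)
        ]
        frame = frame_with_waters(waters)
        config = ShellConfig(radius_A=10.0)
        got = {w.water_id for w in extract_shell(frame, config)}
        refs = [a.position for a in toy_residue() if a.atom_name == "CA"]
        expected = {
            w.water_id
            for w in waters
            if any(np.linalg.norm(w.o_position - r) <= 10.0 for r in refs)
        }
        assert got == expected

    def test_all_heavy_reference_widens_shell(self):
        """A water near a side-chain tip but >10 A from the C-alpha is
        captured only under the all_heavy reference."""
        atoms = toy_residue()
        nme_c = next(a for a in atoms if a.residue_name == "NME" and a.atom_name == "CH3")
        # place along the CA->NME direction, 9 A past the NME methyl
        direction = nme_c.position - ca_position()
        direction /= np.linalg.norm(direction)
        w = make_water(0, nme_c.position + direction * 9.0)
        frame = frame_with_waters([w])
        assert extract_shell(frame, ShellConfig(reference="calpha")) == []
        got = extract_shell(
            frame, ShellConfig(reference="all_heavy", include_caps=True)
        )
        assert [x.water_id for x in got] == [0]

    def test_no_reference_atoms_is_configuration_error(self):
        frame = Frame(frame_index=0, waters=[], residue_atoms=[])
        with pytest.raises(ConfigurationError):
            extract_shell(frame, ShellConfig())

    def test_shrinking_radius_never_adds_rings(self):
        frame, _ = make_scene(PlantSpec(ring_sizes=(3, 4, 5), n_noise_waters=6, seed=13))
        counts = []
        for radius in (12.0, 10.0, 7.0, 4.0):
            waters = extract_shell(frame, ShellConfig(radius_A=radius))
            rings = find_rings(build_graph(waters, mode="energy"))
            counts.append(len(rings))
        assert counts == sorted(counts, reverse=True)


class TestAssignRing:
    def test_ring_near_carbonyl_oxygen(self):
        """A ring parked next to the backbone carbonyl O is assigned
        class O, region backbone."""
        atoms = toy_residue()
        carbonyl = next(
            a for a in atoms if a.residue_name == "ALA" and a.atom_name == "O"
        )
        direction = carbonyl.position - ca_position()
        direction /= np.linalg.norm(direction)
        waters = make_ring(3, center=carbonyl.position + direction * 3.5)
        frame = frame_with_waters(waters)
        ring = find_rings(build_graph(waters, mode="energy"))[0]
        a = assign_ring(ring, frame)
        assert a.nearest_atom.serial == carbonyl.serial
        assert a.atom_class == "O" and a.region == "backbone"
        assert a.residue_name == "ALA"

    def test_tie_breaks_to_lowest_serial(self):
        atoms = [
            AtomRecord(serial=s, atom_name=n, element="C", residue_name="ALA",
                       residue_seq=1, chain_id="A", position=p)
            for s, n, p in [(7, "CB", (4.0, 0, 0)), (5, "CA", (-4.0, 0, 0))]
        ]
        waters = [make_water(0, (0, 0, 0)), make_water(1, (0, 2.8, 0)),
                  make_water(2, (2.4, 1.4, 0))]
        # symmetric-enough fake ring: use water 0 only for distances
        ring = TWNRing(member_ids=(0, 1, 2), size=3, criterion_tag="distance")
        frame = Frame(frame_index=0, waters=waters, residue_atoms=atoms)
        # waters 0 is 4.0 from both atoms; water 2 is closer to serial 7
        # => min distance over ring oxygens decides, then serial
        d5 = min(np.linalg.norm(w.o_position - np.array([-4.0, 0, 0])) for w in waters)
        d7 = min(np.linalg.norm(w.o_position - np.array([4.0, 0, 0])) for w in waters)
        a = assign_ring(ring, frame)
        assert a.nearest_atom.serial == (5 if d5 < d7 else 7 if d7 < d5 else 5)

    def test_exact_tie_uses_serial(self):
        atoms = [
            AtomRecord(serial=s, atom_name="CB", element="C", residue_name="ALA",
                       residue_seq=1, chain_id="A", position=p)
            for s, p in [(9, (5.0, 0, 0)), (4, (-5.0, 0, 0))]
        ]
        waters = [make_water(0, (0, 0, 0)), make_water(1, (1.4, 2.4, 0)),
                  make_water(2, (-1.4, 2.4, 0))]
        ring = TWNRing(member_ids=(0, 1, 2), size=3)
        frame = Frame(frame_index=0, waters=waters, residue_atoms=atoms)
        a = assign_ring(ring, frame)
        assert a.nearest_atom.serial == 4

    def test_matches_exhaustive_distance_table(self, rng):
        frame, truth = make_scene(PlantSpec(ring_sizes=(4,), n_noise_waters=5, seed=21))
        ring = find_rings(build_graph(frame.waters, mode="energy"), sizes=(4,))[0]
        a = assign_ring(ring, frame)
        by_id = frame.water_by_id()
        best = min(
            (
                (min(float(np.linalg.norm(by_id[m].o_position - atom.position))
                     for m in ring.member_ids), atom.serial)
                for atom in frame.heavy_atoms()
            ),
        )
        assert (round(a.min_distance_A, 10), a.nearest_atom.serial) == (
            round(best[0], 10), best[1],
        )

    def test_caps_not_assignment_targets_by_default(self):
        atoms = toy_residue()
        ace_o = next(a for a in atoms if a.residue_name == "ACE" and a.atom_name == "O")
        direction = ace_o.position - ca_position()
        direction /= np.linalg.norm(direction)
        waters = make_ring(3, center=ace_o.position + direction * 3.0)
        frame = frame_with_waters(waters)
        ring = find_rings(build_graph(waters, mode="energy"))[0]
        assert assign_ring(ring, frame).nearest_atom.residue_name not in ("ACE", "NME")
        with_caps = assign_ring(ring, frame, ShellConfig(include_caps=True))
        assert with_caps.nearest_atom.serial == ace_o.serial

    def test_no_candidates_is_assignment_error(self):
        waters = make_ring(3)
        frame = Frame(frame_index=0, waters=list(waters), residue_atoms=[])
        ring = find_rings(build_graph(list(waters), mode="energy"))[0]
        with pytest.raises(AssignmentError):
            assign_ring(ring, frame)


def fake_assignments(spec):
    """Build RingAssignment-like records via aggregate()'s real path:
    construct single-water 'rings' near chosen atoms."""
    from twn.shell import RingAssignment

    out = []
    wid = 0
    for residue_name, atom_name, element, region, count in spec:
        atom = AtomRecord(
            serial=wid + 1, atom_name=atom_name, element=element,
            residue_name=residue_name, residue_seq=1, chain_id="A",
            position=(0, 0, 0),
        )
        for _ in range(count):
            ring = TWNRing(member_ids=(wid, wid + 1, wid + 2), size=3)
            out.append(
                RingAssignment(ring=ring, nearest_atom=atom, min_distance_A=3.0,
                               atom_class=element, region=region,
                               residue_name=residue_name)
            )
            wid += 3
    return out


class TestAggregate:
    def test_ile_md_column_arithmetic(self):
        """Class counts O=86, N=25, C=230 give Total 341 and ratios
        0.33 / 0.67."""
        a = fake_assignments([
            ("ILE", "O", "O", "backbone", 86),
            ("ILE", "N", "N", "backbone", 25),
            ("ILE", "CD1", "C", "sidechain", 230),
        ])
        table = aggregate(a, scope="combined", ring_size=3)
        assert int(table.totals["ILE"]) == 341
        r = table.rounded_ratios()
        assert r.at["O,N/Total", "ILE"] == pytest.approx(0.33)
        assert r.at["C/Total", "ILE"] == pytest.approx(0.67)

    def test_ile_crystal_column_arithmetic(self):
        a = fake_assignments([
            ("ILE", "O", "O", "backbone", 3514),
            ("ILE", "N", "N", "backbone", 377),
            ("ILE", "CD1", "C", "sidechain", 591),
        ])
        table = aggregate(a, scope="combined", ring_size=3)
        assert int(table.totals["ILE"]) == 4482
        assert table.rounded_ratios().at["O,N/Total", "ILE"] == pytest.approx(0.87)

    def test_half_up_rounding(self):
        # 215/344 = 0.625 -> printed as 0.63, not banker's 0.62
        assert round_half_up(215 / 344) == 0.63
        assert round_half_up(0.005, 2) == 0.01

    def test_backbone_plus_sidechain_equals_combined(self):
        spec = [
            ("ILE", "O", "O", "backbone", 5),
            ("ILE", "CD1", "C", "sidechain", 7),
            ("SER", "OG", "O", "sidechain", 3),
            ("SER", "N", "N", "backbone", 2),
        ]
        a = fake_assignments(spec)
        combined = aggregate(a, scope="combined", ring_size=3)
        backbone = aggregate(a, scope="backbone", ring_size=3)
        sidechain = aggregate(a, scope="sidechain", ring_size=3)
        summed = backbone.add(sidechain)
        assert combined.counts.equals(summed.counts)
        for t in (combined, backbone, sidechain):
            t.validate()

    def test_zero_assignments_gives_empty_table(self):
        table = aggregate([], scope="combined", ring_size=3)
        assert table.counts.empty or table.totals.sum() == 0
        rendered = table.render()
        assert (rendered == "").all().all() or rendered.empty

    def test_mixed_ring_sizes_rejected(self):
        from twn.shell import RingAssignment

        a3 = fake_assignments([("ILE", "O", "O", "backbone", 1)])
        atom = a3[0].nearest_atom
        a4 = RingAssignment(
            ring=TWNRing(member_ids=(0, 1, 2, 3), size=4),
            nearest_atom=atom, min_distance_A=3.0, atom_class="O",
            region="backbone", residue_name="ILE",
        )
        with pytest.raises(ValueError):
            aggregate(a3 + [a4], scope="combined", ring_size=3)

    def test_gly_sidechain_column_empty(self):
        """Glycine has no side-chain heavy atoms, so its side-chain
        column is blank."""
        a = fake_assignments([
            ("GLY", "CA", "C", "backbone", 10),
            ("GLY", "O", "O", "backbone", 4),
        ])
        sidechain = aggregate(a, scope="sidechain", ring_size=3)
        assert "GLY" not in sidechain.counts.columns or sidechain.totals["GLY"] == 0

    def test_split_partitions_assignments(self):
        a = fake_assignments([
            ("ILE", "O", "O", "backbone", 4),
            ("ILE", "CD1", "C", "sidechain", 6),
        ])
        backbone, sidechain = split_backbone_sidechain(a)
        assert len(backbone) == 4 and len(sidechain) == 6
        assert len(backbone) + len(sidechain) == len(a)
        assert split_backbone_sidechain([]) == ([], [])


class TestRenderRoundTrip:
    def test_tsv_round_trip_preserves_counts(self, tmp_path):
        a = fake_assignments([
            ("ILE", "O", "O", "backbone", 86),
            ("ILE", "N", "N", "backbone", 25),
            ("ILE", "CD1", "C", "sidechain", 230),
            ("CYS", "SG", "S", "sidechain", 93),
            ("CYS", "O", "O", "backbone", 97),
        ])
        table = aggregate(a, scope="combined", ring_size=3)
        p = tmp_path / "counts.tsv"
        table.to_tsv(p)
        back = CountsTable.read_tsv(p)
        assert back.counts.equals(table.counts)
        back.validate()

    def test_column_order_follows_hydropathy(self):
        a = fake_assignments([
            ("ARG", "NH1", "N", "sidechain", 1),
            ("ILE", "CD1", "C", "sidechain", 1),
            ("SER", "OG", "O", "sidechain", 1),
        ])
        table = aggregate(a, scope="combined", ring_size=3)
        assert list(table.counts.columns) == ["ILE", "SER", "ARG"]

    def test_blank_cells_for_zero_counts(self, tmp_path):
        a = fake_assignments([("ILE", "CD1", "C", "sidechain", 3)])
        rendered = aggregate(a, scope="combined", ring_size=3).render()
        assert rendered.at["S", "Ile"] == ""
        assert rendered.at["S/Total", "Ile"] == ""
        assert rendered.at["C/Total", "Ile"] == "1.00"
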