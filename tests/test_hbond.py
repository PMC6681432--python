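"""Hydrogen-bond criteria: TIP3P pair energy and crystal O-O distance."""

import numpy as np
import pytest

from twn.exceptions import CriterionUnavailableError, SingularGeometryError
from twn.hbond import (
    DistanceCriterion,
    TIP3PParams,
    build_graph,
    distance_edge,
    energy_edge,
    pair_energy,
)

from conftest import make_water, near_linear_dimer
from oracles import all_pairs_edges, pair_energy_oracle, water_sites


def random_water(rng, center_scale=10.0):
    o = rng.uniform(-center_scale, center_scale, size=3)
    return make_water(
        int(rng.integers(0, 10_000_000)), o, h1_dir=rng.normal(size=3), hint=rng.normal(size=3)
    )


class TestPairEnergy:
    def test_matches_nine_term_oracle_on_dimer(self, dimer):
        a, b = dimer
        expected = pair_energy_oracle(water_sites(a), water_sites(b))
        assert pair_energy(a, b) == pytest.approx(expected, abs=1e-6)

    def test_matches_oracle_on_random_geometries(self, rng):
        for _ in range(25):
            a, b = random_water(rng), random_water(rng)
            if np.linalg.norm(a.o_position - b.o_position) < 1.0:
                continue
            expected = pair_energy_oracle(water_sites(a), water_sites(b))
            assert pair_energy(a, b) == pytest.approx(expected, abs=1e-6)

    def test_symmetric(self, dimer):
        a, b = dimer
        assert pair_energy(a, b) == pytest.approx(pair_energy(b, a), abs=1e-10)

    def test_vanishes_at_long_range(self):
        a = make_water(0, (0, 0, 0), h1_dir=(1, 0, 0))
        b = make_water(1, (50, 0, 0), h1_dir=(0, 1, 0))
        assert abs(pair_energy(a, b)) < 0.05

    def test_rigid_motion_invariance(self, rng, dimer):
        a, b = dimer
        e0 = pair_energy(a, b)
        # random rotation + translation applied to both waters
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.uniform(-20, 20, size=3)

        def moved(wm, new_id):
            from twn.io import WaterMolecule

            return WaterMolecule(
                water_id=new_id,
                o_position=rot @ wm.o_position + t,
                h_positions=[rot @ h + t for h in wm.h_positions],
            )

        assert pair_energy(moved(a, 10), moved(b, 11)) == pytest.approx(e0, abs=1e-9)

    def test_requires_hydrogens(self):
        a = make_water(0, (0, 0, 0))
        b = make_water(1, (3, 0, 0), h1_dir=(1, 0, 0))
        with pytest.raises(CriterionUnavailableError):
            pair_energy(a, b)

    def test_coincident_oxygens_rejected(self):
        a = make_water(0, (0, 0, 0), h1_dir=(1, 0, 0))
        b = make_water(1, (0, 0, 0), h1_dir=(0, 1, 0))
        with pytest.raises(SingularGeometryError):
            pair_energy(a, b)

    def test_minimum_image_across_boundary(self):
        """A dimer split across the periodic boundary has the same
        energy as the unwrapped dimer."""
        box = np.array([20.0, 20.0, 20.0])
        a, b = near_linear_dimer()
        e0 = pair_energy(a, b, box=box)
        from twn.io import WaterMolecule

        b_wrapped = WaterMolecule(
            water_id=1,
            o_position=b.o_position + box * np.array([1, 0, 0]),
            h_positions=[h + box * np.array([1, 0, 0]) for h in b.h_positions],
        )
        assert pair_energy(a, b_wrapped, box=box) == pytest.approx(e0, abs=1e-9)

    def test_neutrality_enforced(self):
        with pytest.raises(ValueError):
            TIP3PParams(q_O=-0.8, q_H=0.417)


class TestEdgeCriteria:
    def test_energy_edge_certified_dimer(self, dimer):
        a, b = dimer
        e = pair_energy_oracle(water_sites(a), water_sites(b))
        assert e <= -2.25  # near-linear dimer at 2.75 A is a strong H-bond
        assert energy_edge(a, b)

    def test_energy_edge_inclusive_at_cutoff(self, dimer):
        """A pair whose energy equals the cutoff exactly counts as bonded."""
        a, b = dimer
        e = pair_energy(a, b)
        params = TIP3PParams(energy_cutoff=e)
        assert energy_edge(a, b, params)

    def test_energy_edge_false_at_long_range(self):
        a = make_water(0, (0, 0, 0), h1_dir=(1, 0, 0))
        b = make_water(1, (50, 0, 0), h1_dir=(0, 1, 0))
        assert not energy_edge(a, b)

    @pytest.mark.parametrize(
        "r_oo,expected", [(3.4, True), (3.5, False), (0.0, True)]
    )
    def test_distance_edge_strict_boundary(self, r_oo, expected):
        a = make_water(0, (0, 0, 0))
        b = make_water(1, (r_oo, 0, 0))
        assert distance_edge(a, b) is expected

    def test_distance_monotone_in_cutoff(self, rng):
        """Shrinking the O-O cutoff never adds edges."""
        waters = [make_water(i, rng.uniform(0, 15, size=3)) for i in range(25)]
        cutoffs = [4.5, 3.5, 3.0, 2.0]
        prev = None
        for c in cutoffs:
            g = build_graph(waters, mode="distance", criterion=DistanceCriterion(c))
            edges = set(g.edges)
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestBuildGraph:
    def test_empty_and_single(self):
        assert build_graph([], mode="distance").edges == []
        w = make_water(0, (0, 0, 0))
        g = build_graph([w], mode="distance")
        assert g.vertices == [0] and g.edges == []

    def test_equilateral_triangle(self):
        d = 2.8
        pts = [(0, 0, 0), (d, 0, 0), (d / 2, d * np.sqrt(3) / 2, 0)]
        waters = [make_water(i, p) for i, p in enumerate(pts)]
        g = build_graph(waters, mode="distance")
        assert g.edges == [(0, 1), (0, 2), (1, 2)]

    @pytest.mark.parametrize("mode", ["distance", "energy"])
    def test_pruned_equals_all_pairs(self, mode, rng):
        """KD-tree pruned graph is identical to the naive all-pairs
        oracle graph on random water boxes."""
        for trial in range(5):
            n = int(rng.integers(10, 40))
            waters = []
            while len(waters) < n:
                o = rng.uniform(0, 20, size=3)
                # keep duplicate-collapse out of this comparison
                if all(np.linalg.norm(o - w.o_position) > 0.6 for w in waters):
                    waters.append(
                        make_water(len(waters), o, h1_dir=rng.normal(size=3),
                                   hint=rng.normal(size=3))
                    )
            g = build_graph(waters, mode=mode)
            assert set(g.edges) == all_pairs_edges(waters, mode=mode)

    def test_no_edge_beyond_prune_radius(self, rng):
        """Under default parameters nothing bonds beyond 6 A, so the
        pruned search loses no edges (checked against the oracle with
        an enormous prune radius)."""
        waters = [
            make_water(i, rng.uniform(0, 12, size=3), h1_dir=rng.normal(size=3))
            for i in range(20)
        ]
        g_pruned = build_graph(waters, mode="energy")
        g_wide = build_graph(waters, mode="energy", prune_radius_A=100.0)
        assert g_pruned.edges == g_wide.edges

    def test_energy_mode_rejects_hydrogen_free_waters(self):
        waters = [make_water(0, (0, 0, 0)), make_water(1, (3, 0, 0))]
        with pytest.raises(CriterionUnavailableError):
            build_graph(waters, mode="energy")

    def test_duplicates_collapsed_with_warning(self):
        waters = [
            make_water(0, (0, 0, 0)),
            make_water(1, (0.1, 0, 0)),  # duplicate of 0
            make_water(2, (3.0, 0, 0)),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            g = build_graph(waters, mode="distance")
        assert g.vertices == [0, 2]
        assert g.collapsed_ids == [1]
        assert g.edges == [(0, 2)]

    def test_edge_tsv_export(self, tmp_path):
        waters = [make_water(0, (0, 0, 0)), make_water(1, (2.8, 0, 0))]
        g = build_graph(waters, mode="distance")
        out = tmp_path / "edges.tsv"
        g.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["water_id_a", "water_id_b", "r_oo_A", "energy_kcal_mol"]
        assert lines[1].startswith("0\t1\t2.8000\t")
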