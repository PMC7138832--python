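"""Geometry oracles: hull peeling, half-sphere exposure, depth, SASA,
sequence mapping."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull, QhullError

from methylsite.datasets import AtomRecord
from methylsite.struct_features import (
    GeometryConfig,
    Structure,
    SurfaceModel,
    build_extended_tripeptide,
    chops_layers,
    depth,
    half_sphere_exposure,
    l1_depth,
    map_structure_to_sequence,
    max_asa_reference,
    parse_pdb,
    relative_sasa,
    residue_chops,
    structure_chops,
    surface_points,
    unit_sphere_points,
)
from methylsite.synthetic import gen_toy_structure


def brute_force_peeling(points):
    """Independent reimplementation of iterative hull peeling."""
    pts = np.asarray(points, dtype=float)
    layers = np.zeros(len(pts), dtype=int)
    alive = list(range(len(pts)))
    layer = 1
    while alive:
        sub = pts[alive]
        degenerate = len(sub) < 4 or np.linalg.matrix_rank(sub - sub[0]) < 3
        if degenerate:
            for i in alive:
                layers[i] = layer
            break
        try:
            hull = ConvexHull(sub)
        except QhullError:
            for i in alive:
                layers[i] = layer
            break
        on = {alive[v] for v in hull.vertices}
        for i in on:
            layers[i] = layer
        alive = [i for i in alive if i not in on]
        layer += 1
    return layers


class TestChopsLayers:
    def test_tetrahedron_single_layer(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        assert np.array_equal(chops_layers(pts), [1, 1, 1, 1])

    def test_cube_with_centroid(self):
        corners = [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        pts = corners + [(0.5, 0.5, 0.5)]
        layers = chops_layers(pts)
        assert np.array_equal(layers[:8], [1] * 8)
        assert layers[8] == 2

    def test_matches_bruteforce_oracle_on_random_clouds(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 61))
            pts = rng.normal(size=(n, 3))
            pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
            pts *= rng.random((n, 1)) ** (1 / 3)  # uniform in the ball
            got = chops_layers(pts)
            assert np.array_equal(got, brute_force_peeling(pts))
            # layers form a contiguous range 1..max, each point assigned once
            assert got.min() == 1
            assert set(got) == set(range(1, got.max() + 1))

    def test_degenerate_coplanar_cloud(self):
        pts = np.column_stack(
            [np.arange(10.0), np.arange(10.0) ** 2, np.zeros(10)]
        )
        assert np.array_equal(chops_layers(pts), [1] * 10)


class TestResidueChops:
    def test_exposed_lysine_on_first_hull(self):
        s = parse_pdb(gen_toy_structure(30, [10], ["exposed"], seed=4))
        assert residue_chops(s, "A", 10) == 1

    def test_buried_lysine_interior(self):
        s = parse_pdb(gen_toy_structure(30, [15], ["buried"], seed=4))
        assert residue_chops(s, "A", 15) >= 2

    def test_equals_oracle_layer_of_key_atom(self, rng):
        for seed in range(3):
            s = parse_pdb(
                gen_toy_structure(25, [8, 16], ["exposed", "buried"], seed=seed)
            )
            oracle = brute_force_peeling(s.coords)
            layers = structure_chops(s)
            for res_seq in (8, 16):
                nz = s.residue_atoms("A", res_seq)["NZ"]
                assert residue_chops(s, "A", res_seq, layers) == oracle[nz]

    def test_arginine_uses_min_of_nh_atoms(self):
        s = parse_pdb(
            gen_toy_structure(30, [12], ["exposed"], seed=2, residue="R")
        )
        layers = structure_chops(s)
        atoms = s.residue_atoms("A", 12)
        expect = min(layers[atoms["NH1"]], layers[atoms["NH2"]])
        assert residue_chops(s, "A", 12, layers) == expect

    def test_missing_key_atom_is_error(self):
        atoms = [
            AtomRecord(1, "CA", "C", "A", 1, "LYS", (0.0, 0.0, 0.0), 1.7),
            AtomRecord(2, "CA", "C", "A", 2, "ALA", (3.8, 0.0, 0.0), 1.7),
        ]
        with pytest.raises(ValueError, match="NZ"):
            residue_chops(Structure(atoms), "A", 1)


@pytest.fixture(scope="module")
def helix():
    return parse_pdb(gen_toy_structure(40, [], [], seed=9))


class TestHalfSphereExposure:

    def test_no_neighbours_within_tiny_radius(self, helix):
        for v in ("AU", "AD", "BU", "BD"):
            assert half_sphere_exposure(helix, "A", 20, 0.5, v) == 0

    def test_partition_identity(self, helix):
        # up + down == total CA neighbours within radius, for both variants
        for res_seq in (5, 20, 35):
            ca = helix.coords[helix.ca_index("A", res_seq)]
            for radius in (8.0, 13.0, 20.0):
                total = 0
                for key in helix.residue_keys():
                    if key == ("A", res_seq):
                        continue
                    other = helix.ca_index(*key)
                    d = np.linalg.norm(helix.coords[other] - ca)
                    if d <= radius:
                        total += 1
                for x in ("A", "B"):
                    up = half_sphere_exposure(helix, "A", res_seq, radius, x + "U")
                    down = half_sphere_exposure(helix, "A", res_seq, radius, x + "D")
                    assert up + down == total

    def test_counts_nondecreasing_in_radius(self, helix):
        for v in ("AU", "BD"):
            counts = [
                half_sphere_exposure(helix, "A", 10, r, v)
                for r in (5, 10, 15, 20, 25, 30)
            ]
            assert counts == sorted(counts)

    def test_matches_enumeration_oracle(self, helix):
        # independent dot-product enumeration for the B variant
        res_seq, radius = 20, 13.0
        atoms = helix.residue_atoms("A", res_seq)
        ca = helix.coords[helix.ca_index("A", res_seq)]
        u = helix.coords[atoms["CB"]] - ca
        up = down = 0
        for key in helix.residue_keys():
            if key == ("A", res_seq):
                continue
            v = helix.coords[helix.ca_index(*key)] - ca
            if np.linalg.norm(v) <= radius:
                if np.dot(v, u) > 0:
                    up += 1
                else:
                    down += 1
        assert half_sphere_exposure(helix, "A", res_seq, radius, "BU") == up
        assert half_sphere_exposure(helix, "A", res_seq, radius, "BD") == down

    def test_isolated_residue_a_variant_error(self):
        atoms = [AtomRecord(1, "CA", "C", "A", 1, "GLY", (0.0, 0.0, 0.0), 1.7)]
        with pytest.raises(ValueError):
            half_sphere_exposure(Structure(atoms), "A", 1, 13.0, "AU")


class TestSurfaceAndDepth:
    def test_single_atom_keeps_all_points(self):
        atoms = [AtomRecord(1, "CA", "C", "A", 1, "ALA", (0.0, 0.0, 0.0), 1.7)]
        pts = surface_points(Structure(atoms), probe=1.4, n_sphere=96)
        assert len(pts) == 96
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.7 + 1.4)

    def test_enclosed_atom_contributes_nothing(self):
        # dense shell of atoms around the origin occludes the central atom
        shell_pts = unit_sphere_points(60) * 2.2
        atoms = [AtomRecord(1, "CA", "C", "A", 1, "ALA", (0.0, 0.0, 0.0), 1.7)]
        atoms += [
            AtomRecord(i + 2, "CA", "C", "B", i + 1, "ALA", tuple(p), 1.7)
            for i, p in enumerate(shell_pts)
        ]
        surf = SurfaceModel(Structure(atoms), probe=1.4, n_sphere=96)
        assert surf.kept_fraction[0] == 0.0

    def test_two_atom_dimer_matches_cap_area(self):
        # fraction of sphere points surviving = 1 - cap area / full area,
        # cap height h = r - d/2 for equal radii spheres at distance d
        r, d = 1.7 + 1.4, 2.0
        atoms = [
            AtomRecord(1, "CA", "C", "A", 1, "ALA", (0.0, 0.0, 0.0), 1.7),
            AtomRecord(2, "CA", "C", "A", 2, "ALA", (d, 0.0, 0.0), 1.7),
        ]
        surf = SurfaceModel(Structure(atoms), probe=1.4, n_sphere=960)
        h = r - d / 2
        expect = 1.0 - (2 * math.pi * r * h) / (4 * math.pi * r * r)
        assert surf.kept_fraction[0] == pytest.approx(expect, abs=0.03)

    def test_isolated_atom_depth_is_expanded_radius(self):
        atoms = [AtomRecord(1, "NZ", "N", "A", 1, "LYS", (0.0, 0.0, 0.0), 1.55)]
        s = Structure(atoms)
        surf = SurfaceModel(s, probe=1.4, n_sphere=96)
        res_d, atom_d = depth(s, "A", 1, surf)
        assert atom_d == pytest.approx(1.55 + 1.4)
        assert res_d == pytest.approx(1.55 + 1.4)

    def test_central_atom_deeper_than_shell(self):
        shell_pts = unit_sphere_points(40) * 4.0
        atoms = [AtomRecord(1, "CA", "C", "A", 1, "ALA", (0.0, 0.0, 0.0), 1.7)]
        atoms += [
            AtomRecord(i + 2, "CA", "C", "B", i + 1, "ALA", tuple(p), 1.7)
            for i, p in enumerate(shell_pts)
        ]
        s = Structure(atoms)
        surf = SurfaceModel(s, probe=1.4, n_sphere=192)
        _, center_depth = depth(s, "A", 1, surf)
        _, shell_depth = depth(s, "B", 1, surf)
        assert center_depth > shell_depth

    def test_depth_matches_bruteforce_min_distance(self, rng):
        coords = rng.normal(scale=3.0, size=(12, 3))
        atoms = [
            AtomRecord(i + 1, "CA", "C", "A", i + 1, "ALA", tuple(p), 1.7)
            for i, p in enumerate(coords)
        ]
        s = Structure(atoms)
        surf = SurfaceModel(s, probe=1.4, n_sphere=96)
        for res_seq in (1, 5, 9):
            res_d, atom_d = depth(s, "A", res_seq, surf)
            x = coords[res_seq - 1]
            brute = np.min(np.linalg.norm(surf.points - x, axis=1))
            assert atom_d == pytest.approx(brute)
            assert res_d == pytest.approx(brute)


class TestL1Depth:
    def _structure_with_ca(self, coords):
        atoms = [
            AtomRecord(i + 1, "CA", "C", "A", i + 1, "ALA", tuple(p), 1.7)
            for i, p in enumerate(coords)
        ]
        return Structure(atoms)

    def test_octahedral_symmetry_gives_one(self):
        coords = [
            (3, 0, 0), (-3, 0, 0), (0, 3, 0), (0, -3, 0), (0, 0, 3), (0, 0, -3),
        ]
        s = self._structure_with_ca(coords)
        assert l1_depth((0, 0, 0), s, 10.0, "res") == pytest.approx(1.0)

    def test_far_point_limit_is_zero(self):
        coords = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 1)]
        s = self._structure_with_ca(coords)
        val = l1_depth((1e6, 0, 0), s, 1e7, "res")
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_matches_vector_sum_oracle(self, rng):
        coords = rng.normal(scale=5.0, size=(20, 3))
        s = self._structure_with_ca(coords)
        for _ in range(10):
            x = rng.normal(scale=4.0, size=3)
            radius = float(rng.uniform(4, 12))
            d = coords - x
            norms = np.linalg.norm(d, axis=1)
            mask = (norms <= radius) & (norms > 0)
            got = l1_depth(x, s, radius, "res")
            if not mask.any():
                assert math.isnan(got)
            else:
                units = d[mask] / norms[mask, None]
                expect = 1 - np.linalg.norm(units.mean(axis=0))
                assert got == pytest.approx(expect)
                assert 0.0 <= got <= 1.0 + 1e-12

    def test_no_neighbours_reported_missing(self):
        s = self._structure_with_ca([(0, 0, 0)])
        assert math.isnan(l1_depth((50.0, 0, 0), s, 5.0, "res"))


class TestRelativeSasa:
    def test_isolated_atom_full_sphere_area(self):
        atoms = [AtomRecord(1, "CA", "C", "A", 1, "ALA", (0.0, 0.0, 0.0), 1.7)]
        surf = SurfaceModel(Structure(atoms), probe=1.4, n_sphere=960)
        area = surf.atom_sasa()[0]
        assert area == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2)

    def test_extended_tripeptide_lysine_near_one(self):
        # self-consistency with the builder behind the reference table
        tri = build_extended_tripeptide("LYS")
        cfg = GeometryConfig(sphere_points=192)
        rsa_total, rsa_side = relative_sasa(tri, "A", 2, cfg)
        assert 0.9 <= rsa_total <= 1.1
        assert 0.9 <= rsa_side <= 1.1

    def test_enclosed_residue_zero(self):
        shell_pts = unit_sphere_points(80) * 2.4
        atoms = [AtomRecord(1, "CA", "C", "A", 1, "ALA", (0.0, 0.0, 0.0), 1.7)]
        atoms += [
            AtomRecord(i + 2, "CA", "C", "B", i + 1, "ALA", tuple(p), 1.7)
            for i, p in enumerate(shell_pts)
        ]
        s = Structure(atoms)
        cfg = GeometryConfig(sphere_points=96)
        surf = SurfaceModel(s, probe=1.4, n_sphere=96)
        total, side = relative_sasa(s, "A", 1, cfg, surf)
        assert total == 0.0

    def test_unknown_residue_type_rejected(self):
        atoms = [AtomRecord(1, "CA", "C", "A", 1, "XXX", (0.0, 0.0, 0.0), 1.7)]
        with pytest.raises(ValueError, match="reference"):
            relative_sasa(Structure(atoms), "A", 1, GeometryConfig(sphere_points=96))

    def test_reference_table_covers_standard_residues(self):
        table = max_asa_reference(1.4, 96)
        assert len(table) == 20
        assert all(t > 0 and s >= 0 for t, s in table.values())
        assert table["GLY"][1] == 0.0  # no side chain


class TestParsePdb:
    def test_single_atom(self):
        line = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C"
        )
        s = parse_pdb(line + "\nEND\n")
        assert len(s.atoms) == 1
        assert s.atoms[0].vdw_radius == 1.70

    def test_altloc_b_dropped(self):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C",
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50  0.00           C",
            "END",
        ]
        s = parse_pdb("\n".join(lines))
        assert len(s.atoms) == 1
        assert s.atoms[0].coord == (0.0, 0.0, 0.0)

    def test_hetatm_and_hydrogen_dropped(self):
        lines = [
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  H   ALA A   1       0.500   0.000   0.000  1.00  0.00           H",
            "HETATM    3  O   HOH A 101       5.000   0.000   0.000  1.00  0.00           O",
            "END",
        ]
        s = parse_pdb("\n".join(lines))
        assert len(s.atoms) == 1

    def test_toy_structure_roundtrips_atom_count(self):
        text = gen_toy_structure(20, [5], ["exposed"], seed=0)
        n_atom_lines = sum(1 for ln in text.splitlines() if ln.startswith("ATOM"))
        s = parse_pdb(text)
        assert len(s.atoms) == n_atom_lines

    def test_no_atoms_is_error(self):
        with pytest.raises(ValueError):
            parse_pdb("REMARK nothing here\nEND\n")


class TestSequenceMapping:
    def test_identity_map(self):
        s = parse_pdb(gen_toy_structure(15, [], [], seed=1))
        seq = s.chain_sequence("A")
        mapping = map_structure_to_sequence(s, seq)
        assert mapping == {i + 1: i + 1 for i in range(15)}

    def test_offset_by_two(self):
        s = parse_pdb(gen_toy_structure(15, [], [], seed=1))
        seq = "MG" + s.chain_sequence("A")
        mapping = map_structure_to_sequence(s, seq)
        assert mapping == {i + 1: i + 3 for i in range(15)}

    def test_internal_gap_hand_alignment(self):
        s = parse_pdb(gen_toy_structure(12, [4, 8], ["exposed", "exposed"], seed=1))
        chain_seq = s.chain_sequence("A")  # AAAKAAAKAAAA
        target = chain_seq[:6] + "WW" + chain_seq[6:]
        mapping = map_structure_to_sequence(s, target)
        for res_seq, pos in mapping.items():
            assert chain_seq[res_seq - 1] == target[pos - 1]
        assert mapping[1] == 1
        assert mapping[12] == 14

    def test_low_identity_gives_empty_map(self, caplog):
        s = parse_pdb(gen_toy_structure(15, [], [], seed=1))
        with caplog.at_level("WARNING"):
            mapping = map_structure_to_sequence(s, "W" * 15)
        assert mapping == {}
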