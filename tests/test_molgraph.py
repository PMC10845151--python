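"""Graph construction and eigenvalue-fingerprint comparison."""

import numpy as np
import pytest
import scipy.linalg

from deltabh.geometry import ElementError, Geometry, GeometryError, read_xyz, write_xyz
from deltabh.molgraph import (
    MolecularGraph,
    build_graph,
    same_conformation,
    same_connectivity,
    spectrum_fingerprint,
    weighted_fingerprint,
)

from conftest import random_molgraph


class TestBuildGraph:
    def test_methane_bonds(self, methane):
        g = build_graph(methane)
        assert g.n_edges == 4
        assert all(g.adjacency[0, i] == 1 for i in range(1, 5))  # C-H only
        assert g.adjacency[1:, 1:].sum() == 0  # no H-H

    def test_single_atom(self):
        g = build_graph(Geometry(("O",), np.zeros((1, 3))))
        assert g.n_atoms == 1 and g.n_edges == 0

    def test_formaldehyde_edges_match_bruteforce(self, formaldehyde):
        g = build_graph(formaldehyde, scale=1.2)
        # independent oracle: all-pairs distance vs threshold with the same table
        radii = {"H": 0.31, "C": 0.76, "O": 0.66}
        expected = set()
        for i in range(4):
            for j in range(i + 1, 4):
                d = np.linalg.norm(formaldehyde.coords[i] - formaldehyde.coords[j])
                if d <= 1.2 * (radii[formaldehyde.symbols[i]] + radii[formaldehyde.symbols[j]]):
                    expected.add((i, j))
        assert set(g.edges()) == expected == {(0, 1), (0, 2), (0, 3)}

    def test_overlapping_atoms_rejected(self):
        geom = Geometry(("C", "C"), np.array([[0, 0, 0], [0, 0, 0.3]]))
        with pytest.raises(GeometryError):
            build_graph(geom)

    def test_unsupported_element_rejected(self):
        with pytest.raises(ElementError):
            Geometry(("C", "S"), np.array([[0, 0, 0], [0, 0, 1.8]]))

    @pytest.mark.parametrize("scale", [0.9, 1.6])
    def test_scale_out_of_range(self, methane, scale):
        with pytest.raises(ValueError):
            build_graph(methane, scale=scale)


class TestSpectrumFingerprint:
    def test_two_node_ch_closed_form(self):
        g = MolecularGraph(np.array([[0, 1], [1, 0]]), np.array([6, 1]))
        expected = np.sort([(7 + np.sqrt(29)) / 2, (7 - np.sqrt(29)) / 2])
        assert np.allclose(spectrum_fingerprint(g), expected, atol=1e-12)

    def test_edgeless_graph_gives_sorted_atomic_numbers(self):
        g = MolecularGraph(np.zeros((3, 3), dtype=int), np.array([8, 1, 6]))
        assert np.allclose(spectrum_fingerprint(g), [1, 6, 8])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        g = random_molgraph(rng)
        fp = spectrum_fingerprint(g)
        for _ in range(20):
            order = rng.permutation(g.n_atoms)
            assert np.allclose(spectrum_fingerprint(g.permuted(list(order))), fp, atol=1e-10)

    def test_matches_independent_solver_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_molgraph(rng)
            m = g.adjacency.astype(float) + np.diag(g.atomic_numbers.astype(float))
            oracle = np.sort(np.real(scipy.linalg.eigvals(m)))
            assert np.max(np.abs(spectrum_fingerprint(g) - oracle)) < 1e-8


HCN_ADJ = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])  # H-C-N chain
HNC_ADJ = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]])  # H-N, N-C


class TestSameConnectivity:
    def test_self_comparison(self):
        g = MolecularGraph(HCN_ADJ, np.array([1, 6, 7]))
        assert same_connectivity(g, g)

    def test_hcn_vs_hnc_differ(self):
        a = MolecularGraph(HCN_ADJ, np.array([1, 6, 7]))
        b = MolecularGraph(HNC_ADJ, np.array([1, 6, 7]))
        assert not same_connectivity(a, b)

    def test_size_mismatch(self):
        a = MolecularGraph(np.zeros((2, 2), dtype=int), np.array([6, 1]))
        b = MolecularGraph(np.zeros((3, 3), dtype=int), np.array([6, 1, 1]))
        assert not same_connectivity(a, b)

    def test_distinct_four_node_graphs_distinguishable(self):
        # six distinct CHNO 4-node graphs: no false merges at tol 1e-4
        z = np.array([6, 7, 8, 1])
        chain = np.array([[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]])
        star_c = np.array([[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]])
        ring = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]])
        chain_swap = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0]])
        tri = np.array([[0, 1, 1, 0], [1, 0, 1, 0], [1, 1, 0, 1], [0, 0, 1, 0]])
        two_pairs = np.array([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]])
        graphs = [MolecularGraph(a, z) for a in (chain, star_c, ring, chain_swap, tri, two_pairs)]
        for i in range(len(graphs)):
            for j in range(i + 1, len(graphs)):
                assert not same_connectivity(graphs[i], graphs[j], tol=1e-4), (i, j)


class TestWeightedFingerprint:
    def test_identical_geometries(self, formaldehyde):
        assert same_conformation(formaldehyde, formaldehyde)

    def test_stretched_bond_detected(self, formaldehyde):
        coords = formaldehyde.coords.copy()
        coords[1, 2] *= 1.2  # stretch C=O
        stretched = Geometry(formaldehyde.symbols, coords)
        fa = weighted_fingerprint(formaldehyde)
        fb = weighted_fingerprint(stretched)
        assert np.max(np.abs(fa - fb)) > 1e-3

    def test_rotation_and_permutation_invariant(self, methane):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        order = list(rng.permutation(methane.n_atoms))
        rotated = Geometry(methane.symbols, methane.coords @ q).permuted(order)
        assert np.max(np.abs(weighted_fingerprint(methane) - weighted_fingerprint(rotated))) < 1e-8

    def test_mirror_image_not_distinguished(self, formaldehyde):
        # reflection preserves all distances: a recorded limitation
        mirrored = Geometry(formaldehyde.symbols, formaldehyde.coords * [1, 1, -1])
        assert same_conformation(formaldehyde, mirrored)

    def test_rotamers_distinguished(self):
        # anti vs gauche butane-like H3C-CH2-CH2-CH3 heavy-atom chain (with H
        # omitted): torsion change alters nonbonded C1..C4 distance
        def chain(torsion_deg):
            d = 1.52
            ang = np.deg2rad(111.0)
            t = np.deg2rad(torsion_deg)
            c1 = np.array([0.0, 0.0, 0.0])
            c2 = np.array([d, 0.0, 0.0])
            c3 = c2 + d * np.array([-np.cos(ang), np.sin(ang), 0.0])
            u = c3 - c2
            # place c4 with given dihedral about the c2-c3 axis
            axis = u / np.linalg.norm(u)
            v0 = -u
            perp = np.cross(axis, [0.0, 0.0, 1.0])
            rot = (
                np.cos(t) * perp / np.linalg.norm(perp)
                + np.sin(t) * np.cross(axis, perp / np.linalg.norm(perp))
            )
            c4 = c3 + d * (np.cos(np.pi - ang) * axis + np.sin(np.pi - ang) * rot / np.linalg.norm(rot))
            return Geometry(("C", "C", "C", "C"), np.vstack([c1, c2, c3, c4]))

        anti, gauche = chain(180.0), chain(60.0)
        ga, gg = build_graph(anti), build_graph(gauche)
        assert same_connectivity(ga, gg)
        assert not same_conformation(anti, gauche)


def test_xyz_roundtrip(tmp_path, methane, formaldehyde):
    path = tmp_path / "mols.xyz"
    write_xyz(path, [methane, formaldehyde], comments=["methane", "h2co"])
    back = read_xyz(path)
    assert len(back) == 2
    assert back[0].symbols == methane.symbols
    assert np.allclose(back[1].coords, formaldehyde.coords, atol=1e-7)
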