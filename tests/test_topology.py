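"""Toy-fold generation, PDB-derived topologies, disulfide detection, and
the inextensibility bound."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ssmech.topology import (SS_CUTOFF, ToyFoldSpec, default_toy_spec,
                             detect_disulfides, generate_toy_fold,
                             load_structure, max_extension_bound,
                             rnase_mimic_spec, write_pdb, write_topology)


class TestToyFoldSpec:
    def test_blocks_must_tile_chain(self):
        with pytest.raises(ValueError, match="tile"):
            ToyFoldSpec(n_residues=10, blocks=(("loop", 4),))

    def test_crosslink_in_helix_rejected(self):
        with pytest.raises(ValueError, match="helix"):
            ToyFoldSpec(n_residues=10, blocks=(("helix", 10),),
                        crosslinks=((2, 7),))

    def test_crosslink_outside_chain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ToyFoldSpec(n_residues=10, blocks=(("loop", 10),),
                        crosslinks=((2, 12),))


class TestGenerateToyFold:
    def test_linear_chain_without_crosslinks(self):
        spec = ToyFoldSpec(n_residues=20, blocks=(("loop", 20),), seed=0)
        topo, coords = generate_toy_fold(spec)
        assert topo.crosslinks == []
        assert len(topo.backbone_bonds) == 19
        assert topo.n_residues == 20

    def test_seed_determinism_bitwise(self):
        spec = default_toy_spec(7)
        t1, c1 = generate_toy_fold(spec)
        t2, c2 = generate_toy_fold(spec)
        assert np.array_equal(c1, c2)
        assert t1.crosslinks == t2.crosslinks
        assert [b.r0 for b in t1.native_contacts] == [b.r0 for b in t2.native_contacts]

    def test_different_seed_different_fold(self):
        c1 = generate_toy_fold(default_toy_spec(1))[1]
        c2 = generate_toy_fold(default_toy_spec(2))[1]
        assert not np.allclose(c1, c2)

    def test_rnase_mimic_has_four_closed_crosslinks(self, mimic):
        topo, coords = mimic
        assert topo.n_residues == 124
        assert topo.crosslinks == [(25, 83), (39, 94), (57, 109), (64, 71)]
        for i, j in topo.crosslinks:
            d = np.linalg.norm(coords[topo.sc_index[i]] - coords[topo.sc_index[j]])
            assert d < SS_CUTOFF

    def test_self_avoiding(self, toy):
        topo, coords = toy
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        resid = topo.bead_residues()
        far = np.abs(resid[:, None] - resid[None, :]) > 1
        assert d[far].min() >= 2.0

    def test_native_contacts_respect_sequence_separation(self, toy):
        topo, _ = toy
        assert all(abs(c.i - c.j) >= 3 for c in topo.native_contacts)

    def test_elements_label_contacts(self, toy):
        topo, _ = toy
        labels = {c.element for c in topo.native_contacts}
        assert "H1" in labels          # helix-internal contacts
        assert any(l.startswith("B1-") for l in labels)  # sheet pairing
        assert "SS" in labels          # crosslink side-center contacts


class TestDetectDisulfides:
    def test_cutoff_boundary(self, tiny_pair):
        topo, _ = tiny_pair
        topo = _with_cbeta(topo, {2: [0, 0, 0], 5: [5.4, 0, 0]})
        assert detect_disulfides(topo) == [(2, 5)]
        topo = _with_cbeta(topo, {2: [0, 0, 0], 5: [5.6, 0, 0]})
        assert detect_disulfides(topo) == []

    def test_greedy_one_partner_per_cysteine(self):
        spec = ToyFoldSpec(n_residues=14, blocks=(("loop", 14),),
                           crosslinks=((2, 6), (6, 10)), seed=5)
        topo, _ = generate_toy_fold(spec)
        topo = _with_cbeta(topo, {2: [0, 0, 0], 6: [4.0, 0, 0], 10: [8.5, 0, 0]})
        # 2-6 is closest; 6 is then taken, and 2-10 is out of range
        assert detect_disulfides(topo) == [(2, 6)]

    def test_native_toy_fold_recovers_spec_pairs(self, toy, mimic):
        for topo, coords in (toy, mimic):
            assert detect_disulfides(topo, coords) == topo.crosslinks


def _with_cbeta(topo, cbeta):
    import copy
    t = copy.copy(topo)
    t.cbeta = {k: np.asarray(v, dtype=float) for k, v in cbeta.items()}
    return t


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  C   ALA A   1       2.000  -1.400   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.300  -2.400   0.000  1.00  0.00           O
ATOM      6  N   GLY A   2       3.300  -1.400   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.100  -2.600   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.600  -2.300   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.100  -1.200   0.000  1.00  0.00           O
ATOM     10  N   SER A   3       6.300  -3.400   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       7.700  -3.500   0.500  1.00  0.00           C
ATOM     12  CB  SER A   3       8.300  -4.900   0.500  1.00  0.00           C
ATOM     13  OG  SER A   3       9.700  -4.800   0.700  1.00  0.00           O
ATOM     14  C   SER A   3       8.500  -2.400   1.200  1.00  0.00           C
ATOM     15  O   SER A   3       8.000  -1.600   2.000  1.00  0.00           O
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40  0.00           C
ATOM      3  CA BALA A   1       1.600   0.100   0.000  0.60  0.00           C
ATOM      4  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      5  C   ALA A   1       2.000  -1.400   0.000  1.00  0.00           C
ATOM      6  O   ALA A   1       1.300  -2.400   0.000  1.00  0.00           O
ATOM      7  N   GLY A   2       3.300  -1.400   0.000  1.00  0.00           N
ATOM      8  CA  GLY A   2       4.100  -2.600   0.000  1.00  0.00           C
ATOM      9  C   GLY A   2       5.600  -2.300   0.000  1.00  0.00           C
ATOM     10  O   GLY A   2       6.100  -1.200   0.000  1.00  0.00           O
TER
END
"""


class TestLoadStructure:
    def test_three_residue_fixture_round_trip(self):
        topo, coords = load_structure(THREE_RESIDUE_PDB)
        assert topo.n_residues == 3
        assert [b.index for b in topo.beads if b.kind == "backbone-center"] == [0, 1, 2]
        # side centroid of SER = mean of CB and OG
        sc = coords[topo.sc_index[2]]
        assert sc == pytest.approx([(8.3 + 9.7) / 2, (-4.9 - 4.8) / 2, 0.6], abs=1e-3)

    def test_altloc_reduced_to_highest_occupancy(self):
        topo, coords = load_structure(ALTLOC_PDB)
        assert topo.n_residues == 2
        n_bb = sum(1 for b in topo.beads if b.kind == "backbone-center")
        assert n_bb == 2
        assert coords[topo.bb_index[0]][0] == pytest.approx(1.6, abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            load_structure("END\n")

    def test_mimic_pdb_round_trip(self, mimic, tmp_path):
        """The synthetic RNase-A stand-in written as PDB reloads with 124
        residues and exactly the four published disulfide pairs."""
        topo, coords = mimic
        path = tmp_path / "synthetic_rnase_mimic.pdb"
        write_pdb(topo, coords, path)
        t2, c2 = load_structure(path.read_text())
        assert t2.n_residues == 124
        pairs_1based = [(i + 1, j + 1) for i, j in detect_disulfides(t2, c2)]
        assert pairs_1based == [(26, 84), (40, 95), (58, 110), (65, 72)]


class TestMaxExtensionBound:
    def test_linear_chain_geometry(self):
        spec = ToyFoldSpec(n_residues=20, blocks=(("loop", 20),),
                           anchors=(0, 19), seed=0)
        topo, _ = generate_toy_fold(spec)
        assert max_extension_bound(topo) == pytest.approx(19 * 3.8)

    def test_single_crosslink_shortcut_formula(self):
        spec = ToyFoldSpec(n_residues=16, blocks=(("loop", 16),),
                           crosslinks=((3, 12),), anchors=(0, 15), seed=0)
        topo, _ = generate_toy_fold(spec)
        i, j, n = 3, 12, 16
        expected = (i + (n - 1 - j)) * 3.8 + 4.0
        assert max_extension_bound(topo) == pytest.approx(expected)

    def test_against_exhaustive_path_oracle(self, mimic):
        topo, _ = mimic
        g = nx.Graph()
        for i, j, r0 in topo.backbone_bonds:
            g.add_edge(i, j, weight=r0)
        for i, j in topo.crosslinks:
            g.add_edge(i, j, weight=4.0)
        a, b = topo.anchors
        # enumerate all simple paths (few, thanks to the nested crosslinks)
        best = min(
            sum(g[u][v]["weight"] for u, v in itertools.pairwise(p))
            for p in nx.all_simple_paths(g, a, b))
        assert max_extension_bound(topo) == pytest.approx(best)

    def test_monotone_under_crosslink_removal(self, mimic):
        topo, _ = mimic
        xl = topo.crosslinks
        prev = max_extension_bound(topo, xl)
        for k in range(len(xl) - 1, -1, -1):
            cur = max_extension_bound(topo, xl[:k])
            assert cur >= prev - 1e-9
            prev = cur


def test_topology_tsv_bundle_written(toy, tmp_path):
    import pandas as pd

    topo, _ = toy
    prefix = tmp_path / "toy"
    write_topology(topo, prefix)
    beads = pd.read_csv(f"{prefix}_beads.tsv", sep="\t")
    assert len(beads) == topo.n_beads
    contacts = pd.read_csv(f"{prefix}_contacts.tsv", sep="\t")
    assert len(contacts) == len(topo.native_contacts)
    lines = (tmp_path / "toy_crosslinks.tsv").read_text().splitlines()
    assert lines[0].startswith("# cysteines")
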