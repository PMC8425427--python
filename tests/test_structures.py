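"""Structure parsing, distance/contact maps, SASA, interface area, filters."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from c2contact.structures import (DimerStructure, MonomerStructure, Residue,
                                  StructureRecord, hydrophobicity_features,
                                  inter_contact_map, interface_area,
                                  intra_distance_map, min_heavy_atom_distance,
                                  parse_structure, passes_dataset_filters,
                                  sasa, write_pdb)
from c2contact.constants import WIMLEY_WHITE

from conftest import brute_force_sasa, pdb_line


def _res(name, *coords, observed=True, author=1):
    atoms = [(f"C{i}", "C", tuple(map(float, c)), 1.0, "")
             for i, c in enumerate(coords)]
    return Residue(name, atoms, observed, (author, ""))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParsing:
    def test_minimal_two_residue_chain(self, write_pdb_text):
        path = write_pdb_text([
            pdb_line(1, "CA", "ALA", 1, (0, 0, 0)),
            pdb_line(2, "CA", "GLY", 2, (3.8, 0, 0)),
        ])
        m = parse_structure(path, "A")
        assert len(m) == 2
        assert m.sequence == "AG"
        assert sum(len(r.atoms) for r in m.residues) == 2

    def test_hydrogens_excluded(self, write_pdb_text):
        path = write_pdb_text([
            pdb_line(1, "CA", "ALA", 1, (0, 0, 0)),
            pdb_line(2, "H", "ALA", 1, (1, 0, 0), element="H"),
            pdb_line(3, "CA", "GLY", 2, (3.8, 0, 0)),
        ])
        m = parse_structure(path, "A")
        assert sum(len(r.atoms) for r in m.residues) == 2

    def test_altloc_highest_occupancy_kept(self, write_pdb_text):
        path = write_pdb_text([
            pdb_line(1, "N", "ALA", 1, (0, 0, 0), occ=0.4, altloc="A"),
            pdb_line(2, "N", "ALA", 1, (9, 0, 0), occ=0.6, altloc="B"),
            pdb_line(3, "CA", "ALA", 1, (1.5, 0, 0)),
        ])
        m = parse_structure(path, "A")
        names = [a[0] for a in m.residues[0].atoms]
        assert names.count("N") == 1
        kept = m.residues[0].atom_coord("N")
        assert kept[0] == pytest.approx(9.0)  # the 0.6-occupancy copy

    def test_numbering_gap_becomes_placeholder(self, write_pdb_text):
        path = write_pdb_text([
            pdb_line(1, "CA", "ALA", 1, (0, 0, 0)),
            pdb_line(2, "CA", "GLY", 4, (8, 0, 0)),
        ])
        m = parse_structure(path, "A")
        assert len(m) == 4
        assert list(m.observed_mask) == [True, False, False, True]

    def test_missing_chain_lists_alternatives(self, write_pdb_text):
        path = write_pdb_text([pdb_line(1, "CA", "ALA", 1, (0, 0, 0))])
        with pytest.raises(ValueError, match="available chains"):
            parse_structure(path, "Q")

    def test_unparsable_file(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("not a structure\n")
        with pytest.raises(ValueError, match="could not parse"):
            parse_structure(str(bad), "A")

    def test_roundtrip_via_pdb(self, tmp_path, small_dimer):
        _, dimer, _ = small_dimer
        path = tmp_path / "dimer.pdb"
        write_pdb(str(path), dimer.chain_a, dimer.chain_b)
        a = parse_structure(str(path), "A")
        b = parse_structure(str(path), "B")
        assert a.sequence == dimer.chain_a.sequence
        native = inter_contact_map(dimer).values
        reparsed = inter_contact_map(DimerStructure(a, b)).values
        assert np.array_equal(native, reparsed)


# ---------------------------------------------------------------------------
# distances and contacts
# ---------------------------------------------------------------------------

class TestDistances:
    def test_single_atom_pair(self):
        d = min_heavy_atom_distance(_res("GLY", (0, 0, 0)),
                                    _res("GLY", (0, 0, 7.5)))
        assert d == pytest.approx(7.5)

    def test_minimum_over_atom_pairs(self):
        d = min_heavy_atom_distance(_res("GLY", (0, 0, 0)),
                                    _res("GLY", (0, 0, 7.5), (0, 0, 3.0)))
        assert d == pytest.approx(3.0)

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(0)
        a = _res("LYS", *rng.normal(size=(5, 3)))
        b = _res("GLU", *(rng.normal(size=(4, 3)) + 5))
        oracle = min(float(np.linalg.norm(np.array(x[2]) - np.array(y[2])))
                     for x in a.atoms for y in b.atoms)
        assert min_heavy_atom_distance(a, b) == pytest.approx(oracle)

    def test_unobserved_residue_errors(self):
        ghost = Residue("ALA", [], observed=False)
        with pytest.raises(ValueError):
            min_heavy_atom_distance(_res("GLY", (0, 0, 0)), ghost)

    def test_intra_map_single_residue(self):
        m = MonomerStructure("A", [_res("GLY", (0, 0, 0))])
        dm = intra_distance_map(m)
        assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0

    def test_intra_map_brute_force(self):
        rng = np.random.default_rng(1)
        residues = [_res("ALA", *rng.normal(scale=4, size=(3, 3)), author=i + 1)
                    for i in range(10)]
        m = MonomerStructure("A", residues)
        dm = intra_distance_map(m)
        assert np.allclose(dm.values, dm.values.T)
        for i in range(10):
            for j in range(10):
                oracle = cdist(residues[i].coords(), residues[j].coords()).min()
                assert dm.values[i, j] == pytest.approx(oracle)

    def test_unobserved_rows_masked(self):
        residues = [_res("ALA", (0, 0, 0)), Residue("ALA", [], observed=False),
                    _res("GLY", (5, 0, 0))]
        dm = intra_distance_map(MonomerStructure("A", residues))
        assert not dm.mask[1].any() and not dm.mask[:, 1].any()
        assert dm.mask[0, 2]


class TestContacts:
    @pytest.mark.parametrize("gap,expected", [(7.9, 1), (8.0, 1), (8.1, 0)])
    def test_cutoff_boundary_inclusive(self, gap, expected):
        a = MonomerStructure("A", [_res("GLY", (0, 0, 0))])
        b = MonomerStructure("B", [_res("GLY", (0, 0, gap))])
        cm = inter_contact_map(DimerStructure(a, b))
        assert cm.values[0, 0] == expected

    def test_fixture_dimer_contacts_exactly_planted(self, small_dimer):
        spec, dimer, _ = small_dimer
        cm = inter_contact_map(dimer)
        expected = set()
        for (i, j) in spec.interface_pairs:
            expected |= {(i, j), (j, i)}
        got = {(int(a), int(b)) for a, b in zip(*np.nonzero(cm.values))}
        assert got == expected

    def test_monotone_in_cutoff(self, small_dimer):
        _, dimer, _ = small_dimer
        six = inter_contact_map(dimer, cutoff=6.0).values
        eight = inter_contact_map(dimer, cutoff=8.0).values
        assert np.all(eight[six > 0] == 1)


# ---------------------------------------------------------------------------
# SASA and interface area
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_atom_closed_form(self):
        m = MonomerStructure("A", [_res("GLY", (0, 0, 0))])
        closed = 4 * np.pi * (1.76 + 1.4) ** 2
        assert sasa(m, n_points=960)[0] == pytest.approx(closed, rel=0.02)

    def test_far_separated_atoms_additive(self):
        m = MonomerStructure("A", [_res("GLY", (0, 0, 0)),
                                   _res("GLY", (100, 0, 0), author=2)])
        single = 4 * np.pi * (1.76 + 1.4) ** 2
        assert sasa(m).sum() == pytest.approx(2 * single, rel=0.02)

    def test_nearly_coincident_atoms_bury_half_each(self):
        # at vanishing offset each sphere keeps one hemisphere
        m = MonomerStructure("A", [_res("GLY", (0, 0, 0)),
                                   _res("GLY", (0.02, 0, 0), author=2)])
        single = 4 * np.pi * (1.76 + 1.4) ** 2
        assert sasa(m).sum() == pytest.approx(single, rel=0.05)

    def test_bad_point_count(self):
        m = MonomerStructure("A", [_res("GLY", (0, 0, 0))])
        with pytest.raises(ValueError):
            sasa(m, n_points=0)


class TestInterfaceArea:
    def test_far_apart_is_zero(self):
        a = MonomerStructure("A", [_res("GLY", (0, 0, 0))])
        b = MonomerStructure("B", [_res("GLY", (100, 0, 0))])
        assert interface_area(DimerStructure(a, b)) == pytest.approx(0.0, abs=1.0)

    @staticmethod
    def _close_dimer():
        # two parallel strands 4.5 A apart: probe-excluded surface is buried
        a = MonomerStructure("A", [_res("GLY", (0, 0, 4.0 * k), author=k + 1)
                                   for k in range(6)])
        b = MonomerStructure("B", [_res("GLY", (4.5, 0, 4.0 * k), author=k + 1)
                                   for k in range(6)])
        return DimerStructure(a, b)

    def test_symmetric_in_chain_order(self):
        dimer = self._close_dimer()
        ab = interface_area(dimer)
        ba = interface_area(DimerStructure(dimer.chain_b, dimer.chain_a))
        assert ab == pytest.approx(ba, rel=1e-6)
        assert ab > 10.0

    def test_against_independent_sasa_oracle(self):
        dimer = self._close_dimer()
        coords_a, _ = dimer.chain_a.heavy_coords()
        coords_b, _ = dimer.chain_b.heavy_coords()
        radii_a = np.full(len(coords_a), 1.76)
        radii_b = np.full(len(coords_b), 1.76)
        sa = brute_force_sasa(coords_a, radii_a).sum()
        sb = brute_force_sasa(coords_b, radii_b).sum()
        sab = brute_force_sasa(np.vstack([coords_a, coords_b]),
                               np.concatenate([radii_a, radii_b])).sum()
        oracle = (sa + sb - sab) / 2
        got = interface_area(dimer, n_points=4000)
        assert got == pytest.approx(oracle, rel=0.05, abs=2.0)


# ---------------------------------------------------------------------------
# hydrophobicity and filter predicates
# ---------------------------------------------------------------------------

class TestHydrophobicity:
    def test_channels(self, small_dimer):
        _, dimer, _ = small_dimer
        feats = hydrophobicity_features(dimer.chain_a)
        assert feats.shape == (30, 3)
        assert (feats[:, 0] > 0).all()           # exposed dummy residues
        assert np.array_equal(feats[:, 0], feats[:, 1])
        for i, aa in enumerate(dimer.chain_a.sequence):
            assert feats[i, 2] == WIMLEY_WHITE[aa]


def _record(**kw):
    base = dict(resolution=2.0, n_chains=2, chain_length=200,
                chain_identity=1.0, symmetry_label="C2", interface_area=1500.0)
    base.update(kw)
    return StructureRecord(**base)


class TestDatasetFilters:
    def test_all_rules_met(self):
        ok, failed = passes_dataset_filters(_record())
        assert ok and failed == []

    def test_resolution_is_strict(self):
        ok, failed = passes_dataset_filters(_record(resolution=3.0))
        assert not ok and failed == ["resolution"]

    def test_each_violation_reported(self):
        ok, failed = passes_dataset_filters(_record(
            symmetry_label="D2", n_chains=3, resolution=3.5, chain_length=30,
            chain_identity=0.5, interface_area=500.0))
        assert not ok
        assert set(failed) == {"symmetry", "n_chains", "resolution",
                               "chain_length", "chain_identity",
                               "interface_area"}

    def test_survivor_count_on_synthetic_table(self):
        records = []
        expected_pass = 0
        violations = [dict(), dict(resolution=3.2), dict(n_chains=1),
                      dict(chain_length=501), dict(chain_identity=0.98)]
        for k in range(20):
            kw = violations[k % 5]
            records.append(_record(**kw))
            expected_pass += not kw
        survivors = sum(passes_dataset_filters(r)[0] for r in records)
        assert survivors == expected_pass == 4
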