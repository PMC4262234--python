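"""Structure parsing, loop detection, SASA, interfaces, coverage, superposition."""

import io

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dsloop import structure_survey as ss
from dsloop import synthetic_data as syn
from dsloop.loops import DisulphideLoop
from conftest import make_pdb_text
from oracles import brute_force_interface, monte_carlo_sasa, numeric_superposition_rmsd


def _structure_from(spec):
    return ss.parse_structure(io.StringIO(syn.make_loop_structure(spec)), "syn")


def _chain_atoms(structure):
    out = {}
    for chain in structure[0]:
        out[chain.id] = [((chain.id, r.id[1]), a.coord) for r in chain for a in r]
    return out


# ---------------------------------------------------------------------------
# parsing

class TestParseStructure:
    def test_round_trip_against_generator_spec(self):
        spec = syn.StructureSpec(n_chains=2, chain_length=17)
        structure = _structure_from(spec)
        model = structure[0]
        assert [c.id for c in model] == ["A", "B"]
        assert all(len(c) == 17 for c in model)

    def test_ter_end_only_is_an_error(self):
        with pytest.raises(ValueError):
            ss.parse_structure(io.StringIO("TER\nEND\n"), "empty")

    def test_empty_file_is_an_error(self):
        with pytest.raises(ValueError):
            ss.parse_structure(io.StringIO(""), "empty")

    def test_altloc_pair_collapses_to_single_atom(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.500   0.000   0.000  0.40  0.00           C\n"
            "ATOM      3  CA BALA A   1       1.600   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        structure = ss.parse_structure(io.StringIO(text), "alt")
        residue = structure[0]["A"][1]
        ca = [a for a in residue.get_unpacked_list() if a.get_name() == "CA"]
        # parser keeps both conformers but the canonical view is one atom
        assert "CA" in residue
        assert residue["CA"].get_coord().shape == (3,)

    def test_hydrogens_and_waters_removed(self):
        text = make_pdb_text([
            ("A", 1, "ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                             ("H", "H", (0.5, 0.5, 0))]),
        ]) .replace("END", "HETATM    9  O   HOH A 100      9.000   9.000   9.000  1.00  0.00           O\nEND")
        structure = ss.parse_structure(io.StringIO(text), "h")
        atoms = [a.get_name() for a in structure[0].get_atoms()]
        assert atoms == ["N", "CA"]


# ---------------------------------------------------------------------------
# detection

class TestDetectLoops:
    def test_no_cysteines_gives_empty(self):
        structure = _structure_from(syn.StructureSpec(loop_plants=()))
        assert ss.detect_disulphide_loops(structure) == []

    def test_planted_bond_outside_window_ignored(self):
        structure = _structure_from(
            syn.StructureSpec(loop_plants=(("A", 10, 15, 3.2),)))
        assert ss.detect_disulphide_loops(structure) == []

    def test_interleaved_bonds_both_excluded(self):
        structure = _structure_from(syn.StructureSpec(
            chain_length=40,
            loop_plants=(("A", 5, 12, 2.05), ("A", 8, 16, 2.05)),
        ))
        assert ss.detect_disulphide_loops(structure) == []

    def test_cysteine_without_sg_skipped_with_warning(self, caplog):
        text = make_pdb_text([
            ("A", 1, "CYS", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0))]),
            ("A", 4, "CYS", [("CA", "C", (11.4, 0, 0)), ("SG", "S", (12.0, 0, 1))]),
        ])
        structure = ss.parse_structure(io.StringIO(text), "nosg")
        with caplog.at_level("WARNING", logger="dsloop.structure_survey"):
            assert ss.detect_disulphide_loops(structure) == []
        assert any("no SG" in rec.message for rec in caplog.records)

    def test_invariant_to_rigid_transform(self, rng):
        spec = syn.StructureSpec(loop_plants=(("A", 10, 15, 2.05), ("B", 4, 11, 2.2)))
        structure = _structure_from(spec)
        before = ss.detect_disulphide_loops(structure)
        rot = Rotation.random(random_state=42).as_matrix().astype(np.float32)
        shift = np.array([13.0, -4.0, 7.5], dtype=np.float32)
        for atom in structure[0].get_atoms():
            atom.coord = rot @ atom.coord + shift
        after = ss.detect_disulphide_loops(structure)
        assert [(l.chain, l.cys_i, l.cys_j) for l in before] == \
               [(l.chain, l.cys_i, l.cys_j) for l in after]

    def test_invariant_to_chain_record_order(self):
        spec = syn.StructureSpec(loop_plants=(("A", 10, 15, 2.05), ("B", 4, 11, 2.2)))
        text = syn.make_loop_structure(spec)
        blocks = {"A": [], "B": [], "other": []}
        for line in text.splitlines():
            key = line[21] if line.startswith(("ATOM", "TER")) and len(line) > 21 else "other"
            blocks.get(key, blocks["other"]).append(line)
        swapped = "\n".join(blocks["B"] + blocks["A"] + ["END"]) + "\n"
        loops = ss.detect_disulphide_loops(ss.parse_structure(io.StringIO(swapped), "sw"))
        assert [(l.chain, l.cys_i, l.cys_j) for l in loops] == \
               [("A", 10, 15), ("B", 4, 11)]


# ---------------------------------------------------------------------------
# interfaces

class TestInterfaces:
    def test_single_chain_empty_map(self):
        structure = _structure_from(syn.StructureSpec(n_chains=1))
        assert ss.find_interface_residues(structure).by_pair == {}

    @pytest.mark.parametrize("gap, expect_contacts", [(2.9, True), (3.1, False)])
    def test_contact_boundary(self, gap, expect_contacts):
        structure = _structure_from(syn.StructureSpec(inter_chain_gap=gap))
        imap = ss.find_interface_residues(structure, cutoff=3.0)
        assert bool(imap.all_residues()) is expect_contacts
        assert imap.all_residues() == brute_force_interface(
            _chain_atoms(structure), cutoff=3.0)

    def test_map_symmetric_across_pair(self):
        structure = _structure_from(syn.StructureSpec(inter_chain_gap=2.9))
        imap = ss.find_interface_residues(structure, cutoff=3.0)
        assert imap.residues("A") and imap.residues("B")
        for keys in imap.by_pair.values():
            chains = {c for c, _ in keys}
            assert len(chains) == 2


# ---------------------------------------------------------------------------
# SASA

class TestSasa:
    def _free_residue(self):
        text = make_pdb_text([
            ("A", 1, "GLY", [("N", "N", (0.0, 0.0, 0.0)),
                             ("CA", "C", (1.5, 0.0, 0.0)),
                             ("C", "C", (2.4, 1.2, 0.0)),
                             ("O", "O", (3.6, 1.2, 0.5))]),
        ])
        return ss.parse_structure(io.StringIO(text), "gly")

    def test_free_glycine_exposed(self):
        structure = self._free_residue()
        profile = ss.compute_sasa(structure, n_points=960)
        assert profile.area("A", 1) > 2.5

    def test_free_glycine_matches_monte_carlo(self):
        structure = self._free_residue()
        profile = ss.compute_sasa(structure, n_points=960)
        radii = {"N": 1.55, "C": 1.7, "O": 1.52}
        atoms = list(structure[0].get_atoms())
        mc = monte_carlo_sasa([a.coord for a in atoms],
                              [radii[a.element] for a in atoms],
                              probe=1.4, n_samples=40000)
        assert profile.area("A", 1) == pytest.approx(mc.sum(), rel=0.03)

    def test_enclosed_atom_fully_buried(self):
        # central carbon inside an icosahedral shell of carbons at 3.0 A
        phi = (1 + np.sqrt(5)) / 2
        verts = [(0, 1, phi), (0, 1, -phi), (0, -1, phi), (0, -1, -phi),
                 (1, phi, 0), (1, -phi, 0), (-1, phi, 0), (-1, -phi, 0),
                 (phi, 0, 1), (-phi, 0, 1), (phi, 0, -1), (-phi, 0, -1)]
        residues = [("A", 1, "ALA", [("CA", "C", (0.0, 0.0, 0.0))])]
        for k, v in enumerate(verts, start=2):
            xyz = tuple(3.0 * np.asarray(v) / np.linalg.norm(v))
            residues.append(("A", k, "ALA", [("CA", "C", xyz)]))
        structure = ss.parse_structure(io.StringIO(make_pdb_text(residues)), "shell")
        profile = ss.compute_sasa(structure, n_points=960)
        assert profile.area("A", 1) == pytest.approx(0.0, abs=1e-6)

    def test_point_doubling_convergence(self):
        structure = _structure_from(syn.StructureSpec(chain_length=12))
        lo = ss.compute_sasa(structure, n_points=960)
        hi = ss.compute_sasa(structure, n_points=1920)
        for key, area in hi.areas.items():
            assert lo.areas[key] == pytest.approx(area, rel=0.02, abs=0.5)

    def test_monomer_complex_consistency(self):
        structure = _structure_from(syn.StructureSpec(inter_chain_gap=2.9))
        cplx = ss.compute_sasa(structure)
        monos = {c: ss.compute_sasa(structure, chains=[c]) for c in ("A", "B")}
        for key, area in cplx.areas.items():
            assert monos[key[0]].areas[key] - area >= -0.1
        assert sum(cplx.areas.values()) <= sum(
            sum(m.areas.values()) for m in monos.values()) + 1e-6

    def test_unknown_chain_rejected(self):
        structure = _structure_from(syn.StructureSpec())
        with pytest.raises(ValueError):
            ss.compute_sasa(structure, chains=["Q"])


class TestClassifySurface:
    def test_strict_threshold_boundary(self):
        profile = ss.SasaProfile(areas={("A", 1): 2.5, ("A", 2): 2.51}, context="complex")
        assert ss.classify_surface(profile, threshold=2.5) == {("A", 2)}

    def test_all_zero_areas_empty(self):
        profile = ss.SasaProfile(areas={("A", 1): 0.0, ("A", 2): 0.0}, context="complex")
        assert ss.classify_surface(profile) == set()

    def test_synthetic_exposed_loop_classified_surface(self):
        structure = _structure_from(
            syn.StructureSpec(n_chains=1, loop_plants=(("A", 10, 15, 2.05),)))
        profile = ss.compute_sasa(structure)
        surface = ss.classify_surface(profile)
        for resseq in range(11, 15):
            assert ("A", resseq) in surface


# ---------------------------------------------------------------------------
# coverage

def _imap(residues, cutoff=3.0):
    return ss.InterfaceMap(by_pair={("A", "B"): frozenset(residues)}, cutoff=cutoff)


class TestCoverage:
    def test_loop_covering_whole_interface_has_share_one(self):
        lp = DisulphideLoop("s", "A", 3, 8, "AAAA")
        imap = _imap({("A", k) for k in range(3, 9)})
        cov = ss.loop_interface_coverage(lp, imap, mode="residue_count")
        assert cov.loop_share == 1.0
        assert cov.majority_of_interface

    def test_hand_counted_half_coverage(self):
        lp = DisulphideLoop("s", "A", 3, 8, "AAAA")
        iface = {("A", k) for k in (3, 4, 5, 12, 13, 14)}  # 3 of 6 inside loop
        cov = ss.loop_interface_coverage(lp, _imap(iface), mode="residue_count")
        assert cov.loop_share == pytest.approx(0.5)
        assert not cov.majority_of_interface
        assert (cov.n_loop_interface_residues, cov.n_chain_interface_residues) == (3, 6)

    def test_buried_area_mode_weights_by_delta_sasa(self):
        lp = DisulphideLoop("s", "A", 3, 8, "AAAA")
        iface = {("A", k) for k in (3, 4, 12)}
        mono = ss.SasaProfile(areas={("A", k): 10.0 for k in range(1, 15)},
                              context="monomer")
        # loop residues bury 6 each, outside residue buries 3
        cplx_areas = {("A", k): 10.0 for k in range(1, 15)}
        cplx_areas[("A", 3)] = 4.0
        cplx_areas[("A", 4)] = 4.0
        cplx_areas[("A", 12)] = 7.0
        cplx = ss.SasaProfile(areas=cplx_areas, context="complex")
        cov = ss.loop_interface_coverage(lp, _imap(iface), mono, cplx, mode="buried_area")
        assert cov.loop_share == pytest.approx(12.0 / 15.0)

    def test_modes_agree_when_delta_sasa_uniform(self):
        lp = DisulphideLoop("s", "A", 3, 8, "AAAA")
        iface = {("A", k) for k in (3, 4, 5, 12)}
        mono = ss.SasaProfile(areas={("A", k): 8.0 for k in range(1, 15)}, context="monomer")
        cplx = ss.SasaProfile(areas={("A", k): 5.0 for k in range(1, 15)}, context="complex")
        count = ss.loop_interface_coverage(lp, _imap(iface), mode="residue_count")
        area = ss.loop_interface_coverage(lp, _imap(iface), mono, cplx, mode="buried_area")
        assert count.loop_share == pytest.approx(area.loop_share)

    def test_no_interface_flagged(self):
        lp = DisulphideLoop("s", "A", 3, 8, "AAAA")
        cov = ss.loop_interface_coverage(lp, _imap(set()), mode="residue_count")
        assert cov.no_interface and cov.loop_share == 0.0

    def test_missing_chain_in_profiles_rejected(self):
        lp = DisulphideLoop("s", "A", 3, 8, "AAAA")
        other = ss.SasaProfile(areas={("B", 1): 1.0}, context="monomer")
        with pytest.raises(ValueError):
            ss.loop_interface_coverage(lp, _imap({("A", 3)}), other, other,
                                       mode="buried_area")


# ---------------------------------------------------------------------------
# dedup + superposition

class TestDeduplicate:
    def test_smallest_structure_id_wins(self):
        a = DisulphideLoop("2XYZ", "A", 3, 8, "AAAA", accession="P1")
        b = DisulphideLoop("1ABC", "B", 3, 8, "AAAA", accession="P1")
        assert ss.deduplicate_loops([a, b]) == [b]

    def test_unique_loops_unchanged(self):
        loops = [DisulphideLoop("1ABC", "A", 3, 8, "AAAA", accession="P1"),
                 DisulphideLoop("1ABC", "A", 12, 18, "AAAAA", accession="P2")]
        assert set(ss.deduplicate_loops(loops)) == set(loops)

    def test_empty_input(self):
        assert ss.deduplicate_loops([]) == []


class TestSuperposition:
    def test_identity_and_symmetry(self, rng):
        frag = rng.normal(size=(8, 3))
        assert ss.superpose_calpha(frag, frag) == pytest.approx(0.0, abs=1e-9)
        other = frag + rng.normal(scale=0.3, size=frag.shape)
        assert ss.superpose_calpha(frag, other) == pytest.approx(
            ss.superpose_calpha(other, frag), abs=1e-9)

    def test_rigid_transform_invariance(self, rng):
        frag = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("xyz", [90, 0, 0], degrees=True).as_matrix()
        moved = frag @ rot.T + np.array([5.0, -2.0, 11.0])
        assert ss.superpose_calpha(moved, frag) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_matches_numeric_oracle(self, rng):
        ref = rng.normal(scale=3.0, size=(10, 3))
        model = ref.copy()
        model[4] += np.array([1.0, 0.0, 0.0])
        expected = numeric_superposition_rmsd(model, ref)
        assert ss.superpose_calpha(model, ref) == pytest.approx(expected, abs=1e-5)

    def test_mismatched_or_short_inputs_rejected(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            ss.superpose_calpha(a, b)
        with pytest.raises(ValueError):
            ss.superpose_calpha(a[:2], a[:2])


class TestSurveyTable:
    def test_round_trips_planted_counts(self, tmp_path):
        for k in range(2):
            spec = syn.StructureSpec(loop_plants=(("A", 10, 15, 2.05),),
                                     inter_chain_gap=2.9, seed=k)
            syn.make_loop_structure(spec, tmp_path / f"s{k}.pdb")
        table = ss.survey_structures(sorted(tmp_path.glob("*.pdb")))
        assert len(table) == 2
        assert (table["interior"] == "AAAA").all()
        assert ((table["loop_share"] >= 0) & (table["loop_share"] <= 1)).all()
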