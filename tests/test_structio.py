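"""Structure I/O, disulfide detection and SASA."""

import numpy as np
import pytest

from flap import structio
from flap.sasa import compute_sasa, fibonacci_sphere
from flap.structure import Atom, Chain, Residue, Structure
from flap.geometry import rotate_about_axis

from conftest import reference_dssp


def _single_atom_structure(coords, names=None, resname="GLY", element="C",
                           chain="A"):
    residues = []
    for i, xyz in enumerate(coords):
        name = (names or ["CA"] * len(coords))[i]
        residues.append(Residue(name=resname, number=i + 1, atoms=[
            Atom(name, element, np.asarray(xyz, float), 1.7)]))
    return Structure(id="toy", chains=[Chain(id=chain, residues=residues)])


class TestReadWrite:
    def test_roundtrip_preserves_hierarchy(self, helix12, tmp_path):
        path = tmp_path / "helix.pdb"
        structio.write_structure(helix12, path)
        back = structio.read_structure(path)
        assert len(back.chains) == 1
        assert back.n_residues == 12
        assert back.n_atoms == helix12.n_atoms
        assert np.allclose(back.coords(), helix12.coords(), atol=1e-2)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "altloc.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA BALA A   1       9.999   0.000   0.000  0.40  0.00           C\n"
            "ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C\n"
            "END\n")
        s = structio.read_structure(pdb)
        res = s.chains[0].residues[0]
        cas = [a for a in res.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].coord[0] == pytest.approx(1.458, abs=1e-3)

    def test_water_only_file_rejected(self, tmp_path):
        pdb = tmp_path / "water.pdb"
        pdb.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O\n"
            "END\n")
        with pytest.raises(structio.FormatError):
            structio.read_structure(pdb)

    def test_hydrogens_dropped(self, tmp_path):
        pdb = tmp_path / "withh.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  H   ALA A   1       0.500   0.800   0.000  1.00  0.00           H\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        s = structio.read_structure(pdb)
        assert {a.name for a in s.chains[0].residues[0].atoms} == {"N", "CA"}

    def test_multimodel_roundtrip(self, helix12, tmp_path):
        frames = np.stack([helix12.coords(), helix12.coords() + 1.0])
        path = tmp_path / "ens.pdb"
        structio.write_ensemble(helix12, frames, path)
        ref, coords = structio.read_ensemble_coords(path)
        assert coords.shape == (2, helix12.n_atoms, 3)
        assert np.allclose(coords[1] - coords[0], 1.0, atol=1e-2)


class TestDisulfides:
    def test_bonded_pair_found(self, clamped_hairpin):
        pairs = structio.find_disulfides(clamped_hairpin)
        assert pairs == [(("A", 7, ""), ("A", 14, ""))]

    def test_no_pairs_beyond_cutoff(self, hairpin):
        assert structio.find_disulfides(hairpin) == []

    def test_greedy_matches_brute_force_on_three_cysteines(self):
        # SG triangle at mutual 2.0 / 2.1 / 4.0 A: optimal matching has
        # exactly one pair, the closest one
        sg = [np.array([0.0, 0.0, 0.0]), np.array([2.0, 0.0, 0.0]),
              np.array([1.3, 4.0, 0.0])]
        residues = [Residue(name="CYS", number=i + 1, atoms=[
            Atom("CA", "C", p + np.array([0, 0, 2.0]), 1.7),
            Atom("SG", "S", p, 1.8)]) for i, p in enumerate(sg)]
        s = Structure(id="cys3", chains=[Chain(id="A", residues=residues)])
        pairs = structio.find_disulfides(s, sg_cutoff=2.5)

        # oracle: enumerate all matchings, keep those with all pair
        # distances within the cutoff, maximise pair count then total
        # closeness
        def all_matchings(items):
            if len(items) < 2:
                yield []
                return
            first, rest = items[0], items[1:]
            yield from all_matchings(rest)
            for k, other in enumerate(rest):
                for sub in all_matchings(rest[:k] + rest[k + 1:]):
                    yield [(first, other)] + sub

        feasible = []
        for matching in all_matchings([0, 1, 2]):
            if all(np.linalg.norm(sg[i] - sg[j]) <= 2.5 for i, j in matching):
                feasible.append(matching)
        best = max(feasible, key=lambda m: (len(m),
                                            -sum(np.linalg.norm(sg[i] - sg[j])
                                                 for i, j in m)))
        assert len(pairs) == len(best) == 1
        assert pairs[0] == (("A", 1, ""), ("A", 2, ""))

    def test_map_symmetric_and_involutive(self, clamped_hairpin):
        pairs = structio.find_disulfides(clamped_hairpin)
        dmap = structio.disulfide_map(pairs)
        for a, b in dmap.items():
            assert dmap[b] == a
            assert dmap[dmap[a]] == a


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = _single_atom_structure([[0.0, 0.0, 0.0]])
        prof = compute_sasa(s, probe=1.4, n_points=960)
        expected = 4.0 * np.pi * (1.7 + 1.4) ** 2  # 120.76 A^2
        assert prof.total == pytest.approx(expected, rel=1e-12)
        assert prof.total == pytest.approx(120.76, abs=0.01)

    def test_fully_caged_atom_buried(self):
        # central atom enclosed by a dense shell of neighbours
        shell = 2.2 * fibonacci_sphere(40)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        s = _single_atom_structure(coords)
        prof = compute_sasa(s, n_points=400)
        assert prof.values[("A", 1, "")] == pytest.approx(0.0, abs=1e-9)

    def test_contact_pair_buries_area(self):
        iso = compute_sasa(_single_atom_structure([[0.0, 0.0, 0.0]])).total
        pair = compute_sasa(_single_atom_structure([[0.0, 0.0, 0.0],
                                                    [3.4, 0.0, 0.0]]))
        assert pair.total < 2 * iso
        # dense-point oracle at 10x density agrees closely
        dense = compute_sasa(_single_atom_structure([[0.0, 0.0, 0.0],
                                                     [3.4, 0.0, 0.0]]),
                             n_points=9600)
        assert pair.total == pytest.approx(dense.total, rel=0.01)

    def test_point_count_convergence(self, hairpin):
        a = compute_sasa(hairpin, n_points=960).total
        b = compute_sasa(hairpin, n_points=3840).total
        assert abs(a - b) / b <= 0.02

    def test_rigid_motion_invariance(self, hairpin):
        base = compute_sasa(hairpin, n_points=960)
        moved = hairpin.copy()
        xyz = rotate_about_axis(moved.coords(), np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, 1.0, 0.0]), 73.0) + np.array([5.0, -3.0, 11.0])
        moved.set_coords(xyz)
        other = compute_sasa(moved, n_points=960)
        for key, val in base.values.items():
            if val > 1e-6:
                assert abs(other.values[key] - val) / val < 1e-6

    def test_per_residue_sums_to_total(self, clamped_hairpin):
        prof = compute_sasa(clamped_hairpin, n_points=400)
        assert sum(prof.values.values()) == pytest.approx(prof.total, rel=1e-12)
        assert all(v >= 0 for v in prof.values.values())

    def test_duplicate_atoms_rejected(self):
        s = _single_atom_structure([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="duplicate"):
            compute_sasa(s)


class TestSecondaryStructure:
    def test_ideal_helix_interior_matches_reference_dssp(self, helix12, tmp_path):
        mine = "".join(structio.assign_secondary_structure(helix12).states)
        ref = reference_dssp(helix12, tmp_path)
        assert mine == ref
        assert set(mine[2:-2]) == {"H"}

    def test_hairpin_strands_and_turn_match_reference_dssp(self, hairpin, tmp_path):
        mine = "".join(structio.assign_secondary_structure(hairpin).states)
        ref = reference_dssp(hairpin, tmp_path)
        assert mine == ref
        assert set(mine[8:13]) == {"C"}          # the loop stays coil
        assert mine.count("E") >= 8              # both strands assigned

    def test_agreement_rate_across_fixture_set(self, helix12, hairpin,
                                               clamped_hairpin, linear6, tmp_path):
        agree = total = 0
        for s in (helix12, hairpin, clamped_hairpin, linear6):
            mine = "".join(structio.assign_secondary_structure(s).states)
            ref = reference_dssp(s, tmp_path)
            agree += sum(a == b for a, b in zip(mine, ref))
            total += len(mine)
        assert agree / total >= 0.95

    def test_short_fragment_all_coil(self):
        from flap import fixtures

        frag = fixtures.build_structure(
            fixtures.FixtureSpec(kind="helix", length=3, sequence="AAA"))
        states = structio.assign_secondary_structure(frag).states
        assert states == ["C", "C", "C"]
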