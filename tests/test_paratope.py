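"""Interface analysis, the simplified energy score and the alanine-
hexapeptide scan."""

import numpy as np
import pytest

from flap import paratope
from flap.energy import (COULOMB_CONST, EnergyConfig, lj_pair_energy,
                         pairwise_energy)
from flap.geometry import rotate_about_axis
from flap.paratope import (CDRRange, ComplexSpec, alanine_hexapeptide_scan,
                           enumerate_cdr_windows, find_contact_residues,
                           interaction_energy, longest_contact_run)
from flap.structure import Atom, Chain, Residue, Structure


def _two_atom_complex(name_a, res_a, name_b, res_b, distance,
                      element_a="C", element_b="C"):
    ra = Residue(name=res_a, number=1,
                 atoms=[Atom(name_a, element_a, np.zeros(3), 1.7)])
    rb = Residue(name=res_b, number=1,
                 atoms=[Atom(name_b, element_b,
                             np.array([distance, 0.0, 0.0]), 1.7)])
    s = Structure(id="pair", chains=[Chain(id="A", residues=[ra]),
                                     Chain(id="B", residues=[rb])])
    return ComplexSpec(structure=s, receptor_chains=("A",),
                       ligand_chains=("B",))


def _toy_spec(structure, cdr_lo=7, cdr_hi=16):
    return ComplexSpec(structure=structure, receptor_chains=("A",),
                       ligand_chains=("B",),
                       cdrs={"B": [CDRRange("CDR-1", cdr_lo, cdr_hi)]},
                       window_prefix={"B": "TH"})


class TestEnergyScore:
    def test_lj_minimum_closed_form(self):
        # neutral pair at r = 2^(1/6) sigma scores exactly -epsilon
        sigma, eps = 3.40, 0.086  # carbon-carbon
        r = 2 ** (1 / 6) * sigma
        assert lj_pair_energy(r, sigma, eps) == pytest.approx(-eps, rel=1e-12)
        c = _two_atom_complex("CB", "ALA", "CB", "ALA", r)
        assert interaction_energy(c) == pytest.approx(-eps, rel=1e-9)

    def test_salt_bridge_coulomb_hand_value(self):
        # +1 (Lys NZ) vs -0.5 (Asp OD1) at 3 A with eps(r) = 4r:
        # 332 * q1 q2 / (4 * 3 * 3), on top of the N/O LJ term
        c = _two_atom_complex("NZ", "LYS", "OD1", "ASP", 3.0,
                              element_a="N", element_b="O")
        coulomb = COULOMB_CONST * 1.0 * (-0.5) / (4.0 * 3.0 * 3.0)
        sigma = 0.5 * (3.25 + 2.96)
        eps = np.sqrt(0.17 * 0.21)
        expected = coulomb + lj_pair_energy(3.0, sigma, eps)
        assert interaction_energy(c) == pytest.approx(expected, rel=1e-9)
        assert coulomb == pytest.approx(-4.611, abs=1e-3)
        # the canonical unit-charge pair at 3 A: 332/(4*3*3)
        assert COULOMB_CONST * 1.0 * (-1.0) / (4.0 * 3.0 * 3.0) == \
            pytest.approx(-9.222, abs=1e-3)

    def test_noninteracting_limit(self, toy_complex):
        spec = _toy_spec(toy_complex)
        far = toy_complex.copy()
        for chain in far.chains:
            if chain.id == "B":
                for r in chain.residues:
                    for a in r.atoms:
                        a.coord = a.coord + np.array([500.0, 0.0, 0.0])
        far_spec = ComplexSpec(structure=far, receptor_chains=("A",),
                               ligand_chains=("B",))
        assert interaction_energy(far_spec) == pytest.approx(0.0, abs=1e-12)
        assert interaction_energy(spec) < 0  # the designed complex binds

    def test_rigid_motion_invariance(self, toy_complex):
        spec = _toy_spec(toy_complex)
        e0 = interaction_energy(spec)
        moved = toy_complex.copy()
        xyz = rotate_about_axis(moved.coords(), np.array([2.0, 1.0, 0.0]),
                                np.array([1.0, 2.0, 2.0]), 61.0) - 4.2
        moved.set_coords(xyz)
        e1 = interaction_energy(_toy_spec(moved))
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_interface_clash_rejected(self):
        c = _two_atom_complex("CB", "ALA", "CB", "ALA", 0.3)
        with pytest.raises(ValueError, match="clash"):
            interaction_energy(c)

    def test_adjacent_residues_excluded_from_nonbonded(self, helix12):
        # nonbonded sum never counts sequence neighbours, whose spacing
        # is covalent; an all-pair sum over the helix would explode
        e = pairwise_energy(helix12, EnergyConfig())
        assert np.isfinite(e)
        assert abs(e) < 1e3


class TestContacts:
    def test_designed_six_run_recovered_exactly(self, toy_complex):
        spec = _toy_spec(toy_complex)
        contacts = find_contact_residues(spec)
        assert sorted(contacts["B"]) == [9, 10, 11, 12, 13, 14]
        numbers = [r.number for r in toy_complex.chain("B").residues]
        assert longest_contact_run(contacts["B"], numbers) == 6

    def test_designed_four_set_recovered_exactly(self, toy_complex4):
        spec = ComplexSpec(structure=toy_complex4, receptor_chains=("A",),
                           ligand_chains=("B",))
        contacts = find_contact_residues(spec)
        assert sorted(contacts["B"]) == [10, 11, 12, 13]

        # all-pairs distance oracle, independent of the KDTree path
        coords = toy_complex4.coords()
        keys = toy_complex4.atom_residue_keys()
        rec = np.array([c for c, k in zip(coords, keys) if k[0] == "A"])
        expected = set()
        for c, k in zip(coords, keys):
            if k[0] == "B":
                if np.sqrt(((rec - c) ** 2).sum(axis=1)).min() <= 4.5:
                    expected.add(k[1])
        assert contacts["B"] == expected

    def test_close_atom_in_far_atom_out(self):
        near = _two_atom_complex("CB", "ALA", "CB", "ALA", 3.0)
        far = _two_atom_complex("CB", "ALA", "CB", "ALA", 10.0)
        assert find_contact_residues(near)["B"] == {1}
        assert find_contact_residues(far)["B"] == set()

    @pytest.mark.parametrize("contacts,numbers,expected", [
        ({3, 4, 5, 9}, list(range(1, 12)), 3),
        (set(), list(range(1, 12)), 0),
        ({2, 3, 4, 5, 6, 7, 9}, list(range(1, 12)), 6),
    ])
    def test_longest_run(self, contacts, numbers, expected):
        assert longest_contact_run(contacts, numbers) == expected


class TestWindows:
    def test_full_contact_cdr_window_series(self, toy_complex):
        spec = _toy_spec(toy_complex)
        contacts = find_contact_residues(spec)
        wins = enumerate_cdr_windows(spec, contacts, require_contact=False)
        # fully-inside windows of the 10-residue CDR annotation plus
        # overlapping flanking windows; names are ordinal N->C
        assert [w.name for w in wins] == [f"TH{i+1}" for i in range(len(wins))]
        starts = [w.start for w in wins]
        # a window starting at s overlaps the CDR iff s+5 >= 7 and s <= 16
        expected_starts = [s for s in range(1, 24 - 4)
                           if s + 5 >= 7 and s <= 16]
        assert starts == expected_starts

    def test_require_contact_filters_and_renumbers(self, toy_complex):
        spec = _toy_spec(toy_complex)
        contacts = find_contact_residues(spec)
        wins = enumerate_cdr_windows(spec, contacts, require_contact=True)
        assert all(w.contact_count >= 1 for w in wins)
        assert [w.name for w in wins] == [f"TH{i+1}" for i in range(len(wins))]

    def test_no_contacts_empty(self, toy_complex):
        spec = _toy_spec(toy_complex)
        wins = enumerate_cdr_windows(spec, {"B": set()}, require_contact=True)
        assert wins == []

    def test_six_residue_cdr_one_fully_inside_window(self, toy_complex):
        spec = _toy_spec(toy_complex, cdr_lo=9, cdr_hi=14)
        contacts = {"B": {11}}
        wins = enumerate_cdr_windows(spec, contacts, require_contact=True)
        inside = [w for w in wins if w.start >= 9 and w.start + 5 <= 14]
        assert len(inside) == 1
        assert inside[0].start == 9


class TestAlanineScan:
    def test_hot_window_top_ranked(self, fixture_run):
        reports = fixture_run["cdr"].reports
        best = max(reports, key=lambda r: r.loss)
        assert best.window.sequence == "KKKKKK"
        assert best.selected
        assert best.window.contact_count == 6

    def test_threshold_mode_separates_hot_from_cold(self, toy_complex):
        spec = _toy_spec(toy_complex, cdr_lo=2, cdr_hi=22)
        contacts = find_contact_residues(spec)
        wins = enumerate_cdr_windows(spec, contacts, require_contact=False)
        reports = alanine_hexapeptide_scan(spec, wins, mode="threshold",
                                           threshold=0.0)
        hot = max(reports, key=lambda r: r.loss)
        cold_losses = [r.loss for r in reports if r.window.contact_count == 0]
        assert hot.window.sequence == "KKKKKK"
        # selection is stable for any threshold between the cold and
        # hot loss levels
        lo, hi = max(cold_losses), hot.loss
        assert hi > lo + 5.0
        for tau in np.linspace(lo + 0.5, hi - 0.5, 3):
            rep = alanine_hexapeptide_scan(spec, wins, mode="threshold",
                                           threshold=float(tau))
            chosen = {r.window.name for r in rep if r.selected}
            assert hot.window.name in chosen
            assert all(r.window.contact_count > 0 for r in rep if r.selected)

    def test_identity_alanine_window_loss_zero(self, toy_complex):
        # a window that is already AAAAAA has loss exactly 0 and is
        # never selected under a positive threshold
        mutant = toy_complex.copy()
        from flap.graftlab import mutate_window

        mutant = mutate_window(mutant, ("B", 17), "AAAAAA")
        spec = _toy_spec(mutant, cdr_lo=17, cdr_hi=22)
        wins = enumerate_cdr_windows(spec, {"B": {17}}, require_contact=True)
        assert len(wins) >= 1
        target = [w for w in wins if w.start == 17]
        reports = alanine_hexapeptide_scan(spec, target, mode="threshold",
                                           threshold=1e-9)
        assert reports[0].loss == 0.0
        assert not reports[0].selected

    def test_window_disjoint_from_interface_loss_zero(self, toy_complex):
        # residues 19-24 are beyond the pairwise cutoff from every
        # receptor atom: mutating them cannot change the binding score
        spec = _toy_spec(toy_complex, cdr_lo=19, cdr_hi=24)
        wins = enumerate_cdr_windows(spec, {"B": {19}}, require_contact=True)
        target = [w for w in wins if w.start == 19]
        assert target
        reports = alanine_hexapeptide_scan(spec, target, mode="threshold",
                                           threshold=1.0)
        assert abs(reports[0].loss) <= 1e-6

    def test_scan_window_order_invariant(self, toy_complex):
        spec = _toy_spec(toy_complex)
        contacts = find_contact_residues(spec)
        wins = enumerate_cdr_windows(spec, contacts, require_contact=True)
        fwd = alanine_hexapeptide_scan(spec, wins, top_k=2)
        rev = alanine_hexapeptide_scan(spec, list(reversed(wins)), top_k=2)
        assert {r.window.name: round(r.loss, 9) for r in fwd} == \
            {r.window.name: round(r.loss, 9) for r in rev}
        assert {r.window.name for r in fwd if r.selected} == \
            {r.window.name for r in rev if r.selected}

    def test_rank_ties_broken_n_terminal_first(self, toy_complex):
        spec = _toy_spec(toy_complex)
        w = enumerate_cdr_windows(spec, find_contact_residues(spec),
                                  require_contact=True)
        reports = alanine_hexapeptide_scan(spec, w, top_k=len(w))
        assert all(r.selected for r in reports if not r.failed)
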