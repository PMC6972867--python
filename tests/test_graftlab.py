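"""In-silico mutagenesis, homo-hexapeptide profiling and designs."""

import numpy as np
import pytest

from flap import flexengine, graftlab
from flap.geometry import rotate_about_axis
from flap.graftlab import (GAProfile, build_designs, enumerate_homohexapeptides,
                           graft_rmsd, hexapeptide_space_size, mutate_window,
                           profile_site)
from flap.sidechains import CHI1_SET, CHI2_SET, CHI_ATOMS, clash_count
from flap.sitefinder import HexSite, SiteCriteria


SITE = HexSite(scaffold_id="clamped_hairpin", chain_id="A", start=8)


class TestHomoHexapeptides:
    def test_twenty_in_alphabetical_order(self):
        seqs = enumerate_homohexapeptides()
        assert len(seqs) == 20
        assert seqs[0] == "AAAAAA"
        assert seqs == sorted(seqs)
        for probe in ("GGGGGG", "WWWWWW", "IIIIII", "EEEEEE", "RRRRRR"):
            assert probe in seqs

    @pytest.mark.parametrize("alphabet,length,expected", [
        (20, 6, 64_000_000),   # the theoretical hexapeptide space
        (1, 6, 1),
        (4, 3, 64),
    ])
    def test_space_size(self, alphabet, length, expected):
        assert hexapeptide_space_size(alphabet, length) == expected


class TestMutateWindow:
    def test_identity_graft_leaves_coordinates_untouched(self, clamped_hairpin):
        native_seq = "".join(
            r.one_letter for r in clamped_hairpin.chain("A").residues[7:13])
        out = mutate_window(clamped_hairpin, SITE, native_seq)
        assert np.allclose(out.coords(), clamped_hairpin.coords())
        assert graftlab.structure_clash_count(out) == \
            graftlab.structure_clash_count(clamped_hairpin)

    def test_glycine_graft_strips_side_chains(self, clamped_hairpin):
        out = mutate_window(clamped_hairpin, SITE, "GGGGGG")
        for r in out.chain("A").residues[7:13]:
            assert r.name == "GLY"
            assert {a.name for a in r.atoms} == {"N", "CA", "C", "O"}

    def test_backbone_fixed_under_any_graft(self, clamped_hairpin):
        out = mutate_window(clamped_hairpin, SITE, "WWRKDE")
        for before, after in zip(clamped_hairpin.chain("A").residues,
                                 out.chain("A").residues):
            for name in ("N", "CA", "C", "O"):
                assert np.allclose(before.atom(name).coord,
                                   after.atom(name).coord)

    def test_tryptophan_rotamer_matches_exhaustive_search(self, clamped_hairpin):
        # the builder's W placement must equal the best of the full
        # chi1 x chi2 grid, re-scored here independently
        out = mutate_window(clamped_hairpin, SITE, "WGGGGG")
        res = out.chain("A").residue(8)
        env_pts, env_vdw = [], []
        for c, r, a in out.iter_atoms():
            if not (c.id == "A" and r.number == 8):
                env_pts.append(a.coord)
                env_vdw.append(a.vdw)
        env_pts, env_vdw = np.array(env_pts), np.array(env_vdw)
        side = [a for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
        placed = clash_count(np.array([a.coord for a in side]),
                             np.array([a.vdw for a in side]), env_pts, env_vdw)

        from flap.sidechains import _set_chis, _template

        names, elements, tmpl, adj = _template("TRP")
        name_idx = {n: i for i, n in enumerate(names)}
        from flap.geometry import superpose

        triad = np.array([tmpl[name_idx[x]] for x in ("N", "CA", "C")])
        target = np.array([res.atom(x).coord for x in ("N", "CA", "C")])
        base = superpose(triad, target, apply_to=tmpl)
        side_idx = [name_idx[a.name] for a in side]
        best = min(
            clash_count(
                _set_chis(base, name_idx, adj, CHI_ATOMS["TRP"], [c1, c2])[side_idx],
                np.array([a.vdw for a in side]), env_pts, env_vdw)
            for c1 in CHI1_SET for c2 in CHI2_SET)
        assert placed == best

    def test_invalid_sequences_rejected(self, clamped_hairpin):
        with pytest.raises(ValueError):
            mutate_window(clamped_hairpin, SITE, "AAAAA")
        with pytest.raises(ValueError):
            mutate_window(clamped_hairpin, SITE, "AAAAAZ")


class TestProfiling:
    def test_clamped_site_called_ga(self, fixture_run):
        ga = fixture_run["ga"]
        assert [s.name for s in ga.ga_sites] == ["clamped_hairpin-1"]
        prof = ga.profiles[0]
        assert prof.verdict == "GA"
        assert len(prof.entries) == 20
        assert max(prof.entries.values()) < 1.5

    def test_open_loop_site_not_called_ga(self, fixture_run):
        # the open-loop hairpin site fails the CSA stage (mean RMSF >=
        # 1.0 A), so it is never promoted to GA
        scan = fixture_run["scan"]
        assert scan.funnel["hairpin"]["csa"] == 0
        assert scan.funnel["hairpin"]["constrained"] == 1
        assert all(s.scaffold_id != "hairpin" for s in fixture_run["ga"].ga_sites)

    def test_open_loop_profiles_above_clamped_for_every_sequence(
            self, clamped_hairpin, hairpin):
        ref = flexengine.rmsf_from_enm(clamped_hairpin, weighting="contact")
        backend = lambda s: flexengine.rmsf_from_enm(
            s, weighting="contact", calibration=ref.calibration)
        prof_c = profile_site(clamped_hairpin, SITE, backend)
        free_site = HexSite(scaffold_id="hairpin", chain_id="A", start=8)
        prof_f = profile_site(hairpin, free_site, backend, csa_checked=True)
        for aa in graftlab.AA_ALPHABET:
            assert prof_f.entries[aa] > prof_c.entries[aa]

    def test_max_rule_one_failure_flips_verdict(self):
        entries = {aa: 0.9 for aa in graftlab.AA_ALPHABET}
        entries["W"] = 1.8
        prof = GAProfile(site=SITE, entries=entries, threshold=1.5)
        assert prof.verdict == "not-GA"
        prof_ok = GAProfile(site=SITE,
                            entries={aa: 0.9 for aa in graftlab.AA_ALPHABET},
                            threshold=1.5)
        assert prof_ok.verdict == "GA"

    def test_verdict_monotone_in_threshold(self, fixture_run):
        prof = fixture_run["ga"].profiles[0]
        worst = max(prof.entries.values())
        for thr in (worst * 0.5, worst, worst * 2):
            tightened = GAProfile(site=prof.site, entries=prof.entries,
                                  threshold=thr)
            if tightened.verdict == "GA":
                assert thr > worst

    def test_incomplete_profile_has_no_verdict(self):
        prof = GAProfile(site=SITE, entries={"A": 0.9}, threshold=1.5,
                         incomplete=True)
        assert prof.verdict is None


class TestDesigns:
    def test_cross_product_counts(self, clamped_hairpin):
        sites = [HexSite(scaffold_id="clamped_hairpin", chain_id="A", start=8,
                         name=f"Sca{k}-1") for k in range(13)]
        peps = [(f"TH{i}", "KKKKSS") for i in range(5)]
        designs = build_designs(sites, peps, {"clamped_hairpin": clamped_hairpin})
        assert len(designs) == 65          # 5 peptides x 13 GA sites
        assert len({d.name for d in designs}) == 65

    def test_single_design_name_convention(self, clamped_hairpin):
        site = HexSite(scaffold_id="clamped_hairpin", chain_id="A", start=8,
                       name="Sca8-1")
        designs = build_designs([site], [("TH3", "SKKKKS")],
                                {"clamped_hairpin": clamped_hairpin})
        assert [d.name for d in designs] == ["Sca8-1-TH3"]

    def test_duplicate_names_rejected(self, clamped_hairpin):
        site = HexSite(scaffold_id="clamped_hairpin", chain_id="A", start=8,
                       name="Sca8-1")
        with pytest.raises(ValueError, match="duplicate"):
            build_designs([site, site], [("TH3", "SKKKKS")],
                          {"clamped_hairpin": clamped_hairpin})

    def test_empty_inputs_rejected(self, clamped_hairpin):
        with pytest.raises(ValueError):
            build_designs([], [("TH3", "SKKKKS")], {})

    def test_grafted_windows_stay_constrained_on_ga_host(self, fixture_run):
        crit = SiteCriteria()
        for d in fixture_run["designs"].designs:
            assert d.mean_rmsf < crit.rmsf_constrained


def _horn_quaternion_rmsd(P, Q):
    """Independent superposition oracle: Horn's closed-form quaternion
    method, then plain RMSD."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx = P.T @ Q
    N = np.array([
        [Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2], Sxx[1, 2] - Sxx[2, 1],
         Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] - Sxx[1, 0]],
        [Sxx[1, 2] - Sxx[2, 1], Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2],
         Sxx[0, 1] + Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2]],
        [Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] + Sxx[1, 0],
         -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2], Sxx[1, 2] + Sxx[2, 1]],
        [Sxx[0, 1] - Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2],
         Sxx[1, 2] + Sxx[2, 1], -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]],
    ])
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))


class TestGraftRmsd:
    def test_identical_windows_zero(self, clamped_hairpin):
        assert graft_rmsd(clamped_hairpin, SITE, clamped_hairpin, "A", 8) \
            == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_zero(self, clamped_hairpin):
        moved = clamped_hairpin.copy()
        xyz = rotate_about_axis(moved.coords(), np.zeros(3),
                                np.array([0.3, 1.0, -0.2]), 49.0) + 7.0
        moved.set_coords(xyz)
        assert graft_rmsd(moved, SITE, clamped_hairpin, "A", 8) \
            == pytest.approx(0.0, abs=1e-6)

    def test_matches_quaternion_oracle_and_symmetry(self, clamped_hairpin,
                                                    hairpin):
        # same GSSSSG window in two different conformations
        r_ab = graft_rmsd(clamped_hairpin, SITE, hairpin, "A", 8)
        free_site = HexSite(scaffold_id="hairpin", chain_id="A", start=8)
        r_ba = graft_rmsd(hairpin, free_site, clamped_hairpin, "A", 8)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

        def window_coords(s, start):
            chain = s.chain("A")
            out = []
            for k in range(6):
                res = chain.residue(start + k)
                for a in sorted(res.atoms, key=lambda a: a.name):
                    out.append(a.coord)
            return np.array(out)

        P = window_coords(clamped_hairpin, 8)
        Q = window_coords(hairpin, 8)
        assert r_ab == pytest.approx(_horn_quaternion_rmsd(P, Q), abs=1e-9)
        assert r_ab > 0.1

    def test_sequence_mismatch_rejected(self, clamped_hairpin, toy_complex):
        with pytest.raises(ValueError, match="differ"):
            graft_rmsd(clamped_hairpin, SITE, toy_complex, "B", 9)
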