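import numpy as np
import pytest

import hydrophi as hp
from hydrophi.hydration import HBondCriterion, _pair_geometry
from hydrophi.io_core import build_topology, min_image_vectors


def _water(o, h1_dir, h2_dir):
    """Three-site water at *o* with O–H unit directions h1_dir, h2_dir."""
    o = np.asarray(o, float)
    return [o, o + 0.09572 * np.asarray(h1_dir, float),
            o + 0.09572 * np.asarray(h2_dir, float)]


def _water_system(waters, box=(3.0, 3.0, 3.0)):
    coords = [c for w in waters for c in w]
    names = ["O", "H1", "H2"] * len(waters)
    top = build_topology(names, ["HOH"] * len(waters),
                         [range(3 * k, 3 * k + 3) for k in range(len(waters))])
    return top, hp.Frame(np.array(coords), np.array(box))


class TestDetectHBonds:
    def test_ideal_dimer_single_ww_bond(self):
        donor = _water([1.0, 1.0, 1.0], [0, 0, 1], [0.94, 0, -0.33])
        acceptor = _water([1.0, 1.0, 1.28], [1, 0, 0.2], [-1, 0, 0.2])
        top, frame = _water_system([donor, acceptor])
        bonds = hp.detect_hbonds(frame, top)
        assert len(bonds) == 1
        assert bonds[0].category == "ww"
        assert bonds[0].donor_atom == 0 and bonds[0].acceptor_atom == 3

    def test_dimer_beyond_cutoff(self):
        donor = _water([1.0, 1.0, 1.0], [0, 0, 1], [0.94, 0, -0.33])
        acceptor = _water([1.0, 1.0, 1.36], [1, 0, 0.2], [-1, 0, 0.2])
        top, frame = _water_system([donor, acceptor])
        assert hp.detect_hbonds(frame, top) == []

    def test_angle_criterion_rejects_bent_geometry(self):
        # hydrogen 45 degrees off the donor-acceptor axis
        donor = _water([1.0, 1.0, 1.0], [0, 0.707, 0.707], [0.94, 0, -0.33])
        acceptor = _water([1.0, 1.0, 1.28], [1, 0, 0.2], [-1, 0, 0.2])
        top, frame = _water_system([donor, acceptor])
        assert hp.detect_hbonds(frame, top) == []

    def test_no_hydrogens_is_an_error(self):
        top = build_topology(["O"], ["HOH"], [range(0, 1)])
        frame = hp.Frame(np.zeros((1, 3)) + 1.0, np.full(3, 3.0))
        with pytest.raises(ValueError, match="all-atom"):
            hp.detect_hbonds(frame, top)

    def test_matches_all_triples_oracle(self, rng):
        """Detected bonds equal a brute-force loop over every
        (donor, hydrogen, acceptor) triple on a random 50-water box."""
        top, frame = hp.build_water_box(hp.WaterBoxSpec(50, box=1.15,
                                                        seed=13))
        crit = HBondCriterion()
        got = {(b.donor_atom, b.hydrogen_atom, b.acceptor_atom)
               for b in hp.detect_hbonds(frame, top, crit)}
        expected = set()
        mols = top.water_molecules()
        cos_max = np.cos(np.radians(crit.max_hda_angle))
        for mi in mols:
            d = mi.start
            for mj in mols:
                a = mj.start
                if mi == mj:
                    continue
                da = min_image_vectors(frame.coords[a] - frame.coords[d],
                                       frame.box)
                if np.linalg.norm(da) > crit.max_da_distance:
                    continue
                for h in (d + 1, d + 2):
                    dh = min_image_vectors(frame.coords[h] - frame.coords[d],
                                           frame.box)
                    cos = dh @ da / (np.linalg.norm(dh)
                                     * np.linalg.norm(da))
                    if cos >= cos_max:
                        expected.add((d, h, a))
                        break
        assert got == expected
        assert len(got) > 0

    def test_translation_invariance(self):
        top, frame = hp.build_water_box(hp.WaterBoxSpec(50, box=1.15,
                                                        seed=13))
        bonds0 = {(b.donor_atom, b.acceptor_atom)
                  for b in hp.detect_hbonds(frame, top)}
        shifted = hp.Frame(frame.coords + np.array([0.7, -1.3, 2.9]),
                           frame.box)
        bonds1 = {(b.donor_atom, b.acceptor_atom)
                  for b in hp.detect_hbonds(shifted, top)}
        assert bonds0 == bonds1


class TestClassifyWaters:
    def _with_protein(self, water_o_dist):
        prot = build_topology(["CA"], ["ALA"], [range(0, 1)])
        w = _water([1.0 + water_o_dist, 1.0, 1.0], [0, 1, 0], [1, 0, 0])
        names = ["CA", "O", "H1", "H2"]
        top = build_topology(names, ["ALA", "HOH"],
                             [range(0, 1), range(1, 4)])
        coords = np.vstack([[[1.0, 1.0, 1.0]], w])
        return top, hp.Frame(coords, np.full(3, 3.0))

    def test_within_shell_is_interface(self):
        top, frame = self._with_protein(0.35)
        assert hp.classify_waters(frame, top).tolist() == [True]

    def test_beyond_shell_is_bulk(self):
        top, frame = self._with_protein(0.45)
        assert hp.classify_waters(frame, top).tolist() == [False]

    def test_no_protein_all_bulk(self, water_box_216):
        top, frame = water_box_216
        assert not hp.classify_waters(frame, top).any()


class TestHydrationReport:
    @pytest.fixture()
    def hand_fixture(self):
        """One alanine-like residue plus five waters with hand-placed,
        hand-countable hydrogen bonds."""
        prot_coords = np.array([
            [1.00, 1.00, 1.00],    # N (donor, H attached)
            [1.00, 1.10, 1.00],    # H
            [1.12, 0.95, 1.00],    # CA
            [1.25, 1.05, 1.00],    # C
            [1.25, 1.17, 1.00],    # O (acceptor)
        ])
        waters = [
            _water([1.25, 1.45, 1.00], [0, -1, 0], [1, 0, 0]),   # A -> prot O
            _water([1.00, 1.30, 1.00], [0, 1, 0], [-1, 0, 0]),   # B <- prot N
            _water([2.20, 2.20, 2.20], [0, 1, 0], [1, 0, 0]),    # C -> D
            _water([2.20, 2.48, 2.20], [1, 0, 0], [-1, 0, 0]),   # D
            _water([0.30, 2.50, 0.50], [1, 0, 0], [0, 1, 0]),    # E isolated
        ]
        names = (["N", "H", "CA", "C", "O"]
                 + ["O", "H1", "H2"] * 5)
        ranges = [range(0, 5)] + [range(5 + 3 * k, 8 + 3 * k)
                                  for k in range(5)]
        top = build_topology(names, ["ALA"] + ["HOH"] * 5, ranges)
        coords = np.vstack([prot_coords] + [c for w in waters for c in w])
        return top, hp.Frame(coords, np.full(3, 3.0))

    def test_hand_counted_totals(self, hand_fixture):
        top, frame = hand_fixture
        ens = hp.Ensemble(top, [frame])
        rep = hp.hydration_report(ens)
        assert rep.n_interface_waters == 2
        assert rep.n_bulk_waters == 3
        assert rep.hb_ww_interface == pytest.approx(0.0)
        assert rep.hb_wp_interface == pytest.approx(1.0)
        assert rep.hb_total_interface == pytest.approx(1.0)
        assert rep.hb_bulk == pytest.approx(2.0 / 3.0)
        assert rep.hb_pp_total == 0
        assert rep.hb_pw_total == 2

    def test_conservation_identity(self, hand_fixture, solvated_peptide):
        for top, frame in (hand_fixture, solvated_peptide):
            rep = hp.hydration_report(hp.Ensemble(top, [frame]))
            assert rep.hb_total_interface == \
                rep.hb_ww_interface + rep.hb_wp_interface

    def test_frame_duplication_invariance(self, hand_fixture):
        top, frame = hand_fixture
        single = hp.hydration_report(hp.Ensemble(top, [frame]))
        doubled = hp.hydration_report(hp.Ensemble(top, [frame, frame]))
        for key, val in single.to_dict().items():
            assert doubled.to_dict()[key] == pytest.approx(val)


class TestRDF:
    def _single_pair(self, r):
        names = ["CA", "O", "H1", "H2"]
        top = build_topology(names, ["ALA", "HOH"],
                             [range(0, 1), range(1, 4)])
        w = _water([1.0 + r, 1.0, 1.0], [0, 1, 0], [0, 0, 1])
        coords = np.vstack([[[1.0, 1.0, 1.0]], w])
        return hp.Ensemble(top, [hp.Frame(coords, np.full(3, 4.0))])

    def test_single_pair_lands_in_one_bin(self):
        ens = self._single_pair(0.305)
        edges, counts = hp.rdf_unnormalized(ens, bin_width=0.01, r_max=1.5)
        assert counts[30] == 1.0
        assert counts.sum() == 1.0

    def test_bin_sum_equals_pair_count(self, solvated_peptide):
        top, frame = solvated_peptide
        ens = hp.Ensemble(top, [frame])
        _, counts = hp.rdf_unnormalized(ens, bin_width=0.02, r_max=1.2)
        r, _ = _pair_geometry(frame, top)
        assert counts.sum() == np.sum(r < 1.2 + 1e-12)

    def test_matches_double_loop(self, solvated_peptide):
        top, frame = solvated_peptide
        ens = hp.Ensemble(top, [frame])
        edges, counts = hp.rdf_unnormalized(ens, bin_width=0.05, r_max=1.0)
        oxy = top.water_oxygens
        prot = top.protein_atoms
        brute = np.zeros(len(edges) - 1)
        for o in oxy:
            for p in prot:
                d = np.linalg.norm(min_image_vectors(
                    frame.coords[p] - frame.coords[o], frame.box))
                b = int(d / 0.05)
                if b < len(brute):
                    brute[b] += 1
        assert np.array_equal(counts, brute)


class TestAnisotropy:
    def test_aligned_normals_give_two(self):
        # water normal along +z, protein atom straight above the oxygen
        w = _water([2.0, 2.0, 1.0], [1, 0, 0], [0, 1, 0])  # normal = z
        names = ["CA", "O", "H1", "H2"]
        top = build_topology(names, ["ALA", "HOH"],
                             [range(0, 1), range(1, 4)])
        coords = np.vstack([[[2.0, 2.0, 1.30]], w])
        ens = hp.Ensemble(top, [hp.Frame(coords, np.full(3, 4.0))])
        prof = hp.anisotropy_profile(ens, bin_width=0.01, r_max=1.0)
        assert prof.rdf[30] == 1.0
        assert prof.A[30] == pytest.approx(2.0)

    def test_isotropic_orientations_average_to_zero(self):
        """With uniformly random orientations the per-bin orientation mean
        stays within 3 standard errors of zero."""
        top, frame = hp.build_water_box(hp.WaterBoxSpec(2000, box=4.0,
                                                        seed=21))
        # append one protein atom at the box centre
        names = [a.name for a in top.atoms] + ["CA"]
        resn = [n for n, _ in top.residues] + ["ALA"]
        ranges = [r for _, r in top.residues] + [
            range(top.n_atoms, top.n_atoms + 1)]
        top2 = build_topology(names, resn, ranges)
        coords = np.vstack([frame.coords, [[2.0, 2.0, 2.0]]])
        ens = hp.Ensemble(top2, [hp.Frame(coords, frame.box)])
        prof = hp.anisotropy_profile(ens, bin_width=0.25, r_max=2.0)
        with np.errstate(invalid="ignore"):
            mean_s = np.where(prof.rdf > 0, prof.A / prof.rdf, 0.0)
        for b in range(len(mean_s)):
            if prof.rdf[b] >= 50:
                se = np.sqrt(2.0 / prof.rdf[b])   # var(3cos²-1) = 4/5 < 2
                assert abs(mean_s[b]) <= 3 * se

    def test_matches_explicit_pair_loop(self, solvated_peptide):
        top, frame = solvated_peptide
        ens = hp.Ensemble(top, [frame])
        prof = hp.anisotropy_profile(ens, bin_width=0.05, r_max=1.0)
        nb = len(prof.bin_edges) - 1
        s_sum = np.zeros(nb)
        count = np.zeros(nb)
        for rng_ in top.water_molecules():
            o = rng_.start
            h1, h2 = o + 1, o + 2
            v1 = min_image_vectors(frame.coords[h1] - frame.coords[o],
                                   frame.box)
            v2 = min_image_vectors(frame.coords[h2] - frame.coords[o],
                                   frame.box)
            n = np.cross(v1, v2)
            n /= np.linalg.norm(n)
            for p in top.protein_atoms:
                d = min_image_vectors(frame.coords[p] - frame.coords[o],
                                      frame.box)
                r = np.linalg.norm(d)
                if r >= 1.0:
                    continue
                b = int(r / 0.05)
                cos = (d @ n) / r
                s_sum[b] += 3 * cos * cos - 1
                count[b] += 1
        with np.errstate(invalid="ignore"):
            a_brute = np.where(count > 0, s_sum / count, 0.0) * count
        assert np.allclose(prof.A, a_brute, atol=1e-12)
        assert np.array_equal(prof.rdf, count)

    def test_pair_orientation_bounds(self, solvated_peptide):
        top, frame = solvated_peptide
        _, s = _pair_geometry(frame, top)
        assert np.all(s >= -1.0 - 1e-12)
        assert np.all(s <= 2.0 + 1e-12)

    def test_degenerate_water_rejected(self):
        w = _water([1.0, 1.0, 1.0], [0, 0, 1], [0, 0, -1])  # collinear
        names = ["CA", "O", "H1", "H2"]
        top = build_topology(names, ["ALA", "HOH"],
                             [range(0, 1), range(1, 4)])
        coords = np.vstack([[[2.0, 2.0, 2.0]], w])
        ens = hp.Ensemble(top, [hp.Frame(coords, np.full(3, 4.0))])
        with pytest.raises(ValueError, match="collinear"):
            hp.anisotropy_profile(ens)


class TestTotalAnisotropy:
    def test_zero_profile(self):
        prof = hp.AnisotropyProfile(np.arange(0, 1.01, 0.01),
                                    np.zeros(100), np.zeros(100))
        assert hp.total_anisotropy(prof) == 0.0

    def test_single_bin(self):
        a = np.zeros(100)
        a[5] = 2.0
        prof = hp.AnisotropyProfile(np.arange(0, 1.005, 0.01), a,
                                    np.ones(100))
        assert hp.total_anisotropy(prof) == pytest.approx(0.02)

    def test_matches_rectangle_rule(self, rng):
        a = rng.normal(size=80)
        edges = np.arange(0, 0.805, 0.01)
        prof = hp.AnisotropyProfile(edges, a, np.abs(a))
        brute = sum(abs(v) * 0.01 for v in a)
        assert hp.total_anisotropy(prof) == pytest.approx(brute, abs=1e-12)
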