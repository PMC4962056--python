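import numpy as np
import pytest
from scipy import stats

import hydrophi as hp
from hydrophi.contacts_phi import _formed
from hydrophi.io_core import build_topology


def _two_residue_pair(d, sep=3):
    """Minimal chain where residues 0 and *sep* carry one CB each at
    distance *d*; intervening residues are glycine-like (no side chain)."""
    names, resn, ranges, coords = [], [], [], []
    idx = 0
    for r in range(sep + 1):
        has_cb = r in (0, sep)
        n = 3 if has_cb else 2
        resn.append("ALA" if has_cb else "GLY")
        ranges.append(range(idx, idx + n))
        base = np.array([1.0 + 0.4 * r, 1.0, 1.0])
        names.extend(["N", "CA"] + (["CB"] if has_cb else []))
        coords.append(base + [0, 0.1, 0])
        coords.append(base)
        if has_cb:
            cb = (np.array([1.0, 1.0 + d, 1.0]) if r == sep
                  else np.array([1.0, 1.0, 1.0]))
            coords.append(cb)
        idx += n
    top = build_topology(names, resn, ranges)
    return top, hp.Frame(np.array(coords), np.full(3, 10.0))


class TestNativeContacts:
    def test_pair_within_cutoff_included(self):
        top, frame = _two_residue_pair(0.60)
        cmap = hp.native_contacts((top, frame))
        assert cmap.n_pairs == 1
        assert tuple(cmap.residue_pairs[0]) == (0, 3)

    def test_pair_beyond_cutoff_excluded(self):
        top, frame = _two_residue_pair(0.70)
        assert hp.native_contacts((top, frame)).n_pairs == 0

    def test_sequence_neighbours_excluded(self):
        top, frame = _two_residue_pair(0.3, sep=1)
        assert hp.native_contacts((top, frame)).n_pairs == 0

    def test_extended_chain_has_no_contacts(self):
        top, frame = hp.build_peptide(hp.PeptideSpec("KLVFFAED", "beta"))
        assert hp.native_contacts((top, frame)).n_pairs == 0

    def test_glycine_contributes_no_atoms(self, hairpin_contacts, hairpin):
        top, _ = hairpin
        gly = {a.residue_index for a in top.atoms
               if a.residue_name == "GLY"}
        assert not gly & set(hairpin_contacts.residue_pairs.ravel().tolist())


class TestFractionNativeContacts:
    def test_native_frame_gives_one(self, hairpin, hairpin_contacts):
        _, frame = hairpin
        assert hp.fraction_native_contacts(frame, hairpin_contacts) == 1.0

    def test_extended_gives_zero(self, hairpin_contacts):
        top, frame = hp.build_peptide(
            hp.PeptideSpec("KLVFFAEDVGSNKG", "beta"))
        assert hp.fraction_native_contacts(frame, hairpin_contacts) == 0.0

    def test_half_broken_gives_half(self, hairpin, hairpin_contacts):
        """A frame with exactly half the native pairs pushed apart has
        Q = 1/2 by hand count."""
        top, native = hairpin
        cmap = hairpin_contacts
        half = cmap.n_pairs // 2
        p = np.array([0.0] * half + [1.0] * (cmap.n_pairs - half))
        ens = hp.generate_ensemble(
            hp.SynthEnsembleSpec(hairpin, p, 1, seed=5))
        formed = _formed(ens.frames[0], cmap, None)
        assert formed.sum() == cmap.n_pairs - half
        q = hp.fraction_native_contacts(ens.frames[0], cmap)
        assert q == pytest.approx((cmap.n_pairs - half) / cmap.n_pairs)

    def test_empty_map_is_error(self, hairpin):
        top, frame = hairpin
        empty = hp.NativeContactMap(np.empty((0, 2), int),
                                    np.empty((0, 2), int), 0.65, 2,
                                    top.n_residues)
        with pytest.raises(ValueError):
            hp.fraction_native_contacts(frame, empty)


class TestContactFormationMap:
    def test_native_only_all_ones(self, hairpin, hairpin_contacts):
        top, frame = hairpin
        m = hp.contact_formation_map(hp.Ensemble(top, [frame]),
                                     hairpin_contacts)
        for i, j in hairpin_contacts.residue_pairs:
            assert m[i, j] == 1.0

    def test_symmetry_and_range(self, hairpin, hairpin_contacts):
        ens = hp.generate_ensemble(hp.SynthEnsembleSpec(hairpin, 0.4, 30,
                                                        seed=6))
        m = hp.contact_formation_map(ens, hairpin_contacts)
        assert np.allclose(m, m.T, equal_nan=True)
        vals = m[~np.isnan(m)]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_binomial_recovery(self, hairpin, hairpin_contacts):
        n_frames = 300
        ens = hp.generate_ensemble(hp.SynthEnsembleSpec(hairpin, 0.3,
                                                        n_frames, seed=7))
        m = hp.contact_formation_map(ens, hairpin_contacts)
        se = np.sqrt(0.3 * 0.7 / n_frames)
        for i, j in hairpin_contacts.residue_pairs:
            assert abs(m[i, j] - 0.3) <= 3 * se

    def test_marginal_reproduces_phi(self, hairpin, hairpin_contacts):
        """Summing formed/total counts of the residue-pair map per residue
        gives exactly phi_from_ensemble."""
        cmap = hairpin_contacts
        ens = hp.generate_ensemble(hp.SynthEnsembleSpec(hairpin, 0.5, 20,
                                                        seed=8))
        phi = hp.phi_from_ensemble(ens, cmap)
        formed_mean = np.mean([_formed(f, cmap, None) for f in ens.frames],
                              axis=0)
        for r in range(cmap.n_residues):
            ks = [k for k, (i, j) in enumerate(cmap.residue_pairs)
                  if r in (i, j)]
            if not ks:
                assert not phi.valid[r]
                continue
            assert phi.phi[r] == pytest.approx(
                np.sum(formed_mean[ks]) / len(ks), abs=1e-12)


class TestPhiFromEnsemble:
    def test_native_only_gives_one(self, hairpin, hairpin_contacts):
        top, frame = hairpin
        phi = hp.phi_from_ensemble(hp.Ensemble(top, [frame]),
                                   hairpin_contacts)
        assert np.all(phi.phi[phi.valid] == 1.0)

    def test_extended_only_gives_zero(self, hairpin, hairpin_contacts):
        top, _ = hairpin
        _, ext = hp.build_peptide(hp.PeptideSpec("KLVFFAEDVGSNKG", "beta"))
        phi = hp.phi_from_ensemble(hp.Ensemble(top, [ext]),
                                   hairpin_contacts)
        assert np.all(phi.phi[phi.valid] == 0.0)

    def test_even_mixture_gives_half(self, hairpin, hairpin_contacts):
        top, native = hairpin
        _, ext = hp.build_peptide(hp.PeptideSpec("KLVFFAEDVGSNKG", "beta"))
        phi = hp.phi_from_ensemble(hp.Ensemble(top, [native, ext]),
                                   hairpin_contacts)
        assert np.all(phi.phi[phi.valid] == pytest.approx(0.5))

    def test_contactless_residue_invalid(self, hairpin, hairpin_contacts):
        top, frame = hairpin
        phi = hp.phi_from_ensemble(hp.Ensemble(top, [frame]),
                                   hairpin_contacts)
        in_contact = set(hairpin_contacts.residue_pairs.ravel().tolist())
        for r in range(top.n_residues):
            assert phi.valid[r] == (r in in_contact)

    def test_recovers_generator_probabilities(self, hairpin,
                                              hairpin_contacts):
        """Parameter recovery: Φ per residue matches the generating
        per-contact probability within binomial error."""
        n_frames = 300
        ens = hp.generate_ensemble(hp.SynthEnsembleSpec(hairpin, 0.6,
                                                        n_frames, seed=9))
        phi = hp.phi_from_ensemble(ens, hairpin_contacts)
        counts = hairpin_contacts.pairs_per_residue()
        for r in np.flatnonzero(phi.valid):
            se = np.sqrt(0.6 * 0.4 / (n_frames * counts[r]))
            assert abs(phi.phi[r] - 0.6) <= 3.5 * se


class TestPhiRestraintEnergy:
    def _phiset(self, vals, valid=None):
        vals = np.asarray(vals, float)
        if valid is None:
            valid = np.isfinite(vals)
        return hp.PhiSet(vals, valid)

    def test_zero_at_agreement(self):
        a = self._phiset([0.2, 0.8, 0.5])
        assert hp.phi_restraint_energy(a, a, k=10.0) == 0.0

    def test_single_residue_closed_form(self):
        sim = self._phiset([0.5])
        exp = self._phiset([0.0])
        assert hp.phi_restraint_energy(sim, exp, k=1.0) == pytest.approx(0.25)

    def test_out_of_range_experimental_excluded(self):
        sim = self._phiset([0.5, 0.3])
        exp1 = self._phiset([0.0, 1.7], valid=np.array([True, True]))
        exp2 = self._phiset([0.0, -0.4], valid=np.array([True, True]))
        e1 = hp.phi_restraint_energy(sim, exp1, k=1.0)
        e2 = hp.phi_restraint_energy(sim, exp2, k=1.0)
        assert e1 == e2 == pytest.approx(0.25)

    def test_quadratic_scaling(self):
        sim = self._phiset([0.6, 0.9])
        exp = self._phiset([0.4, 0.5])
        e1 = hp.phi_restraint_energy(sim, exp, k=2.0)
        sim2 = self._phiset([0.8, 1.3])   # deviations doubled
        e2 = hp.phi_restraint_energy(sim2, exp, k=2.0)
        assert e2 == pytest.approx(4 * e1)

    def test_no_common_valid_is_error(self):
        sim = self._phiset([np.nan], valid=np.array([False]))
        exp = self._phiset([0.5])
        with pytest.raises(ValueError):
            hp.phi_restraint_energy(sim, exp, k=1.0)


class TestPhiFromDDG:
    def test_limits(self):
        t = hp.DDGTable(np.array([1, 2]), np.array([5.0, 5.0]),
                        np.array([0.0, 5.0]))
        phi = hp.phi_from_ddg(t)
        assert phi.phi[0] == pytest.approx(1.0)   # TS destabilised like N
        assert phi.phi[1] == pytest.approx(0.0)   # TS like D

    def test_small_ddg_flagged_invalid(self):
        t = hp.DDGTable(np.array([1]), np.array([1.25]), np.array([0.5]))
        phi = hp.phi_from_ddg(t, min_ddg=2.5)
        assert not phi.valid[0]

    def test_multi_mutant_average_with_warning(self):
        t = hp.DDGTable(np.array([4, 4]), np.array([5.0, 10.0]),
                        np.array([0.0, 5.0]))
        with pytest.warns(UserWarning):
            phi = hp.phi_from_ddg(t)
        assert phi.phi[0] == pytest.approx(0.75)


class TestBronsted:
    def test_collinear_gives_unit_correlation(self):
        t = hp.DDGTable(np.arange(1, 6), np.arange(5, 10, dtype=float),
                        2.0 * np.arange(5, 10) + 1.0)
        res = hp.bronsted(t)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [0.0, 0.48, 0.77, 1.0])
    def test_recovers_generator_target(self, target):
        t = hp.generate_ddg_table(hp.DDGSpec(30, target, seed=1))
        res = hp.bronsted(t)
        # independent oracle for the same quantity
        oracle = stats.pearsonr(t.ddg_dn, t.ddg_tsn).statistic
        assert res.pearson_r == pytest.approx(target, abs=1e-10)
        assert res.pearson_r == pytest.approx(oracle, abs=1e-13)

    def test_zero_variance_is_error(self):
        t = hp.DDGTable(np.arange(1, 5), np.full(4, 5.0),
                        np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError):
            hp.bronsted(t)

    def test_too_few_mutants(self):
        t = hp.DDGTable(np.array([1, 2]), np.array([3.0, 4.0]),
                        np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            hp.bronsted(t)
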