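"""Restraint construction rules, calibration and energies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrfold import restraints as R
from nmrfold.io import DihedralPrediction


class TestNoeCalibration:
    def test_weakest_peak_maps_to_dmax(self):
        assert R.calibrate_noe_distance(1.0, 1.0, 4.25) == pytest.approx(4.25)

    def test_sixty_four_fold_intensity_halves_distance(self):
        assert R.calibrate_noe_distance(64.0, 1.0, 4.25) == pytest.approx(2.125)

    def test_identity_at_other_dmax(self):
        assert R.calibrate_noe_distance(5.0, 5.0, 5.0) == pytest.approx(5.0)

    def test_below_imin_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            d = R.calibrate_noe_distance(0.5, 1.0, 4.25)
        assert d == pytest.approx(4.25)

    @given(st.floats(1.0, 1e6), st.floats(0.1, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_nonincreasing_and_bounded(self, ratio, i_min):
        d1 = R.calibrate_noe_distance(i_min * ratio, i_min)
        d2 = R.calibrate_noe_distance(i_min * ratio * 2.0, i_min)
        assert d2 <= d1 <= R.D_MAX_DEFAULT + 1e-9

    def test_restraint_well_is_33_percent(self):
        r = R.make_noe_restraint([((1, "HA"), (5, "HA"))], 1.0, 1.0, 4.25)
        assert r.lower == pytest.approx(4.25 * 0.67)
        assert r.upper == pytest.approx(4.25 * 1.33)

    def test_pseudo_atom_pads_upper_bound(self):
        r = R.make_noe_restraint([((1, "QB"), (5, "HA"))], 1.0, 1.0, 4.25,
                                 pseudo_correction=1.0)
        assert r.upper == pytest.approx(4.25 * 1.33 + 1.0)


class TestSquareWell:
    def _restraint(self):
        return R.DistanceRestraint(member_pairs=(((1, "HA"), (2, "HA")),),
                                   target=3.0, lower=2.0, upper=4.0)

    def test_zero_inside_well_and_at_bounds(self):
        r = self._restraint()
        assert R.square_well_energy(3.0, r) == 0.0
        assert R.square_well_energy(4.0, r) == 0.0
        assert R.square_well_energy(2.0, r) == 0.0

    def test_quadratic_outside(self):
        r = self._restraint()
        assert R.square_well_energy(5.0, r) == pytest.approx(1.0)
        assert R.square_well_energy(1.0, r, k_force=2.0) == pytest.approx(2.0)

    def test_ambiguous_effective_distance(self):
        # two members at 3 A: r_eff = 3 * 2^(-1/6)
        assert R.effective_distance([3.0, 3.0]) == pytest.approx(3.0 * 2 ** (-1 / 6))

    @given(st.lists(st.floats(1.0, 10.0), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_reff_below_min_member_and_equal_for_single(self, ds):
        reff = R.effective_distance(ds)
        assert reff <= min(ds) + 1e-9
        assert R.effective_distance([ds[0]]) == pytest.approx(ds[0])

    def test_energy_continuous_at_boundary(self):
        r = self._restraint()
        eps = 1e-6
        assert R.square_well_energy(4.0 + eps, r) < 1e-10
        assert R.square_well_energy(2.0 - eps, r) < 1e-10


class TestHbondRestraints:
    RES = list(range(1, 11))

    def test_qualifying_residue_gets_two_ambiguous_restraints(self):
        out = R.make_hbond_restraints({5: 0.8}, self.RES)
        assert len(out) == 2
        for r in out:
            assert r.target == pytest.approx(1.7)
            assert (r.lower, r.upper) == (pytest.approx(1.4), pytest.approx(2.0))
            assert r.ambiguous

    def test_below_threshold_gives_none(self):
        assert R.make_hbond_restraints({5: 0.70}, self.RES) == []

    def test_two_adjacent_qualifying_residues_give_four(self):
        out = R.make_hbond_restraints({5: 0.8, 6: 0.9}, self.RES)
        assert len(out) == 4

    def test_member_patterns(self):
        out = R.make_hbond_restraints({5: 0.8}, self.RES)
        first, second = out
        # pattern 1: HN(5)/C'(x) or HN(x)/C'(4)
        assert any(p == ((5, "HN"), (x, "O")) for p in first.member_pairs
                   for x in self.RES)
        assert any(p[1] == (4, "O") for p in first.member_pairs)
        # pattern 2: HN(6)/C'(x) or HN(x)/C'(5)
        assert any(p[0] == (6, "HN") for p in second.member_pairs)
        assert any(p[1] == (5, "O") for p in second.member_pairs)

    def test_terminus_alternative_omitted(self):
        out = R.make_hbond_restraints({1: 0.9}, self.RES)
        # residue 0 does not exist: pattern 1 keeps only the HN(1)/C'(x) half
        assert all(pair[1] != (0, "O") for pair in out[0].member_pairs)

    def test_separation_floor_excludes_trivia(self):
        out = R.make_hbond_restraints({5: 0.8}, self.RES, separation_floor=2)
        # pattern 1 anchors: HN(5) donating, and C'(4) accepting
        for hn, co in out[0].member_pairs:
            if hn == (5, "HN"):
                assert abs(co[0] - 5) >= 2
            else:
                assert co == (4, "O") and abs(hn[0] - 4) >= 2

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            R.make_hbond_restraints({5: 1.2}, self.RES)


class TestDihedralRestraints:
    def test_strong_prediction_kept_with_doubled_spread(self):
        preds = [DihedralPrediction(7, "phi", -120.0, 10.0, "Strong")]
        out = R.make_dihedral_restraints(preds)
        assert len(out) == 1
        assert out[0].target == -120.0 and out[0].halfwidth == 20.0

    def test_dyn_prediction_dropped(self):
        preds = [DihedralPrediction(7, "phi", -120.0, 10.0, "Dyn")]
        assert R.make_dihedral_restraints(preds) == []

    def test_zero_spread_uses_minimum_halfwidth(self):
        preds = [DihedralPrediction(7, "psi", 130.0, 0.0, "Strong")]
        with pytest.warns(UserWarning, match="minimum halfwidth"):
            out = R.make_dihedral_restraints(preds, min_halfwidth=5.0)
        assert out[0].halfwidth == 5.0


class TestMetalRestraints:
    SITE = [(44, "SD"), (59, "SG"), (61, "SD")]

    def test_explicit_mode_geometry(self):
        rs = R.make_metal_restraints(self.SITE, mode="explicit")
        assert len(rs.distances) == 3 and len(rs.angles) == 6
        assert all(r.target == 2.3 and r.kind == "metal_bond" for r in rs.distances)
        bond_angles = [a for a in rs.angles if a.kind == "metal_bond_angle"]
        ligand_angles = [a for a in rs.angles if a.kind == "metal_ligand_angle"]
        assert len(bond_angles) == 3 and all(a.target == 120.0 for a in bond_angles)
        assert len(ligand_angles) == 3 and all(a.target == 109.5 for a in ligand_angles)
        assert all(R.METAL in r.member_pairs[0] for r in rs.distances)

    def test_implicit_mode_three_ss_distances(self):
        rs = R.make_metal_restraints(self.SITE, mode="implicit")
        assert len(rs.distances) == 3 and not rs.angles
        assert all(r.target == 4.0 and r.kind == "metal_implicit"
                   for r in rs.distances)

    def test_trigonal_closed_form_consistency(self):
        # law of cosines: S-S = sqrt(2 b^2 (1 - cos 120)) = 2 b sin 60
        b, theta = 2.3, math.radians(120.0)
        ss = math.sqrt(2 * b * b * (1 - math.cos(theta)))
        assert ss == pytest.approx(2 * 2.3 * math.sin(math.radians(60.0)))
        assert ss == pytest.approx(3.98, abs=5e-3)
        assert abs(ss - R.METAL_IMPLICIT_SS) < 0.1

    def test_non_trigonal_site_rejected(self):
        with pytest.raises(ValueError, match="trigonal"):
            R.make_metal_restraints(self.SITE[:2])


class TestNcsCoupling:
    def test_default_segments_cover_18_residues(self):
        ncs = R.make_ncs_coupling([(37, 41), (49, 55), (63, 68)],
                                  free_segments=[(42, 48), (56, 62)])
        assert len(ncs.residues) == 5 + 7 + 6

    def test_free_segments_have_seven_residues(self):
        ncs = R.make_ncs_coupling([(37, 41)], free_segments=[(42, 48)])
        a, b = ncs.free_segments[0]
        assert b - a + 1 == 7

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            R.make_ncs_coupling([(37, 45)], free_segments=[(42, 48)])

    def test_empty_superimpose_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            R.make_ncs_coupling([])


class TestRoundTrip:
    def _set(self):
        rs = R.RestraintSet()
        rs.distances.append(R.DistanceRestraint(
            member_pairs=(((1, "HA"), (5, "HN")), ((2, "QB"), (5, "HN"))),
            target=3.5, lower=2.345, upper=4.655, kind="noe", weight=1.5))
        rs.extend(R.make_metal_restraints(
            [(4, "SG"), (6, "SG"), (8, "SG")], mode="explicit"))
        rs.dihedrals.append(R.DihedralRestraint(3, "phi", -120.0, 20.0))
        return rs

    def test_tsv_round_trip_exact(self, tmp_path):
        rs = self._set()
        path = tmp_path / "restraints.tsv"
        R.restraints_to_tsv(rs, path)
        back = R.restraints_from_tsv(path)
        assert len(back.distances) == len(rs.distances)
        assert back.distances[0].member_pairs == rs.distances[0].member_pairs
        assert back.distances[0].lower == rs.distances[0].lower
        assert back.dihedrals[0].target == -120.0
        assert len(back.angles) == 6

    def test_cyana_style_export(self):
        rs = self._set()
        seq = {i: "ALA" for i in range(1, 10)}
        upl = R.restraints_to_upl(rs, seq)
        assert "HA" in upl and "4.66" in upl
        aco = R.restraints_to_aco(rs, seq)
        assert "PHI" in aco and "-140.0" in aco and "-100.0" in aco
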