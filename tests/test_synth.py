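"""Ground-truth generator: construction quality, determinism, statistics."""

import math

import numpy as np
import pytest

from nmrfold import chemshift, csp, engine, synth


class TestToyFold:
    def test_size_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            synth.make_toy_fold(n_strand_residues=2)
        with pytest.raises(ValueError, match="outside"):
            synth.make_toy_fold(n_strand_residues=12)

    def test_site_sulfurs_near_trigonal(self, truth):
        top = truth.topology
        sg = [truth.coords[top.atom_index(r, "SG")] for r in truth.site_residues]
        ideal = 2 * 2.3 * math.sin(math.radians(60.0))
        for i in range(3):
            for j in range(i + 1, 3):
                d = float(np.linalg.norm(sg[i] - sg[j]))
                assert 3.8 <= d <= 4.2
                assert abs(d - ideal) < 0.25

    def test_sheet_hydrogen_bond_ladder(self, truth):
        """Every hydrogen-bonded registry pair donates in both directions."""
        top = truth.topology
        bonded = truth.params["bonded_pairs"]
        assert len(bonded) >= 4
        for a, b in bonded:
            d1 = np.linalg.norm(truth.coords[top.atom_index(a, "HN")]
                                - truth.coords[top.atom_index(b, "O")])
            d2 = np.linalg.norm(truth.coords[top.atom_index(b, "HN")]
                                - truth.coords[top.atom_index(a, "O")])
            assert d1 < 2.5 and d2 < 2.5

    def test_strands_are_beta(self, truth):
        dihedrals = chemshift.backbone_dihedrals(truth.topology, truth.coords)
        for res in sorted(truth.strand_residues)[1:-1]:
            phi, psi = dihedrals[res]
            assert chemshift.classify_secondary(phi, psi) == "strand"

    def test_same_seed_reproduces_coordinates(self, truth):
        again = synth.make_toy_fold(seed=truth.seed)
        assert np.array_equal(truth.coords, again.coords)
        assert np.array_equal(truth.coords_bound, again.coords_bound)

    def test_metal_position_at_sulfur_centroid(self, truth):
        top = truth.topology_bound
        sg = np.array([truth.coords_bound[top.atom_index(r, "SG")]
                       for r in truth.site_residues])
        assert np.linalg.norm(truth.metal_position - sg.mean(axis=0)) < 1.0

    def test_bound_form_close_to_coordination_geometry(self, truth):
        top = truth.topology_bound
        ag = truth.metal_position
        for r in truth.site_residues:
            d = float(np.linalg.norm(
                truth.coords_bound[top.atom_index(r, "SG")] - ag))
            assert d == pytest.approx(2.3, abs=0.15)


class TestSimulatedShifts:
    def test_zero_noise_reproduces_structure_offsets(self, truth, clean_shifts):
        offsets = truth.structure_offsets()
        for (res, atom), expected in offsets.items():
            s = clean_shifts.get(res, atom, "S")
            u = clean_shifts.get(res, atom, "U")
            assert (s.shift - u.shift) == pytest.approx(expected, abs=1e-9)

    def test_u_against_itself_is_zero(self, clean_shifts):
        profile = csp.compute_delta_rms(clean_shifts, clean_shifts,
                                        form_a="U", form_b="U")
        assert all(v == 0.0 for v in profile.values.values())

    def test_both_forms_present(self, clean_shifts):
        residues_s = set(clean_shifts.residues("S"))
        residues_u = set(clean_shifts.residues("U"))
        assert residues_s == residues_u and len(residues_s) >= 30

    def test_s_form_is_dispersed_relative_to_u(self, clean_shifts):
        hn_s = [e.shift for e in clean_shifts.by_nucleus(("HN",), form="S")]
        hn_u = [e.shift for e in clean_shifts.by_nucleus(("HN",), form="U")]
        assert np.std(hn_s) > 2 * np.std(hn_u)


class TestSimulatedNoesy:
    def test_every_clean_peak_traceable(self, clean_noesy):
        peaks, tmap = clean_noesy
        assert set(tmap) == {p.peak_id for p in peaks}
        assert all(v is not None for v in tmap.values())  # zero decoy rate

    def test_noisy_decoys_flagged(self, noisy_noesy):
        peaks, tmap = noisy_noesy
        n_decoys = sum(1 for v in tmap.values() if v is None)
        assert n_decoys == round(0.10 * (len(peaks) - n_decoys))

    def test_peak_positions_match_shifts_exactly_without_noise(
            self, truth, clean_shifts, clean_noesy):
        peaks, tmap = clean_noesy
        for p in list(peaks)[:50]:
            (ri, ai), (rj, aj) = tmap[p.peak_id]
            assert p.position[0] == pytest.approx(
                clean_shifts.get(ri, ai, "S").shift)
            assert p.position[1] == pytest.approx(
                clean_shifts.get(rj, aj, "S").shift)

    def test_intensity_distance_exponent_recovered(self, truth, noisy_noesy):
        """Regression of log I on log r recovers the -6 law within 0.3."""
        peaks, tmap = noisy_noesy
        top = truth.topology
        logs = []
        for p in peaks:
            pair = tmap[p.peak_id]
            if pair is None:
                continue
            (ri, ai), (rj, aj) = pair
            r = np.linalg.norm(truth.coords[top.atom_index(ri, ai)]
                               - truth.coords[top.atom_index(rj, aj)])
            logs.append((math.log(r), math.log(p.intensity)))
        x, y = np.array(logs).T
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(-6.0, abs=0.3)

    def test_intensity_ratio_follows_r6(self, truth, clean_noesy):
        peaks, tmap = clean_noesy
        top = truth.topology

        def r_of(p):
            (ri, ai), (rj, aj) = tmap[p.peak_id]
            return float(np.linalg.norm(truth.coords[top.atom_index(ri, ai)]
                                        - truth.coords[top.atom_index(rj, aj)]))

        plist = list(peaks)
        p1 = min(plist, key=lambda p: abs(r_of(p) - 2.5))
        p2 = min(plist, key=lambda p: abs(r_of(p) - 5.0))
        expected = (r_of(p1) / r_of(p2)) ** -6.0
        assert p1.intensity / p2.intensity == pytest.approx(expected, rel=1e-6)

    def test_weakest_peak_calibrates_to_dmax(self, clean_noesy):
        from nmrfold.restraints import calibrate_noe_distance

        peaks, _ = clean_noesy
        i_min = min(p.intensity for p in peaks)
        assert calibrate_noe_distance(i_min, i_min, 4.25) == pytest.approx(4.25)

    def test_amide_anchored_peaks_are_3d(self, clean_noesy):
        peaks, tmap = clean_noesy
        for p in peaks:
            pair = tmap[p.peak_id]
            has_hn = any(a == "HN" for _, a in pair)
            assert p.dims == (("H", "HN", "N") if has_hn else ("H", "H"))


class TestSimulatedTitration:
    def test_ratio_zero_is_exact_apo(self, truth):
        s1 = synth.simulate_titration(truth, noise=synth.NoiseModel(seed=5))
        s2 = synth.simulate_titration(truth, noise=synth.NoiseModel(seed=9))
        apo1 = {p.peak_id: p.position for p in s1.points[0][1]}
        apo2 = {p.peak_id: p.position for p in s2.points[0][1]}
        assert apo1 == apo2  # measurement noise never touches the reference

    def test_missing_apo_reference_rejected(self, truth):
        with pytest.raises(ValueError, match="apo"):
            synth.simulate_titration(truth, ratios=(0.5, 1.0))

    def test_site_peaks_drop_out_at_intermediate_ratios(self, truth):
        series = synth.simulate_titration(truth, noise=synth.NoiseModel(seed=5))
        mid = dict(series.points)[0.5]
        present = {p.peak_id for p in mid}
        for res in truth.site_residues:
            assert f"S{res}" not in present
        non_site = next(r for r in truth.topology.residue_indices
                        if r not in truth.site_residues)
        assert f"S{non_site}" in present

    def test_site_peaks_reappear_near_saturation(self, truth):
        series = synth.simulate_titration(truth, noise=synth.NoiseModel(seed=5))
        final = series.points[-1][1]
        for res in truth.site_residues:
            assert f"S{res}" in {p.peak_id for p in final}

    def test_u_form_converts_almost_completely(self, truth):
        series = synth.simulate_titration(truth, noise=synth.NoiseModel(seed=5))
        apo = series.points[0][1]
        final = series.points[-1][1]
        res = truth.topology.residue_indices[2]
        ratio = final[f"U{res}"].intensity / apo[f"U{res}"].intensity
        assert ratio < 0.05

    def test_bound_fraction_is_stoichiometric(self):
        assert synth.bound_fraction(0.0, 0.005) == 0.0
        f = synth.bound_fraction(1.2, 0.005)
        assert 0.95 < f < 1.0
        assert synth.bound_fraction(0.5, 0.005) == pytest.approx(0.5, abs=0.01)


class TestNoiseModel:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            synth.NoiseModel(miss_probability=1.5)
        with pytest.raises(ValueError):
            synth.NoiseModel(decoy_rate=-0.1)
        with pytest.raises(ValueError):
            synth.NoiseModel(intensity_sigma=-1.0)

    def test_noiseless_factory(self):
        nm = synth.NoiseModel.noiseless()
        assert nm.miss_probability == 0 and nm.decoy_rate == 0
        assert all(v == 0 for v in nm.jitter_by_nucleus.values())
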