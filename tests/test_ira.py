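"""Probabilistic assignment: scoring, candidate generation, stripping, cycles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrfold import ira
from nmrfold.io import Peak, PeakList, ShiftEntry, ShiftTable


def _entry(res, atom="HA", shift=4.0, form="S", rtype="A"):
    from nmrfold.io import infer_nucleus

    return ShiftEntry(res, rtype, atom, infer_nucleus(atom), shift, form)


class TestConfig:
    def test_mismatched_schedules_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            ira.IraConfig(sigma_d_schedule=(0.15, 0.1), f_schedule=(50, 20, 5))

    def test_f_must_exceed_one(self):
        with pytest.raises(ValueError, match="f must be > 1"):
            ira.IraConfig(sigma_d_schedule=(0.1,), f_schedule=(0.5,))

    def test_default_has_five_cycles(self):
        cfg = ira.IraConfig()
        assert cfg.n_cycles == 5
        assert cfg.f_schedule == (50.0, 50.0, 20.0, 10.0, 5.0)
        assert cfg.sigma_d_schedule == (0.15, 0.15, 0.15, 0.1, 0.05)


class TestScorePf:
    def test_exact_match_is_one(self):
        assert ira.score_pf([0.0, 0.0], ira.IraConfig()) == 1.0

    def test_one_sigma_deviation(self):
        # |mu - a| = sqrt(sigma_F^2 + gamma_F^2) in one dimension
        assert ira.score_pf([1.0], ira.IraConfig()) == pytest.approx(
            math.exp(-0.5))

    def test_gate_corresponds_to_2p3_sigma(self):
        # Delta = 2.305 -> P_F ~ 0.070: the 0.07 gate sits at ~2.3 deviations
        assert ira.score_pf([2.305], ira.IraConfig()) == pytest.approx(0.070, abs=5e-4)

    def test_density_normalized_variant(self):
        cfg = ira.IraConfig(normalized_density=True)
        assert ira.score_pf([0.0], cfg) == pytest.approx(1 / math.sqrt(2 * math.pi))

    @given(st.floats(0.0, 5.0), st.floats(0.01, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_deviation(self, d, extra):
        cfg = ira.IraConfig()
        assert ira.score_pf([d + extra], cfg) < ira.score_pf([d], cfg)

    def test_pair_scoring_uses_effective_sigma(self):
        cfg = ira.IraConfig()
        entry = _entry(1, "HA", 4.0)
        peak = Peak("p", ("H", "H"), (4.0, 4.0), 1e5)
        sigma_eff = math.hypot(cfg.sigma_f(entry), cfg.gamma_f_by_nucleus["H"])
        peak_off = Peak("p", ("H", "H"), (4.0 + sigma_eff, 4.0), 1e5)
        assert ira.pf_for_pair(peak, [entry, entry], cfg) == 1.0
        assert ira.pf_for_pair(peak_off, [entry, entry], cfg) == pytest.approx(
            math.exp(-0.5))


class _FixedTemplate:
    """Template stub returning preset distances per atom pair."""

    def __init__(self, distances, n_models=1):
        self.distances = distances
        self.n_models = n_models

    def proton_distance(self, pair):
        d = self.distances[pair]
        return [d] * self.n_models if np.isscalar(d) else d


def _candidate(res_i=1, res_j=9, p_f=1.0):
    return ira.AssignmentCandidate(
        "p", (_entry(res_i), _entry(res_j, atom="HN", shift=8.0)), p_f=p_f)


class TestScorePd:
    def test_no_template_long_range_prior(self):
        cand = _candidate(1, 9)
        assert ira.score_pd(cand, None, 0, ira.IraConfig()) == 0.1

    @pytest.mark.parametrize("sep,expected", [
        (0, 1.0), (1, 0.5), (2, 0.3), (3, 0.2), (4, 0.15), (7, 0.1)])
    def test_all_class_priors(self, sep, expected):
        cand = _candidate(5, 5 + sep)
        assert ira.score_pd(cand, None, 0, ira.IraConfig()) == expected

    def test_r0_at_rmin_gives_half(self):
        cfg = ira.IraConfig()
        cand = _candidate()
        tpl = _FixedTemplate({cand.atom_pair: cfg.r_min})
        assert ira.score_pd(cand, tpl, 0, cfg) == pytest.approx(0.5)

    def test_short_distance_saturates_at_kd(self):
        cfg = ira.IraConfig()
        cand = _candidate()
        tpl = _FixedTemplate({cand.atom_pair: 1.0})
        assert ira.score_pd(cand, tpl, 0, cfg) == pytest.approx(cfg.k_d, abs=1e-6)

    def test_ensemble_averages_pd_over_models(self):
        cfg = ira.IraConfig()
        cand = _candidate()
        r1, r2 = 2.0, 8.0
        tpl = _FixedTemplate({cand.atom_pair: [r1, r2]})
        separate = [
            ira.score_pd(cand, _FixedTemplate({cand.atom_pair: r}), 0, cfg)
            for r in (r1, r2)
        ]
        assert ira.score_pd(cand, tpl, 0, cfg) == pytest.approx(np.mean(separate))

    def test_missing_atoms_fall_back_to_prior(self):
        cand = _candidate(1, 9)
        with pytest.warns(UserWarning, match="class prior"):
            val = ira.score_pd(cand, _FixedTemplate({}), 0, ira.IraConfig())
        assert val == 0.1

    def test_nonincreasing_in_distance(self):
        cfg = ira.IraConfig()
        cand = _candidate()
        vals = [ira.score_pd(cand, _FixedTemplate({cand.atom_pair: r}), 0, cfg)
                for r in np.linspace(1.0, 10.0, 20)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestGenerateCandidates:
    def _shifts(self):
        return ShiftTable([
            _entry(1, "HA", 4.00), _entry(2, "HA", 4.50), _entry(1, "HN", 8.00),
            _entry(5, "HN", 8.60),
            _entry(1, "HA", 4.05, form="U"), _entry(3, "HA", 4.62, form="U"),
        ])

    def test_exact_match_has_pf_near_one(self):
        peaks = PeakList([Peak("p1", ("H", "H"), (4.00, 8.60), 1e5)])
        cands = ira.generate_candidates(peaks, self._shifts())
        best = max(cands, key=lambda c: c.p_f)
        assert best.atom_pair == ((1, "HA"), (5, "HN"))
        assert best.p_f > 0.99

    def test_medium_range_u_pair_excluded(self):
        peaks = PeakList([Peak("p1", ("H", "H"), (4.05, 4.62), 1e5)])
        cands = ira.generate_candidates(peaks, self._shifts())
        uu = [c for c in cands if c.both_u]
        assert uu and all(c.status == ira.EXCLUDED_U for c in uu)
        assert all(c.residue_separation <= 4 for c in uu)

    def test_far_peak_yields_no_candidates(self):
        peaks = PeakList([Peak("p1", ("H", "H"), (2.00, 8.00), 1e5)])
        cands = ira.generate_candidates(peaks, self._shifts())
        assert cands == []

    def test_wrong_dimensionality_rejected(self):
        peaks = PeakList([Peak("p1", ("HN", "N"), (8.0, 120.0), 1e5)])
        with pytest.raises(ValueError, match="proton-proton"):
            ira.generate_candidates(peaks, self._shifts())

    def test_gate_excludes_marginal_matches(self):
        cfg = ira.IraConfig()
        peaks = PeakList([Peak("p1", ("H", "H"), (4.00, 8.00), 1e5)])
        cands = ira.generate_candidates(peaks, self._shifts(), cfg)
        assert all(c.p_f > cfg.pf_threshold for c in cands)


def _make_cands(ps):
    out = []
    for k, p in enumerate(ps):
        c = ira.AssignmentCandidate(
            "pk", (_entry(1), _entry(5 + k, atom="HN", shift=8.0)), p_f=p)
        c.p_d = 1.0
        out.append(c)
    return out


class TestStripping:
    def test_strict_threshold(self):
        cands = _make_cands([1.0, 0.05, 0.001])
        ira.strip_candidates(cands, f=50)
        statuses = [c.status for c in cands]
        assert statuses == [ira.ACTIVE, ira.ACTIVE, ira.STRIPPED]

    def test_single_candidate_survives_any_f(self):
        cands = _make_cands([0.001])
        ira.strip_candidates(cands, f=1e6)
        assert cands[0].status == ira.ACTIVE

    def test_ties_at_max_both_survive(self):
        cands = _make_cands([0.4, 0.4])
        ira.strip_candidates(cands, f=50)
        assert all(c.status == ira.ACTIVE for c in cands)

    def test_stripped_candidates_keep_scores(self):
        cands = _make_cands([1.0, 1e-5])
        ira.strip_candidates(cands, f=10)
        assert cands[1].status == ira.STRIPPED and cands[1].p == pytest.approx(1e-5)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=50),
           st.sampled_from([50.0, 20.0, 10.0, 5.0]))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_rule(self, ps, f):
        cands = _make_cands(ps)
        ira.strip_candidates(cands, f)
        p_max = max(ps)
        for c, p in zip(cands, ps):
            expected = ira.STRIPPED if p < p_max / f else ira.ACTIVE
            assert c.status == expected


class TestRunCycles:
    def _dataset(self):
        shifts = ShiftTable([
            _entry(1, "HA", 4.00), _entry(5, "HN", 8.00),
            _entry(2, "HA", 4.40), _entry(6, "HN", 8.40),
        ])
        peaks = PeakList([
            Peak("a", ("H", "H"), (4.00, 8.00), 1e5),
            Peak("b", ("H", "H"), (4.40, 8.40), 2e5),
        ])
        return peaks, shifts

    def test_default_runs_five_cycles(self):
        peaks, shifts = self._dataset()
        tpl = _FixedTemplate({
            ((1, "HA"), (5, "HN")): 3.0, ((1, "HA"), (6, "HN")): 9.0,
            ((2, "HA"), (6, "HN")): 3.0, ((2, "HA"), (5, "HN")): 9.0,
        })
        result = ira.run_cycles(peaks, shifts, lambda rs: tpl)
        assert len(result.audit) == 5
        assert result.audit[-1].cycle == 5

    def test_conservation_of_peaks(self):
        peaks, shifts = self._dataset()
        tpl = _FixedTemplate({
            ((1, "HA"), (5, "HN")): 3.0, ((1, "HA"), (6, "HN")): 9.0,
            ((2, "HA"), (6, "HN")): 3.0, ((2, "HA"), (5, "HN")): 9.0,
        })
        result = ira.run_cycles(peaks, shifts, lambda rs: tpl)
        final = result.audit[-1]
        assert final.n_peaks_assigned + final.n_peaks_dropped == len(peaks)

    def test_engine_failure_aborts_with_context(self):
        peaks, shifts = self._dataset()

        def broken(rs):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="cycle 1"):
            ira.run_cycles(peaks, shifts, broken)

    def test_restraints_from_candidates_builds_ambiguous_sets(self):
        peaks, shifts = self._dataset()
        cands = ira.generate_candidates(peaks, shifts)
        for c in cands:
            c.p_d = 1.0
        rs = ira.restraints_from_candidates(peaks, cands)
        assert len(rs.distances) == 2
        # stronger peak 'b' calibrates shorter than the weakest peak 'a'
        by_source = {r.source: r for r in rs.distances}
        assert by_source["a"].target == pytest.approx(4.25)
        assert by_source["b"].target < 4.25
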