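"""Topology building, energy model, torsion machinery, superposition,
annealing determinism and selection."""

import math

import numpy as np
import pytest

from nmrfold import engine, geom
from nmrfold.restraints import (
    DistanceRestraint, RestraintSet, make_metal_restraints,
)


class TestBuildTopology:
    def test_backbone_atoms_present_and_proline_lacks_hn(self):
        top = engine.build_topology("APG")
        for res in (1, 2, 3):
            for atom in ("N", "CA", "HA", "C", "O"):
                assert top.has_atom(res, atom)
        assert top.has_atom(1, "HN")
        assert not top.has_atom(2, "HN")  # proline

    def test_restrained_sidechain_atom_instantiated_with_parents(self):
        top = engine.build_topology("ACG", restraint_atoms=[(2, "SG")])
        assert top.has_atom(2, "SG") and top.has_atom(2, "CB")
        assert not top.has_atom(1, "CB")  # not requested

    def test_sg_on_met_rejected(self):
        with pytest.raises(ValueError, match="no atom"):
            engine.build_topology("AMG", restraint_atoms=[(2, "SG")])

    def test_met_chain_pulled_in_for_ce(self):
        top = engine.build_topology("AMG", restraint_atoms=[(2, "CE")])
        for atom in ("CB", "CG", "SD", "CE"):
            assert top.has_atom(2, atom)

    def test_metal_atom_appended(self):
        top = engine.build_topology("ACG", with_metal=True)
        assert top.has_metal and top.has_atom(0, "AG")

    def test_deterministic_ordering(self):
        t1 = engine.build_topology("ACDEFG", restraint_atoms=[(2, "SG")])
        t2 = engine.build_topology("ACDEFG", restraint_atoms=[(2, "SG")])
        assert [a.atom_name for a in t1.atoms] == [a.atom_name for a in t2.atoms]


class TestEnergyGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        top = engine.build_topology("GAVC", restraint_atoms=[(4, "SG")])
        rs = RestraintSet(distances=[DistanceRestraint(
            member_pairs=(((1, "HA"), (4, "HA")), ((2, "HA"), (4, "HA"))),
            target=4.0, lower=3.0, upper=4.5)])
        from nmrfold.restraints import DihedralRestraint

        rs.dihedrals.append(DihedralRestraint(2, "phi", -100.0, 15.0))
        model = engine.EnergyModel(top, rs)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, (top.n_atoms, 3)).ravel()
        e, g = model(x)
        h = 1e-6
        num = np.empty_like(g)
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (model(xp)[0] - model(xm)[0]) / (2 * h)
        scale = np.abs(num).max() + 1.0
        assert np.abs(g - num).max() / scale < 5e-4

    def test_components_sum_to_total(self):
        top = engine.build_topology("GAV")
        model = engine.EnergyModel(top, RestraintSet())
        x = np.random.default_rng(1).normal(0, 2, (top.n_atoms, 3))
        e, _ = model(x.ravel())
        assert e == pytest.approx(sum(model.components.values()))


class TestTorsionBuilder:
    def _top(self):
        return engine.build_topology("GACAG", restraint_atoms=[(3, "SG")])

    def test_built_chain_has_requested_torsions(self):
        from nmrfold import chemshift

        top = self._top()
        tb = engine.TorsionBuilder(top)
        tau = tb.default_torsions()
        x = tb.build(tau)
        dihedrals = chemshift.backbone_dihedrals(top, x)
        for res in (2, 3, 4):
            phi, psi = dihedrals[res]
            assert phi == pytest.approx(-120.0, abs=0.5)
            assert psi == pytest.approx(130.0, abs=0.5)

    def test_built_chain_is_nearly_ideal_geometry(self):
        top = self._top()
        tb = engine.TorsionBuilder(top)
        model = engine.EnergyModel(top, RestraintSet())
        e, _ = model(tb.build(tb.default_torsions()).ravel())
        assert e < 20.0  # residual is tiny placement slack, not strain

    def test_l_configuration(self):
        # signed volume (N-CA) . ((C-CA) x (HA-CA)) < 0 for L-amino acids
        top = self._top()
        tb = engine.TorsionBuilder(top)
        x = tb.build(tb.default_torsions())
        for res in (2, 3, 4):
            ca = x[top.atom_index(res, "CA")]
            u = x[top.atom_index(res, "N")] - ca
            v = x[top.atom_index(res, "C")] - ca
            w = x[top.atom_index(res, "HA")] - ca
            assert float(np.dot(u, np.cross(v, w))) < 0

    def test_torsion_gradient_projection(self):
        top = self._top()
        tb = engine.TorsionBuilder(top)
        rs = RestraintSet(distances=[DistanceRestraint(
            member_pairs=(((1, "HA"), (5, "HA")),), target=5.0, lower=4.0,
            upper=6.0)])
        model = engine.EnergyModel(top, rs)
        rng = np.random.default_rng(2)
        tau = tb.default_torsions() + rng.normal(0, 20, tb.n_variables())
        x = tb.build(tau)
        e, g = model(x.ravel())
        analytic = tb.project_gradient(x, g.reshape(-1, 3))
        h = 1e-4
        for i in range(tb.n_variables()):
            tp, tm = tau.copy(), tau.copy()
            tp[i] += h
            tm[i] -= h
            num = (model(tb.build(tp).ravel())[0]
                   - model(tb.build(tm).ravel())[0]) / (2 * h)
            assert analytic[i] == pytest.approx(num, abs=2e-2, rel=2e-3)


class TestSuperposeRmsd:
    def test_identical_models_zero(self):
        x = np.random.default_rng(0).normal(0, 5, (10, 3))
        _, _, rmsd = engine.superpose_rmsd(x, x)
        assert rmsd < 1e-9

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5, (12, 3))
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        y = x @ rot.T + np.array([3.0, -2.0, 7.0])
        _, _, rmsd = engine.superpose_rmsd(x, y)
        assert rmsd < 1e-6

    def test_matches_quaternion_oracle(self):
        # independent quaternion (Horn) method on a known 4-point problem
        rng = np.random.default_rng(3)
        p = rng.normal(0, 3, (4, 3))
        q = p + rng.normal(0, 1.0, (4, 3))
        _, _, rmsd = engine.superpose_rmsd(p, q)

        pc, qc = p - p.mean(0), q - q.mean(0)
        m = np.einsum("ni,nj->ij", qc, pc)
        sxx, sxy, sxz = m[0]
        syx, syy, syz = m[1]
        szx, szy, szz = m[2]
        k = np.array([
            [sxx + syy + szz, szy - syz, sxz - szx, syx - sxy],
            [szy - syz, sxx - syy - szz, sxy + syx, szx + sxz],
            [sxz - szx, sxy + syx, -sxx + syy - szz, syz + szy],
            [syx - sxy, szx + sxz, syz + szy, -sxx - syy + szz],
        ])
        lam = np.linalg.eigvalsh(k)[-1]
        e0 = float(np.sum(pc * pc) + np.sum(qc * qc))
        rmsd_oracle = math.sqrt(max(e0 - 2 * lam, 0.0) / len(p))
        assert rmsd == pytest.approx(rmsd_oracle, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            engine.superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


SMALL = engine.AnnealSchedule(n_starts=1, maxiter_fold=100, maxiter_stage=100,
                              maxiter_final=200)


class TestAnneal:
    def test_no_restraints_gives_clean_chain(self):
        top = engine.build_topology("GAVAG")
        conf = engine.anneal(top, RestraintSet(), seed=1, schedule=SMALL)
        assert conf.energies["noe"] == 0.0
        assert conf.energies["dihedral"] == 0.0
        assert conf.energies["geometry"] < 20.0

    def test_deterministic_under_seed(self):
        top = engine.build_topology("GAVAG")
        rs = RestraintSet(distances=[DistanceRestraint(
            member_pairs=(((1, "HA"), (5, "HA")),), target=6.0, lower=5.0,
            upper=7.0)])
        c1 = engine.anneal(top, rs, seed=7, schedule=SMALL)
        c2 = engine.anneal(top, rs, seed=7, schedule=SMALL)
        assert np.array_equal(c1.coords, c2.coords)

    def test_different_seed_differs(self):
        top = engine.build_topology("GAVAG")
        c1 = engine.anneal(top, RestraintSet(), seed=1, schedule=SMALL)
        c2 = engine.anneal(top, RestraintSet(), seed=2, schedule=SMALL)
        assert not np.allclose(c1.coords, c2.coords)

    def test_quench_trace_monotone_nonincreasing(self):
        top = engine.build_topology("GAVAG")
        conf = engine.anneal(top, RestraintSet(), seed=3, schedule=SMALL)
        trace = conf.quench_trace
        assert len(trace) >= 1
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_trigonal_metal_site_refines_to_target_geometry(self):
        # three cysteines + explicit coordination restraints only
        top = engine.build_topology("GCACAC", restraint_atoms=[
            (2, "SG"), (4, "SG"), (6, "SG")], with_metal=True)
        rs = make_metal_restraints([(2, "SG"), (4, "SG"), (6, "SG")],
                                   mode="explicit")
        conf = engine.anneal(top, rs, seed=11,
                             schedule=engine.AnnealSchedule(
                                 n_starts=2, maxiter_fold=200,
                                 maxiter_stage=200, maxiter_final=400))
        ag = conf.coords[top.atom_index(0, "AG")]
        sgs = [conf.coords[top.atom_index(r, "SG")] for r in (2, 4, 6)]
        bonds = [np.linalg.norm(ag - s) for s in sgs]
        assert np.allclose(bonds, 2.3, atol=0.1)
        for i in range(3):
            for j in range(i + 1, 3):
                u = sgs[i] - ag
                v = sgs[j] - ag
                ang = math.degrees(math.acos(
                    np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
                assert ang == pytest.approx(120.0, abs=8.0)


class TestSelectEnsemble:
    def _pool(self, energies):
        top = engine.build_topology("GAG")
        confs = [
            engine.Conformer(coords=np.full((top.n_atoms, 3), float(i)),
                             energies={"geometry": e})
            for i, e in enumerate(energies)
        ]
        return top, confs

    def test_lowest_energy_first(self):
        top, confs = self._pool([5.0, 1.0, 3.0])
        ens = engine.select_ensemble(confs, n_select=2, topology=top)
        assert ens.scores == [1.0, 3.0]

    def test_oversized_selection_warns_and_returns_pool(self):
        top, confs = self._pool([1.0, 2.0])
        with pytest.warns(UserWarning):
            ens = engine.select_ensemble(confs, n_select=10, topology=top)
        assert len(ens) == 2

    def test_ties_broken_by_index(self):
        top, confs = self._pool([2.0, 2.0, 1.0])
        ens = engine.select_ensemble(confs, n_select=2, topology=top)
        assert ens.models[0].coords[0, 0] == 2.0  # index 2 (E=1) first
        assert ens.models[1].coords[0, 0] == 0.0  # then index 0 of the tie

    def test_null_predictor_ranks_by_energy_only(self):
        top, confs = self._pool([4.0, 2.0])
        ens = engine.select_ensemble(confs, observed_shifts=None, topology=top)
        assert all(m.energies["shift_pseudo"] == 0.0 for m in ens.models)
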