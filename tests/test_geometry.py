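import numpy as np
import pytest
from scipy.optimize import minimize as scipy_minimize

from conftest import random_chain
from refine2lite.fixtures import make_ideal_helix, make_ideal_strand
from refine2lite.geometry import (
    BondGeometry,
    ChainBreakError,
    TorsionSeries,
    assign_secondary_structure,
    circular_difference,
    compute_backbone_torsions,
    kabsch_superpose,
    loop_closure_gap,
    rebuild_backbone_from_torsions,
    triaxial_loop_closure,
)

ANCHOR = np.array([[0.0, 0.0, 0.0], [1.458, 0.0, 0.0], [2.0, 1.4, 0.0]])


class TestTorsions:
    def test_ideal_helix_torsions(self, helix20):
        t = compute_backbone_torsions(helix20)
        assert np.allclose(t.phi[1:], -57.0, atol=1.0)
        assert np.allclose(t.psi[:-1], -47.0, atol=1.0)
        assert not np.isfinite(t.phi[0]) and not np.isfinite(t.psi[-1])

    def test_trans_peptide_omega(self, helix20):
        t = compute_backbone_torsions(helix20)
        assert np.allclose(np.abs(t.omega[:-1]), 180.0, atol=1e-6)

    def test_round_trip_with_extracted_geometry(self):
        model = random_chain(15, seed=2)
        t = compute_backbone_torsions(model)
        geo = BondGeometry.from_model(model)
        rebuilt = rebuild_backbone_from_torsions(t, model.backbone_coords()[0, :3], geo)
        assert np.abs(rebuilt.backbone_coords() - model.backbone_coords()).max() <= 1e-6

    def test_chain_break_raises_with_location(self, helix20):
        broken = helix20.copy()
        for res in broken.residues[8:]:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + 30.0
        with pytest.raises(ChainBreakError, match="8"):
            compute_backbone_torsions(broken)


class TestRebuild:
    def test_helical_ca_ca_distance(self):
        n = 10
        t = TorsionSeries(
            np.concatenate([[np.nan], np.full(n - 1, -57.0)]),
            np.concatenate([np.full(n - 1, -47.0), [np.nan]]),
            np.concatenate([np.full(n - 1, 180.0), [np.nan]]),
        )
        m = rebuild_backbone_from_torsions(t, ANCHOR)
        ca = m.coords("CA")
        d = np.linalg.norm(ca[1:] - ca[:-1], axis=1)
        assert np.allclose(d, 3.8, atol=0.05)

    def test_single_residue_returns_anchor(self):
        t = TorsionSeries([np.nan], [np.nan], [np.nan])
        m = rebuild_backbone_from_torsions(t, ANCHOR)
        assert np.allclose(m.backbone_coords()[0, :3], ANCHOR)

    def test_undefined_interior_torsion_raises(self):
        t = TorsionSeries([np.nan, np.nan, -60.0], [-40.0, -40.0, np.nan],
                          [180.0, 180.0, np.nan])
        with pytest.raises(ValueError, match="undefined interior"):
            rebuild_backbone_from_torsions(t, ANCHOR)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        tr, rmsd = kabsch_superpose(pts, pts)
        assert rmsd <= 1e-9
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation

        P = rng.normal(size=(12, 3))
        R = Rotation.random(random_state=3).as_matrix()
        Q = P @ R.T + np.array([5.0, -2.0, 1.0])
        tr, rmsd = kabsch_superpose(P, Q)
        assert rmsd <= 1e-9
        assert np.isclose(np.linalg.det(tr.rotation), 1.0, atol=1e-9)

    def test_matches_quaternion_optimizer_oracle(self, rng):
        """RMSD equals a brute-force minimization over quaternion rotations."""
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        _, rmsd = kabsch_superpose(P, Q)

        def loss(q):
            q = q / np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            Pc = P - P.mean(axis=0)
            Qc = Q - Q.mean(axis=0)
            return np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))

        best = min(
            scipy_minimize(loss, q0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000}).fun
            for q0 in np.random.default_rng(0).normal(size=(8, 4))
        )
        assert np.isclose(rmsd, np.sqrt(best), atol=1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _loop_setup(seed, n=12, s=3, e=8):
    model = random_chain(n, seed, compact=False)
    t = compute_backbone_torsions(model)
    bb = model.backbone_coords()
    lt = TorsionSeries(t.phi[s:e + 1].copy(), t.psi[s:e + 1].copy(),
                       np.full(e - s + 1, 180.0))
    n_anchor = np.array([bb[s - 1, 2], bb[s, 0], bb[s, 1]])
    c_anchor = bb[e + 1, :3]
    return lt, n_anchor, c_anchor, t.phi[e + 1]


class TestTriaxialLoopClosure:
    def test_identity_recovery_on_perturbed_pivots(self):
        rng = np.random.default_rng(7)
        pivots = (0, 3, 5)
        for seed in range(10):
            lt, na, ca, phi_next = _loop_setup(seed)
            truth = np.concatenate([lt.phi[list(pivots)], lt.psi[list(pivots)]])
            pert = lt.copy()
            for p in pivots:
                pert.phi[p] += rng.uniform(-90, 90)
                pert.psi[p] += rng.uniform(-90, 90)
            sols = triaxial_loop_closure(pert, na, ca, pivots, phi_next)
            assert sols, f"no solutions on seed {seed}"
            recovered = any(
                np.max(np.abs(circular_difference(
                    np.concatenate([s.phi[list(pivots)], s.psi[list(pivots)]]),
                    truth))) < 1e-4
                for s in sols
            )
            assert recovered, f"original closure not among solutions (seed {seed})"

    def test_all_solutions_close_the_chain(self):
        rng = np.random.default_rng(11)
        for seed in range(20, 30):
            lt, na, ca, phi_next = _loop_setup(seed)
            pert = lt.copy()
            for p in (0, 3, 5):
                pert.phi[p] = rng.uniform(-180, 180)
                pert.psi[p] = rng.uniform(-180, 180)
            sols = triaxial_loop_closure(pert, na, ca, (0, 3, 5), phi_next)
            for sol in sols:
                gap, _ = loop_closure_gap(sol, na, ca, phi_next)
                assert gap < 1e-6

    def test_nonpivot_torsions_unchanged(self):
        lt, na, ca, phi_next = _loop_setup(3)
        pivots = (0, 2, 5)
        pert = lt.copy()
        pert.phi[2] += 40.0
        sols = triaxial_loop_closure(pert, na, ca, pivots, phi_next)
        nonpivot = [i for i in range(len(lt)) if i not in pivots]
        for sol in sols:
            assert np.allclose(sol.phi[nonpivot], pert.phi[nonpivot])
            assert np.allclose(sol.psi[nonpivot], pert.psi[nonpivot])

    def test_solution_count_matches_multistart_oracle(self):
        """Independent oracle: multi-start least-squares over the six pivot
        torsions, converged roots clustered and counted."""
        from scipy.optimize import least_squares

        pivots = (0, 3, 5)
        for seed in (1, 4):
            lt, na, ca, phi_next = _loop_setup(seed)
            pert = lt.copy()
            rng = np.random.default_rng(seed)
            for p in pivots:
                pert.phi[p] = rng.uniform(-180, 180)
                pert.psi[p] = rng.uniform(-180, 180)
            sols = triaxial_loop_closure(pert, na, ca, pivots, phi_next)

            def resid(x):
                t = pert.copy()
                for k, p in enumerate(pivots):
                    t.phi[p] = x[k]
                    t.psi[p] = x[3 + k]
                from refine2lite.geometry import BondGeometry, _loop_forward, place_atom
                from refine2lite.config import IDEAL_GEOMETRY as g

                geo = BondGeometry.ideal(len(t), psi=t.psi)
                bb = _loop_forward(t, na, geo)
                Nn = place_atom(bb[-1, 0], bb[-1, 1], bb[-1, 2], g["bond_c_n"],
                                g["angle_ca_c_n"], t.psi[-1])
                CAn = place_atom(bb[-1, 1], bb[-1, 2], Nn, g["bond_n_ca"],
                                 g["angle_c_n_ca"], 180.0)
                Cn = place_atom(bb[-1, 2], Nn, CAn, g["bond_ca_c"],
                                g["angle_n_ca_c"], phi_next)
                return np.concatenate([Nn - ca[0], CAn - ca[1], Cn - ca[2]])

            roots = []
            rng2 = np.random.default_rng(100 + seed)
            for _ in range(60):
                x0 = rng2.uniform(-180, 180, 6)
                res = least_squares(resid, x0, method="lm", max_nfev=500)
                if res.cost < 1e-16:
                    x = circular_difference(res.x, 0.0)
                    if not any(np.max(np.abs(circular_difference(x, r))) < 1e-3
                               for r in roots):
                        roots.append(x)
            assert len(sols) == len(roots), (
                f"seed {seed}: solver found {len(sols)}, oracle {len(roots)}"
            )


class TestSecondaryStructure:
    def test_helix_all_interior_h(self, helix20):
        labels = assign_secondary_structure(helix20).labels
        assert all(lab == "H" for lab in labels[1:-1])

    def test_strand_assignment(self):
        labels = assign_secondary_structure(make_ideal_strand(10)).labels
        assert all(lab == "E" for lab in labels[1:-1])

    def test_mixed_fixture_matches_manual_bins(self):
        # hand-built: 5 helix, 1 outside any bin, 5 strand
        n = 11
        phi = np.concatenate([[np.nan], np.full(4, -57.0), [60.0], np.full(5, -120.0)])
        psi = np.concatenate([np.full(5, -47.0), [60.0], np.full(4, 120.0), [np.nan]])
        om = np.concatenate([np.full(n - 1, 180.0), [np.nan]])
        m = rebuild_backbone_from_torsions(TorsionSeries(phi, psi, om), ANCHOR)
        labels = assign_secondary_structure(m).labels
        # manual application: residues 1-4 H (0 undefined), 5 C, 6-9 E (10 undefined)
        assert labels == ["C", "H", "H", "H", "H", "C", "E", "E", "E", "E", "C"]

    def test_singleton_smoothing(self):
        n = 9
        phi = np.concatenate([[np.nan], np.full(n - 1, 60.0)])
        phi[4] = -57.0  # lone helical residue in a sea of coil
        psi = np.concatenate([np.full(n - 1, 60.0), [np.nan]])
        psi[4] = -47.0
        om = np.concatenate([np.full(n - 1, 180.0), [np.nan]])
        m = rebuild_backbone_from_torsions(TorsionSeries(phi, psi, om), ANCHOR)
        assert assign_secondary_structure(m).labels[4] == "C"
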