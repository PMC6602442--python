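import numpy as np
import pytest

from conftest import random_chain
from refine2lite.energy import RelaxSchedule, build_restraints
from refine2lite.error_estimation import (
    ErrorModelCoefficients,
    FragmentLibrary,
    ResidueErrorProfile,
    detect_ulrs,
    fit_error_model,
    frag_score,
    msa_score,
    predict_residue_error,
    read_fragment_library,
    read_pssm,
    rmsf_score,
    write_fragment_library,
    write_pssm,
)
from refine2lite.geometry import compute_backbone_torsions


class TestRmsf:
    def test_zero_steps_ensemble_gives_zero_rmsf(self, bundle):
        # with no relaxation every run returns the same structure
        rs = build_restraints(bundle)
        out = rmsf_score(bundle, rs, n_runs=3,
                         schedule=RelaxSchedule(steps=0, mode="noisy-minimize"))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_requires_two_runs(self, bundle):
        rs = build_restraints(bundle)
        with pytest.raises(ValueError):
            rmsf_score(bundle, rs, n_runs=1)

    def test_default_run_count_is_24(self):
        from refine2lite.config import DEFAULTS

        assert DEFAULTS["rmsf_runs"] == 24

    def test_rigid_motion_does_not_inflate_rmsf(self, bundle):
        """Two-member hand ensemble vs the direct RMSF formula."""
        from refine2lite.geometry import kabsch_superpose

        ca = bundle.coords("CA")
        moved = ca.copy()
        moved[5] += np.array([0.0, 0.0, 1.0])   # one CA displaced 1 A
        # direct formula: superpose both onto the iterative mean, RMS dev
        ensemble = np.array([ca, moved])
        mean = ensemble[0].copy()
        for _ in range(20):
            aligned = []
            for c in ensemble:
                tr, _ = kabsch_superpose(c, mean)
                aligned.append(tr.apply(c))
            aligned = np.array(aligned)
            mean = aligned.mean(axis=0)
        expect = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=-1), axis=0))
        # residue 5 carries nearly all the fluctuation
        assert expect[5] == max(expect)
        assert expect[5] == pytest.approx(0.5, abs=0.05)


class TestFrag:
    def test_own_windows_score_zero(self, bundle):
        t = compute_backbone_torsions(bundle)
        lib = FragmentLibrary(window=7)
        for s in range(len(t) - 6):
            phi = np.nan_to_num(t.phi[s: s + 7], nan=-70.0)
            psi = np.nan_to_num(t.psi[s: s + 7], nan=140.0)
            lib.add(phi, psi)
        out = frag_score(bundle, lib)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_constant_offset_single_fragment(self):
        model = random_chain(7, seed=0)
        t = compute_backbone_torsions(model)
        lib = FragmentLibrary(window=7)
        lib.add(np.nan_to_num(t.phi, nan=-70.0) + 10.0,
                np.nan_to_num(t.psi, nan=140.0) + 10.0)
        out = frag_score(model, lib)
        # single window covering everything; constant 10 deg offset
        assert np.allclose(out, 10.0, atol=1e-9)

    def test_matches_brute_force_double_loop(self):
        model = random_chain(12, seed=3)
        rng = np.random.default_rng(4)
        lib = FragmentLibrary(window=5)
        for _ in range(6):
            lib.add(rng.uniform(-180, 180, 5), rng.uniform(-180, 180, 5))
        got = frag_score(model, lib)
        # independent oracle
        t = compute_backbone_torsions(model)
        L, w = len(t), 5

        def circ(a, b):
            return np.abs((a - b + 180.0) % 360.0 - 180.0)

        sums = np.zeros(L)
        counts = np.zeros(L)
        for s in range(L - w + 1):
            best = np.inf
            for _, fphi, fpsi in lib.fragments:
                diffs = []
                for k in range(w):
                    if np.isfinite(t.phi[s + k]):
                        diffs.append(circ(t.phi[s + k], fphi[k]))
                    if np.isfinite(t.psi[s + k]):
                        diffs.append(circ(t.psi[s + k], fpsi[k]))
                best = min(best, np.mean(diffs))
            sums[s: s + w] += best
            counts[s: s + w] += 1
        np.testing.assert_allclose(got, sums / counts, atol=1e-9)

    def test_empty_library_raises(self, bundle):
        with pytest.raises(ValueError, match="empty"):
            frag_score(bundle, FragmentLibrary())


class TestMsa:
    def test_constant_matrix_gives_minus_v(self):
        pssm = np.full((6, 20), 3.0)
        out = msa_score(pssm, "A" * 6)
        assert np.allclose(out, -3.0)

    def test_window_one_is_identity(self, rng):
        pssm = rng.normal(size=(10, 20))
        raw = msa_score(pssm, "A" * 10, window=1)
        np.testing.assert_allclose(raw, -pssm.mean(axis=1))

    def test_window_three_matches_moving_average_oracle(self, rng):
        pssm = rng.normal(size=(11, 20))
        raw = -pssm.mean(axis=1)
        got = msa_score(pssm, "A" * 11, window=3)
        expect = np.array([
            raw[max(0, i - 1): min(11, i + 2)].mean() for i in range(11)
        ])
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            msa_score(np.zeros((5, 20)), "AAAA")


class TestLinearModel:
    @staticmethod
    def _profiles(n, coeffs, sigma, rng):
        rmsf = rng.uniform(0, 2, n)
        frag = rng.uniform(0, 40, n)
        msa = rng.normal(0, 1, n)
        y = (coeffs[0] + coeffs[1] * rmsf + coeffs[2] * frag + coeffs[3] * msa
             + rng.normal(0, sigma, n))
        return ResidueErrorProfile(rmsf=rmsf, frag=frag, msa=msa), y

    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        truth = (0.3, 1.2, 0.04, 0.5)
        prof, y = self._profiles(60, truth, 0.0, rng)
        c = fit_error_model([prof], [y])
        assert np.allclose([c.intercept, c.w_rmsf, c.w_frag, c.w_msa], truth,
                           atol=1e-8)

    def test_coefficients_within_3se_in_95pct_of_replicates(self):
        """Monte-Carlo calibration check with the analytic OLS covariance."""
        truth = np.array([0.3, 1.2, 0.04, 0.5])
        sigma, n = 0.1, 200
        covered = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            prof, y = self._profiles(n, truth, sigma, rng)
            X = np.column_stack([np.ones(n), prof.rmsf, prof.frag, prof.msa])
            c = fit_error_model([prof], [y])
            beta = np.array([c.intercept, c.w_rmsf, c.w_frag, c.w_msa])
            resid = y - X @ beta
            s2 = resid @ resid / (n - 4)
            se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
            covered += np.all(np.abs(beta - truth) <= 3 * se)
        assert covered >= 95

    def test_constant_column_rank_deficiency(self):
        rng = np.random.default_rng(2)
        prof, y = self._profiles(50, (0, 1, 0.1, 0.2), 0.1, rng)
        prof.rmsf = np.full(50, 1.7)   # collinear with the intercept
        with pytest.raises(np.linalg.LinAlgError):
            fit_error_model([prof], [y])

    def test_three_parameter_model_without_msa(self):
        rng = np.random.default_rng(3)
        prof, y = self._profiles(50, (0.2, 1.0, 0.05, 0.0), 0.0, rng)
        prof.msa = None
        c = fit_error_model([prof], [y])
        assert c.w_msa is None
        assert c.w_rmsf == pytest.approx(1.0, abs=1e-6)

    def test_predict_clamps_at_zero(self):
        prof = ResidueErrorProfile(rmsf=np.zeros(4), frag=np.zeros(4))
        pred = predict_residue_error(prof, ErrorModelCoefficients(-1.0, 1, 1))
        assert np.all(pred == 0.0)

    def test_predict_monotone_in_rmsf(self):
        prof = ResidueErrorProfile(rmsf=np.array([0.0, 0.0]), frag=np.zeros(2))
        c = ErrorModelCoefficients(0.5, 1.0, 0.0)
        base = predict_residue_error(prof, c).copy()
        prof.rmsf = np.array([0.0, 1.0])
        up = predict_residue_error(prof, c)
        assert up[1] > base[1] and up[0] == base[0]

    def test_intercept_only(self):
        prof = ResidueErrorProfile(rmsf=np.zeros(3), frag=np.zeros(3))
        pred = predict_residue_error(prof, ErrorModelCoefficients(0.5, 1, 1))
        assert np.allclose(pred, 0.5)


class TestDetectUlrs:
    def test_hand_case(self):
        assert detect_ulrs([0, 0, 5, 5, 5, 0, 0], 1.0, 3, 1) == [(3, 5)]

    def test_all_below_threshold(self):
        assert detect_ulrs([0.1] * 10, 1.0, 3, 1) == []

    def test_merge_gap_rule(self):
        vals = [5, 5, 0, 5, 5]
        assert detect_ulrs(vals, 1.0, 3, merge_gap=1) == [(1, 5)]
        assert detect_ulrs(vals, 1.0, 3, merge_gap=0) == []

    def test_termini_eligible(self):
        assert detect_ulrs([5, 5, 5, 0, 0, 0, 5, 5, 5], 1.0, 3, 0) == [(1, 3), (7, 9)]

    def test_ranges_sorted_nonoverlapping_property(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 2, 30)
            thr = float(rng.uniform(0.5, 1.5))
            ulrs = detect_ulrs(vals, thr, min_len=2, merge_gap=1)
            flat = [r for s, e in ulrs for r in range(s, e + 1)]
            assert flat == sorted(set(flat))   # sorted, no overlap
            for s, e in ulrs:
                assert e - s + 1 >= 2


class TestFileDialects:
    def test_pssm_round_trip(self, tmp_path, rng):
        seq = "ACDEFGHIKL"
        pssm = np.round(rng.normal(0, 3, (10, 20)))
        path = tmp_path / "t.pssm"
        write_pssm(path, pssm, seq)
        back, back_seq = read_pssm(path)
        assert back_seq == seq
        np.testing.assert_allclose(back, pssm)

    def test_fraglib_round_trip(self, tmp_path, rng):
        lib = FragmentLibrary(window=5)
        for _ in range(4):
            lib.add(rng.uniform(-180, 180, 5), rng.uniform(-180, 180, 5))
        path = tmp_path / "frags.tsv"
        write_fragment_library(path, lib)
        back = read_fragment_library(path)
        assert back.window == 5 and len(back) == 4
        for (w1, p1, s1), (w2, p2, s2) in zip(lib.fragments, back.fragments):
            assert w1 == w2
            np.testing.assert_allclose(p1, p2, atol=1e-3)
            np.testing.assert_allclose(s1, s2, atol=1e-3)
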