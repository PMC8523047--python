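"""Deformation-gradient estimation, polar decomposition, and scalar
contractile metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcokinetics import mechanics
from sarcokinetics.mechanics import (
    analyze_J,
    c_iso,
    c_parallel,
    compute_F_series,
    estimate_F,
    pair_vectors,
    polar_and_stretches,
    select_frames,
    shortening,
    shortening_summary,
    structural_tensor_oop,
)

MARKERS = np.array([[0.0, 0.0], [10.0, 2.0], [3.0, 8.0], [7.0, 12.0], [12.0, 9.0]])


class TestPairVectors:
    @pytest.mark.parametrize("m,n", [(3, 3), (10, 45)])
    def test_pair_count(self, m, n):
        rng = np.random.default_rng(m)
        assert pair_vectors(rng.uniform(0, 10, size=(m, 2))).shape == (2, n)

    def test_pair_order_stable(self):
        a = pair_vectors(MARKERS)
        b = pair_vectors(MARKERS)
        assert np.array_equal(a, b)

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pair_vectors(MARKERS[:2])


class TestEstimateF:
    def test_identity_when_frames_identical(self):
        lam = pair_vectors(MARKERS)
        assert np.allclose(estimate_F(lam, lam), np.eye(2), atol=1e-12)

    def test_exact_affine_recovery(self):
        F_true = np.array([[0.9, 0.05], [0.0, 1.1]])
        moved = MARKERS @ F_true.T
        F = estimate_F(pair_vectors(MARKERS), pair_vectors(moved))
        assert np.allclose(F, F_true, atol=1e-12)

    def test_noise_error_decreases_with_marker_count(self):
        F_true = np.array([[0.92, 0.03], [-0.02, 1.05]])
        rng = np.random.default_rng(11)
        errs = []
        for m in (5, 20, 80):
            trials = []
            for _ in range(30):
                markers = rng.uniform(0, 100, size=(m, 2))
                moved = markers @ F_true.T + rng.normal(0, 0.5, size=(m, 2))
                F = estimate_F(pair_vectors(markers), pair_vectors(moved))
                trials.append(np.linalg.norm(F - F_true))
            errs.append(np.mean(trials))
        assert errs[0] > errs[1] > errs[2]

    def test_collinear_markers_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_F(pair_vectors(line), pair_vectors(line * 0.9))

    def test_least_squares_optimality_against_random_candidates(self):
        rng = np.random.default_rng(4)
        lam0 = pair_vectors(MARKERS)
        lam = lam0 * 0.93 + rng.normal(0, 0.3, size=lam0.shape)
        F_hat = estimate_F(lam0, lam)
        res_hat = np.linalg.norm(F_hat @ lam0 - lam)
        for _ in range(1000):
            cand = F_hat + rng.normal(0, 0.1, size=(2, 2))
            assert np.linalg.norm(cand @ lam0 - lam) >= res_hat - 1e-9

    def test_rotation_equivariance(self):
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        F_true = np.array([[0.85, 0.0], [0.1, 1.02]])
        moved = MARKERS @ F_true.T
        F_rot = estimate_F(pair_vectors(MARKERS), pair_vectors(moved @ Q.T))
        assert np.allclose(F_rot, Q @ F_true, atol=1e-10)


class TestPolar:
    def test_identity(self):
        st_ = polar_and_stretches(np.eye(2))
        assert np.allclose(st_.R, np.eye(2)) and np.allclose(st_.U, np.eye(2))
        assert st_.lambdas == (1.0, 1.0)

    def test_pure_rotation_has_unit_stretch(self):
        th = np.pi / 6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        st_ = polar_and_stretches(R)
        assert np.allclose(st_.U, np.eye(2), atol=1e-12)
        assert np.allclose(st_.lambdas, (1.0, 1.0))

    def test_diagonal_stretch(self):
        st_ = polar_and_stretches(np.diag([0.8, 1.1]))
        assert st_.lambdas == pytest.approx((0.8, 1.1))
        assert st_.J == pytest.approx(0.88)

    def test_flip_rejected(self):
        with pytest.raises(ValueError, match="det"):
            polar_and_stretches(np.diag([-1.0, 1.0]))

    def test_invariants_on_random_spd_composed_matrices(self):
        """R orthonormal with det +1, U symmetric positive definite,
        F = R U, lambda1 <= lambda2, on 1000 random rotation-stretch
        compositions."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            A = rng.normal(0, 1, size=(2, 2))
            U = A @ A.T + np.eye(2) * 0.2  # SPD
            F = R @ U
            st_ = polar_and_stretches(F)
            assert np.allclose(st_.R.T @ st_.R, np.eye(2), atol=1e-9)
            assert np.linalg.det(st_.R) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(st_.U, st_.U.T, atol=1e-9)
            assert np.all(np.linalg.eigvalsh(st_.U) > 0)
            assert np.allclose(st_.R @ st_.U, F, atol=1e-9)
            assert st_.lambdas[0] <= st_.lambdas[1]
            assert st_.J == pytest.approx(st_.lambdas[0] * st_.lambdas[1], rel=1e-9)


class TestFSeries:
    def positions_isotropic(self, c):
        """Markers scaled about their centroid by factor c(t) per frame."""
        centroid = MARKERS.mean(axis=0)
        return np.array([centroid + (MARKERS - centroid) * ci for ci in c])

    def test_static_scene_identity(self):
        pos = np.repeat(MARKERS[None], 5, axis=0)
        for st_ in compute_F_series(pos, 0):
            assert np.allclose(st_.F, np.eye(2), atol=1e-12)

    def test_isotropic_contraction_recovers_factor(self):
        c = np.array([1.0, 0.95, 0.9, 0.85, 0.9, 1.0])
        for t, st_ in enumerate(compute_F_series(self.positions_isotropic(c), 0)):
            assert st_.lambdas[0] == pytest.approx(c[t], abs=1e-9)
            assert st_.lambdas[1] == pytest.approx(c[t], abs=1e-9)

    def test_uniaxial_program_tracks_one_stretch(self):
        centroid = MARKERS.mean(axis=0)
        cx = np.array([1.0, 0.9, 0.8, 0.9, 1.0])
        pos = np.array(
            [
                centroid + (MARKERS - centroid) * np.array([c, 1.0])
                for c in cx
            ]
        )
        for t, st_ in enumerate(compute_F_series(pos, 0)):
            assert st_.lambdas[0] == pytest.approx(min(cx[t], 1.0), abs=1e-9)
            assert st_.lambdas[1] == pytest.approx(1.0, abs=1e-9)

    def test_det_multiplicative_under_composition(self):
        c1, c2 = 0.9, 0.85
        pos = self.positions_isotropic([1.0, c1, c1 * c2])
        states = compute_F_series(pos, 0)
        J_direct = states[2].J
        J_step = (
            compute_F_series(pos[[0, 1]], 0)[1].J
            * compute_F_series(pos[[1, 2]], 0)[1].J
        )
        assert J_direct == pytest.approx(J_step, abs=1e-9)

    def test_select_frames_monotone_relaxing(self):
        c = np.linspace(0.85, 1.0, 6)  # relaxing over the movie
        ref, contracted = select_frames(self.positions_isotropic(c))
        assert ref == 5
        assert contracted == 0

    def test_select_frames_static_tiebreak(self):
        pos = np.repeat(MARKERS[None], 4, axis=0)
        assert select_frames(pos) == (0, 0)

    def test_select_frames_single_beat(self):
        c = np.array([1.0, 0.97, 0.9, 0.85, 0.9, 0.97, 1.0])
        ref, contracted = select_frames(self.positions_isotropic(c))
        assert contracted == 3


class TestShortening:
    def test_constant_series_zero(self):
        assert shortening(np.zeros(10)) == 0.0

    def test_printed_form(self):
        y = np.array([0.05, 0.0, -0.10, 0.02])
        assert shortening(y) == pytest.approx(0.15 / 1.05)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equivalence_with_length_form(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.uniform(5, 15, size=30)
        y = (L - L.mean()) / L.mean()
        assert abs(shortening(y) - (L.max() - L.min()) / L.max()) < 1e-12

    def test_identical_series_median_equals_mean_series(self):
        y = 0.1 * np.sin(np.linspace(0, 4 * np.pi, 50))
        s_med, s_avg = shortening_summary(np.tile(y, (5, 1)))
        assert s_med == pytest.approx(s_avg)
        assert s_med == pytest.approx(shortening(y))

    def test_antiphase_series_reduce_mean_shortening(self):
        t = np.linspace(0, 4 * np.pi, 100)
        a = 0.1 * np.sin(t)
        b = -0.1 * np.sin(t)
        s_med, s_avg = shortening_summary(np.stack([a, b]))
        assert s_avg < s_med

    def test_single_series_all_equal(self):
        y = 0.05 * np.sin(np.linspace(0, 2 * np.pi, 40))
        s_med, s_avg = shortening_summary(y[None])
        assert s_med == s_avg == shortening(y)

    def test_metrics_monotone_in_contraction_amplitude(self):
        """Stronger prescribed contraction gives larger s, C_iso, C_par."""
        from sarcokinetics import synthgen

        prev = None
        for p in (0.05, 0.10, 0.15):
            scene = synthgen.baseline_scene(
                seed=0, n_frames=40, peak_shortening=p, perlin_magnitude=0.0
            )
            _, gt = synthgen.generate_movie(scene)
            m = gt.metrics
            if prev is not None:
                assert m["s_median"] > prev["s_median"]
                assert m["s_avg"] > prev["s_avg"]
                assert m["C_iso"] > prev["C_iso"]
                assert m["C_parallel"] > prev["C_parallel"]
            prev = m


class TestOrientationMetrics:
    def test_aligned_vectors_oop_one(self):
        r = np.tile([np.cos(0.5), np.sin(0.5)], (50, 1))
        T, oop, v_max = structural_tensor_oop(r)
        assert oop == pytest.approx(1.0, abs=1e-12)
        assert np.trace(T) == pytest.approx(0.0, abs=1e-12)

    def test_evenly_spaced_angles_oop_zero(self):
        angles = np.deg2rad([0, 45, 90, 135])
        r = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        _, oop, _ = structural_tensor_oop(r)
        assert oop == pytest.approx(0.0, abs=1e-12)

    def test_three_to_one_mixture_gives_half(self):
        r = np.array([[1.0, 0.0]] * 3 + [[0.0, 1.0]])
        _, oop, v_max = structural_tensor_oop(r)
        assert oop == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(np.abs(v_max), [1.0, 0.0])

    def test_sign_invariance(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(0, np.pi, size=20)
        r = np.stack([np.cos(th), np.sin(th)], axis=1)
        signs = rng.choice([-1.0, 1.0], size=(20, 1))
        T1, oop1, v1 = structural_tensor_oop(r)
        T2, oop2, v2 = structural_tensor_oop(r * signs)
        assert np.allclose(T1, T2)
        assert oop1 == oop2


class TestContractionMetrics:
    def test_c_iso_identity_zero(self):
        assert c_iso(np.eye(2)) == 0.0

    def test_c_iso_ninety_percent_scaling(self):
        assert c_iso(0.9 * np.eye(2)) == pytest.approx(0.10, abs=1e-12)

    def test_c_iso_uniaxial(self):
        assert c_iso(np.diag([0.8, 1.0])) == pytest.approx(1 - np.sqrt(0.8))

    def test_c_iso_rejects_flip(self):
        with pytest.raises(ValueError):
            c_iso(np.diag([-0.9, 0.9]))

    def test_c_parallel_identity_zero(self):
        assert c_parallel(np.eye(2), np.array([1.0, 0.0])) == 0.0

    def test_c_parallel_uniaxial(self):
        F = np.diag([0.8, 0.95])
        assert c_parallel(F, np.array([1.0, 0.0])) == pytest.approx(0.2)

    def test_c_parallel_isotropic(self):
        th = 1.1
        v = np.array([np.cos(th), np.sin(th)])
        assert c_parallel(0.9 * np.eye(2), v) == pytest.approx(0.1)


class TestAnalyzeJ:
    def test_three_beat_program_detected(self):
        t = np.arange(120)
        J = 1.0 - 0.2 * np.sin(np.pi * (t % 40) / 40.0) ** 2
        summary = analyze_J(J)
        assert summary["n_peaks"] == 3
        assert summary["period"] == pytest.approx(40, abs=1)

    def test_constant_J_no_events(self):
        assert analyze_J(np.ones(50))["n_peaks"] == 0
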