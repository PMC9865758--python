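"""Projected iterative solvers: Kaczmarz variants, Landweber, SART."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomoreduce import (
    IterationControl,
    ScanGeometry,
    assemble_matrix,
    forward_project,
    golden_ratio_order,
    kaczmarz_row_update,
    operator_norm,
    run_mr_gd,
    run_mr_kaczmarz,
    run_mr_kaczmarz_basic,
    run_sart,
)
from tomoreduce.iterative import operator_norm_matvec


def _nonneg_truth(geom: ScanGeometry, rng) -> np.ndarray:
    f = np.zeros((geom.N, geom.N))
    inner = slice(2, geom.N - 2)
    f[inner, inner] = rng.uniform(0, 1, size=(geom.N - 4, geom.N - 4))
    return f


class TestGoldenOrder:
    def test_single_angle(self):
        np.testing.assert_array_equal(golden_ratio_order(1), [0])

    @given(K=st.integers(min_value=2, max_value=400))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_is_a_permutation(self, K):
        np.testing.assert_array_equal(np.sort(golden_ratio_order(K)), np.arange(K))

    def test_consecutive_visits_spread_out(self):
        K = 100
        golden = golden_ratio_order(K)[:10]
        gaps_golden = np.abs(np.diff(golden))
        gaps_golden = np.minimum(gaps_golden, K - gaps_golden)  # circular
        assert gaps_golden.min() > 1  # sequential order's gap is always 1


class TestKaczmarzStep:
    def test_single_equation_solved_in_one_unit_step(self, rng):
        a = rng.normal(size=6)
        f = rng.normal(size=6)
        target = 2.7
        f1 = kaczmarz_row_update(f, a, target, lam=1.0)
        assert float(a @ f1) == pytest.approx(target, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 1.5, 2.0, 2.5])
    def test_distance_contracts_by_one_minus_lam(self, lam, rng):
        a = rng.normal(size=8)
        f = rng.normal(size=8)
        target = 1.3
        dist = abs(float(a @ f) - target) / np.linalg.norm(a)
        f1 = kaczmarz_row_update(f, a, target, lam=lam)
        dist1 = abs(float(a @ f1) - target) / np.linalg.norm(a)
        assert dist1 == pytest.approx(abs(1 - lam) * dist, rel=1e-9)


class TestBasicKaczmarz:
    def test_consistent_system_converges(self, rng):
        g = ScanGeometry(J=6, K=8, N=6)
        truth = _nonneg_truth(g, rng)
        sino = forward_project(truth, g)
        n_rows = g.K * g.J
        ctrl = IterationControl(lam=1.0, n_iter=3000 * n_rows,
                                trace_every=3000 * n_rows)
        img, trace = run_mr_kaczmarz_basic(sino, g, ctrl)
        assert trace.residuals[-1] < 1e-6
        assert img.min() >= 0.0

    def test_all_iterates_nonnegative(self, tiny_geom, rng):
        sino = rng.normal(size=(tiny_geom.K, tiny_geom.J))
        img, _ = run_mr_kaczmarz_basic(sino, tiny_geom, IterationControl(n_iter=50))
        assert img.min() >= 0.0

    def test_out_of_range_lam(self, tiny_geom):
        sino = np.zeros((tiny_geom.K, tiny_geom.J))
        with pytest.raises(ValueError):
            run_mr_kaczmarz_basic(sino, tiny_geom, IterationControl(lam=-0.1))
        with pytest.warns(UserWarning, match="contract"):
            run_mr_kaczmarz_basic(sino, tiny_geom,
                                  IterationControl(lam=2.5, n_iter=5))


class TestImprovedKaczmarz:
    def test_single_angle_iteration_matches_definition(self, rng):
        # one outer iteration = sum of that angle's per-ray corrections
        # computed at the same (zero) estimate, then clipped
        g = ScanGeometry(J=6, K=1, delta_phi=math.pi, N=6)
        sino = rng.normal(size=(1, 6))
        lam = 0.7
        img, _ = run_mr_kaczmarz(sino, g, IterationControl(lam=lam, n_iter=1))
        A = assemble_matrix(g).toarray()
        expected = np.zeros(36)
        for j in range(6):
            a = A[j]
            expected += lam * sino[0, j] / (a @ a) * a
        np.testing.assert_allclose(img.ravel(), np.maximum(expected, 0.0),
                                   atol=1e-12)

    def test_small_step_converges_slower(self, tiny_geom, rng):
        truth = _nonneg_truth(tiny_geom, rng)
        sino = forward_project(truth, tiny_geom)
        n_iter = 3 * tiny_geom.K
        _, slow = run_mr_kaczmarz(sino, tiny_geom,
                                  IterationControl(lam=0.05, n_iter=n_iter))
        _, fast = run_mr_kaczmarz(sino, tiny_geom,
                                  IterationControl(lam=1.0, n_iter=n_iter))
        assert slow.residuals[-1] > fast.residuals[-1]

    def test_orderings_reach_the_same_limit(self, rng):
        # full-column-rank instance: the consistent solution is unique, so
        # both angle orderings must converge to the same image
        g = ScanGeometry(J=12, K=12, N=6)
        truth = _nonneg_truth(g, rng)
        sino = forward_project(truth, g)
        n_iter = 1200 * g.K
        ctrl_g = IterationControl(lam=1.0, n_iter=n_iter, ordering="golden",
                                  trace_every=n_iter)
        ctrl_s = IterationControl(lam=1.0, n_iter=n_iter, ordering="sequential",
                                  trace_every=n_iter)
        img_g, _ = run_mr_kaczmarz(sino, g, ctrl_g)
        img_s, _ = run_mr_kaczmarz(sino, g, ctrl_s)
        np.testing.assert_allclose(img_g, img_s, atol=1e-5)


class TestOperatorNorm:
    def test_identity(self):
        assert operator_norm_matvec(lambda x: x, lambda y: y, 7) == pytest.approx(1.0)

    def test_diagonal(self):
        d = np.array([3.0, 1.0])
        norm = operator_norm_matvec(lambda x: d * x, lambda y: d * y, 2)
        assert norm == pytest.approx(3.0, rel=1e-5)

    def test_matches_dense_svd(self, tiny_geom):
        dense = np.linalg.svd(assemble_matrix(tiny_geom).toarray(),
                              compute_uv=False)[0]
        assert operator_norm(tiny_geom) == pytest.approx(dense, abs=1e-5 * dense)


class TestLandweber:
    def test_zero_sinogram_stays_zero(self, tiny_geom):
        img, trace = run_mr_gd(np.zeros((tiny_geom.K, tiny_geom.J)), tiny_geom,
                               IterationControl(n_iter=5))
        assert np.all(img == 0)
        assert trace.residuals[-1] == 0.0

    def test_residual_monotone_without_projection(self, tiny_geom, rng):
        sino = rng.normal(size=(tiny_geom.K, tiny_geom.J)) + 2.0
        norm = operator_norm(tiny_geom)
        ctrl = IterationControl(lam=1.0 / norm**2, n_iter=30)
        _, trace = run_mr_gd(sino, tiny_geom, ctrl, nonneg=False)
        res = np.array(trace.residuals)
        assert np.all(np.diff(res) <= 1e-10)

    def test_step_size_bound_enforced(self, tiny_geom):
        norm = operator_norm(tiny_geom)
        with pytest.raises(ValueError, match="below"):
            run_mr_gd(np.zeros((tiny_geom.K, tiny_geom.J)), tiny_geom,
                      IterationControl(lam=2.1 / norm**2, n_iter=2))

    def test_projected_iterates_nonnegative(self, tiny_geom, rng):
        sino = rng.normal(size=(tiny_geom.K, tiny_geom.J))
        img, _ = run_mr_gd(sino, tiny_geom, IterationControl(n_iter=10))
        assert img.min() >= 0.0


class TestSart:
    def test_zero_sinogram_gives_zero_image(self, tiny_geom):
        img, _ = run_sart(np.zeros((tiny_geom.K, tiny_geom.J)), tiny_geom,
                          IterationControl(n_iter=5))
        assert np.all(img == 0)

    def test_residual_decreases_on_consistent_data(self, tiny_geom, rng):
        truth = _nonneg_truth(tiny_geom, rng)
        sino = forward_project(truth, tiny_geom)
        _, trace = run_sart(sino, tiny_geom,
                            IterationControl(lam=1.0, n_iter=10))
        res = np.array(trace.residuals)
        assert np.all(np.diff(res) < 0)

    def test_output_nonnegative(self, tiny_geom, rng):
        sino = rng.normal(size=(tiny_geom.K, tiny_geom.J))
        img, _ = run_sart(sino, tiny_geom, IterationControl(n_iter=8))
        assert img.min() >= 0.0
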