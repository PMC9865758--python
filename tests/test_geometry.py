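"""Strip geometry, forward/adjoint projection and whitening."""

import math

import numpy as np
import pytest

from tomoreduce import (
    NoiseModel,
    ScanGeometry,
    adjoint_project,
    assemble_matrix,
    forward_project,
    strip_matrix,
    strip_row,
    whiten,
)


class TestScanGeometry:
    def test_defaults_fill_in(self):
        g = ScanGeometry(J=10, K=12)
        assert g.N == 10
        assert g.delta_phi == pytest.approx(math.pi / 12)
        assert g.omega_radius == 5
        assert g.angles.shape == (12,)
        assert g.angles[3] == pytest.approx(3 * math.pi / 12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"J": 0, "K": 4},
            {"J": 4, "K": 4, "d": -1.0},
            {"J": 4, "K": 4, "delta_phi": math.pi / 16},  # < 180 deg coverage
            {"J": 4, "K": 4, "omega_radius": 5.0},
            {"J": 4, "K": 4, "n_subpixel": 0},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScanGeometry(**kwargs)

    def test_uncovered_disc_warns(self):
        with pytest.warns(UserWarning, match="sensor span"):
            ScanGeometry(J=4, K=8, N=16)


class TestStripRow:
    def test_axis_aligned_strip_is_a_pixel_column(self):
        g = ScanGeometry(J=8, K=4, N=8)
        row = strip_row(g, 0, 5)
        assert len(row.weights) == 8
        np.testing.assert_allclose(row.weights, 1.0)
        assert set(row.indices[:, 1]) == {5}
        assert row.norm_sq == pytest.approx(8.0)

    def test_partition_of_unity_at_fixed_angle(self):
        # strips at one angle tile the plane, so every pixel inside the
        # sensor span has total weight equal to its area (= 1)
        g = ScanGeometry(J=12, K=4, N=8)
        for k in range(g.K):
            totals = np.asarray(strip_matrix(g, k).sum(axis=0)).reshape(8, 8)
            np.testing.assert_allclose(totals, 1.0, atol=1e-12)

    def test_index_range_checked(self):
        g = ScanGeometry(J=8, K=4, N=8)
        with pytest.raises(IndexError):
            strip_row(g, 4, 0)
        with pytest.raises(IndexError):
            strip_row(g, 0, 8)

    def test_diagonal_strip_matches_polygon_clipping_oracle(self):
        # independent geometric oracle: exact pixel/strip intersection areas
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import box, Polygon

        g = ScanGeometry(J=6, K=4, d=1.0, delta_phi=math.pi / 4, N=4,
                         n_subpixel=16)
        k = 1  # phi = pi/4
        phi = g.angles[k]
        half = (g.N - 1) / 2
        L = 100.0
        for j in range(g.J):
            a = -g.J * g.d / 2 + j * g.d
            b = a + g.d
            c, s = math.cos(phi), math.sin(phi)
            corners = [
                (a * c - L * -s, a * s - L * c),
                (a * c + L * -s, a * s + L * c),
                (b * c + L * -s, b * s + L * c),
                (b * c - L * -s, b * s - L * c),
            ]
            strip_poly = Polygon(corners)
            got = strip_matrix(g, k).getrow(j).toarray().reshape(g.N, g.N)
            for r in range(g.N):
                for col in range(g.N):
                    x, y = col - half, half - r
                    pixel = box(x - 0.5, y - 0.5, x + 0.5, y + 0.5)
                    exact = pixel.intersection(strip_poly).area
                    # sampling tolerance ~ edge length * sample spacing
                    assert got[r, col] == pytest.approx(exact, abs=0.05)


class TestForwardAdjoint:
    def test_zero_image_projects_to_zero(self, small_geom):
        assert np.all(forward_project(np.zeros((16, 16)), small_geom) == 0)
        assert np.all(adjoint_project(np.zeros((20, 20)), small_geom) == 0)

    def test_centered_disc_gives_angle_invariant_sinogram(self):
        from tomoreduce import PhantomElement, PhantomSpec, make_phantom

        g = ScanGeometry(J=64, K=12, N=64)
        disc = make_phantom(PhantomSpec(
            kind="discs", N=64,
            elements=(PhantomElement(axes=(20.0, 20.0), value=1.0),),
        ))
        sino = forward_project(disc, g)
        # rotational symmetry up to edge discretization: the RMS row spread
        # is small although single samples on the disc's steep edge may not be
        spread = float(np.sqrt(np.mean((sino - sino[0]) ** 2)))
        assert spread < 0.03 * sino.max()

    def test_nonnegative_image_projects_nonnegative(self, small_geom, rng):
        f = rng.uniform(0, 1, size=(16, 16))
        assert forward_project(f, small_geom).min() >= 0

    def test_matrix_free_matches_assembled_matrix(self, small_geom, rng):
        A = assemble_matrix(small_geom)
        f = rng.normal(size=(16, 16))
        s = rng.normal(size=(20, 20))
        np.testing.assert_allclose(
            forward_project(f, small_geom).ravel(), A @ f.ravel(), atol=1e-10
        )
        np.testing.assert_allclose(
            adjoint_project(s, small_geom).ravel(), A.T @ s.ravel(), atol=1e-10
        )

    def test_adjoint_identity(self, small_geom, rng):
        for _ in range(5):
            f = rng.normal(size=(16, 16))
            y = rng.normal(size=(20, 20))
            lhs = float(np.sum(forward_project(f, small_geom) * y))
            rhs = float(np.sum(f * adjoint_project(y, small_geom)))
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_shape_mismatch_rejected(self, small_geom):
        with pytest.raises(ValueError):
            forward_project(np.zeros((8, 8)), small_geom)
        with pytest.raises(ValueError):
            adjoint_project(np.zeros((5, 5)), small_geom)

    def test_assemble_matrix_refuses_large_instances(self):
        g = ScanGeometry(J=100, K=100, N=100)
        with pytest.raises(ValueError, match="cap"):
            assemble_matrix(g, cap=10**6)

    def test_assemble_matrix_tiny_instance_rows(self):
        # one angle (phi=0), two unit sensors over a 2x2 image: each strip
        # covers one pixel column
        g = ScanGeometry(J=2, K=1, delta_phi=math.pi, N=2)
        A = assemble_matrix(g).toarray()
        assert A.shape == (2, 4)
        np.testing.assert_allclose(A.sum(axis=1), 2.0)
        np.testing.assert_allclose(sorted(A.ravel()), [0, 0, 0, 0, 1, 1, 1, 1])


class TestWhiten:
    def test_unit_sigma_is_identity(self, rng):
        s = rng.normal(size=(3, 4))
        out, scales = whiten(s, NoiseModel(sigma=1.0))
        np.testing.assert_array_equal(out, s)
        np.testing.assert_array_equal(scales, 1.0)

    def test_white_noise_scaling(self):
        s = np.full((2, 2), 4.0)
        out, scales = whiten(s, NoiseModel(sigma=2.0))
        np.testing.assert_allclose(out, 2.0)
        np.testing.assert_allclose(scales, 0.5)

    def test_diagonal_variances(self):
        s = np.ones((1, 3))
        out, scales = whiten(s, NoiseModel(variances=(1.0, 4.0, 9.0)))
        np.testing.assert_allclose(scales.ravel(), [1, 0.5, 1 / 3])
        np.testing.assert_allclose(out.ravel(), [1, 0.5, 1 / 3])

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            whiten(np.ones((1, 2)), NoiseModel(variances=(1.0, 0.0)))

    def test_noise_model_validation(self):
        with pytest.raises(ValueError):
            NoiseModel()
        with pytest.raises(ValueError):
            NoiseModel(sigma=-1.0)
        with pytest.raises(ValueError):
            NoiseModel(sigma=1.0, variances=(1.0,))
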