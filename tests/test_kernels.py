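import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from smash._exceptions import ValidationError
from smash.kernels import (
    KernelSpec,
    center_summaries,
    cosine_kernel,
    data_driven_grid,
    default_battery,
    gaussian_kernel,
    projection_battery,
    projection_kernel,
    transform_parameter_grid,
)


@pytest.fixture
def coords(rng):
    return rng.uniform(0, 1, (40, 2))


class TestGaussianKernel:
    def test_unit_diagonal_and_known_offdiagonal(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        H = gaussian_kernel(pts, 1.0).dense()
        assert H[0, 0] == H[1, 1] == 1.0
        np.testing.assert_allclose(H[0, 1], np.exp(-0.5))

    def test_huge_lengthscale_limit(self, coords):
        scale = 1e6 * pdist(coords).max()
        H = gaussian_kernel(coords, scale).dense()
        assert np.all(np.abs(H - 1.0) < 1e-6)

    def test_entries_monotone_in_lengthscale(self, coords):
        H1 = gaussian_kernel(coords, 0.1).dense()
        H2 = gaussian_kernel(coords, 0.3).dense()
        off = ~np.eye(len(coords), dtype=bool)
        assert np.all(H2[off] >= H1[off])

    def test_translation_and_rotation_invariance(self, coords, rng):
        H = gaussian_kernel(coords, 0.2).dense()
        Ht = gaussian_kernel(coords + np.array([3.7, -1.2]), 0.2).dense()
        np.testing.assert_allclose(Ht, H, atol=1e-10)
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Hr = gaussian_kernel(coords @ R.T, 0.2).dense()
        np.testing.assert_allclose(Hr, H, atol=1e-10)

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_kernel(np.array([[0.0, np.nan], [1.0, 2.0]]), 1.0)


class TestCosineKernel:
    def test_period_landmarks(self):
        # distances 0, p and p/2 hit cos values 1, 1 and −1
        p = 0.8
        pts = np.array([[0.0, 0.0], [p, 0.0], [p / 2, 0.0]])
        H = cosine_kernel(pts, p).dense()
        np.testing.assert_allclose(H[0, 0], 1.0)
        np.testing.assert_allclose(H[0, 1], 1.0)
        np.testing.assert_allclose(H[0, 2], -1.0)
        assert np.all(H >= -1 - 1e-12) and np.all(H <= 1 + 1e-12)


class TestProjectionKernel:
    def test_idempotent_and_trace_equals_rank(self, rng):
        pts = rng.uniform(0, 1, (50, 2))
        km = projection_kernel(pts)
        D = km.dense()
        np.testing.assert_allclose(D @ D, D, atol=1e-8)
        assert km.rank == 2
        np.testing.assert_allclose(np.trace(D), 2.0, atol=1e-8)

    def test_quadratic_form_equals_regression_r2(self, rng):
        # d = 1: yᵀDy = R²·yᵀy for the simple regression of y on centered x
        x = rng.uniform(0, 1, (30, 1))
        y = rng.standard_normal(30)
        y -= y.mean()
        km = projection_kernel(x)
        q = float(km.quad_form(y[None])[0])
        xc = x[:, 0] - x[:, 0].mean()
        beta = (xc @ y) / (xc @ xc)
        r2 = 1.0 - np.sum((y - beta * xc) ** 2) / np.sum(y**2)
        np.testing.assert_allclose(q, r2 * (y @ y), rtol=1e-10)

    def test_transform_families(self, rng):
        pts = rng.uniform(0, 1, (40, 2))
        for transform, param in [("gaussian_transform", 0.3), ("cosine_transform", 0.5)]:
            km = projection_kernel(pts, transform, param)
            D = km.dense()
            np.testing.assert_allclose(D @ D, D, atol=1e-8)

    def test_degenerate_coordinates_rejected(self):
        pts = np.zeros((10, 2))
        with pytest.raises(ValidationError):
            projection_kernel(pts)


class TestCenterSummaries:
    def test_all_ones_kernel_is_pure_mean(self):
        tc, tsc = center_summaries(np.ones((20, 20)))
        assert abs(tc) < 1e-10 and abs(tsc) < 1e-10

    def test_identity_kernel(self):
        tc, tsc = center_summaries(np.eye(17))
        np.testing.assert_allclose(tc, 16.0, atol=1e-10)
        np.testing.assert_allclose(tsc, 16.0, atol=1e-8)

    def test_matches_dense_double_centering(self, rng):
        A = rng.standard_normal((30, 30))
        H = A + A.T
        N = 30
        C = np.eye(N) - np.ones((N, N)) / N
        Ht = C @ H @ C
        tc, tsc = center_summaries(H)
        np.testing.assert_allclose(tc, np.trace(Ht), atol=1e-9)
        np.testing.assert_allclose(tsc, np.trace(Ht @ Ht), rtol=1e-9)


class TestDataDrivenGrid:
    def test_grid_spans_distance_percentiles(self, rng):
        pts = rng.uniform(0, 1, (200, 2))
        specs = data_driven_grid(pts, 10, "gaussian", subsample_cap=1000, seed=3)
        vals = np.array([s.parameter for s in specs])
        assert np.all(np.diff(vals) > 0)
        d = pdist(pts)
        lo, hi = np.percentile(d[d > 0], [1, 99])
        assert vals[0] >= lo - 1e-12 and vals[-1] <= hi + 1e-12

    def test_single_value_is_geometric_mean(self, rng):
        pts = rng.uniform(0, 1, (100, 2))
        [spec] = data_driven_grid(pts, 1, "cosine", seed=0)
        d = pdist(pts)
        lo, hi = np.percentile(d[d > 0], [1, 99])
        np.testing.assert_allclose(spec.parameter, np.sqrt(lo * hi), rtol=1e-10)

    def test_deterministic_under_subsampling(self, rng):
        pts = rng.uniform(0, 1, (2000, 2))
        a = data_driven_grid(pts, 10, "gaussian", subsample_cap=1000, seed=42)
        b = data_driven_grid(pts, 10, "gaussian", subsample_cap=1000, seed=42)
        assert [s.parameter for s in a] == [s.parameter for s in b]

    def test_coincident_spots_rejected(self):
        with pytest.raises(ValidationError):
            data_driven_grid(np.zeros((10, 2)), 10, "gaussian")


class TestBatteries:
    def test_default_battery_size_and_families(self, coords):
        bat = default_battery(coords)
        assert len(bat) == 31
        fams = [km.spec.family for km in bat]
        assert fams.count("gaussian") == 10
        assert fams.count("cosine") == 10
        assert fams.count("projection") == 11

    def test_projection_battery_transform_parameters(self, coords):
        bat = projection_battery(coords)
        params = transform_parameter_grid(coords)
        assert len(bat) == 11
        got = [km.spec.transform_parameter for km in bat[1:6]]
        np.testing.assert_allclose(got, params)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(
    shift=st.tuples(
        st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
    ),
    lengthscale=st.floats(0.05, 2.0),
)
def test_gaussian_kernel_translation_invariant(shift, lengthscale):
    """The kernel depends on coordinates only through pairwise distances."""
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 1, (15, 2))
    H = gaussian_kernel(pts, lengthscale).dense()
    Hs = gaussian_kernel(pts + np.array(shift), lengthscale).dense()
    np.testing.assert_allclose(Hs, H, atol=1e-9)


def test_kernel_spec_validation():
    with pytest.raises(ValidationError):
        KernelSpec("gaussian", -1.0)
    with pytest.raises(ValidationError):
        KernelSpec("unknown", 1.0)
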