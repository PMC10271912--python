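"""Distance, binning/J2, hulls and density mismatch."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import divdrift as dd


class TestNetDistance:
    def test_no_motion_gives_zero(self):
        P = np.random.default_rng(0).normal(size=(20, 2))
        assert dd.average_net_distance(P, P) == 0.0

    def test_pythagorean_pair(self):
        assert dd.average_net_distance([[0.0, 0.0]], [[3.0, 4.0]]) == 5.0

    def test_mean_of_two_distances(self):
        init = [[0.0, 0.0], [0.0, 0.0]]
        fin = [[1.0, 0.0], [0.0, 3.0]]
        assert dd.average_net_distance(init, fin) == 2.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dd.average_net_distance(np.zeros((3, 2)), np.zeros((4, 2)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(angle=st.floats(0, 2 * np.pi), tx=st.floats(-5, 5), ty=st.floats(-5, 5))
    def test_rigid_motion_invariance(self, angle, tx, ty):
        rng = np.random.default_rng(7)
        init = rng.normal(size=(50, 2))
        fin = rng.normal(size=(50, 2))
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        t = np.array([tx, ty])
        d0 = dd.average_net_distance(init, fin)
        d1 = dd.average_net_distance(init @ R.T + t, fin @ R.T + t)
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestRelativeDifference:
    def test_equal_distances(self):
        assert dd.signed_relative_difference(1.3, 1.3) == 0.0

    def test_arithmetic(self):
        assert dd.signed_relative_difference(1.0, 1.076) == pytest.approx(0.076)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            dd.signed_relative_difference(0.0, 1.0)


class TestBinning:
    def test_single_bin_sum_and_mean(self):
        F = np.array([[0.01, 1.0], [0.02, 2.0], [0.03, 3.0]])
        bs = dd.bin_positions(F, r=1.0)
        assert bs.m == 1
        assert bs.sums[0] == 6.0
        assert bs.means[0] == 2.0
        assert np.allclose(bs.x2_values[0], [1.0, 2.0, 3.0])

    def test_bin_larger_than_range(self):
        rng = np.random.default_rng(3)
        F = rng.uniform(0, 0.5, size=(40, 2))
        assert dd.bin_positions(F, r=10.0).m == 1

    def test_two_point_split(self):
        F = np.array([[0.05, 1.0], [0.15, 2.0]])
        bs = dd.bin_positions(F, r=0.1)
        assert bs.m == 2
        assert np.array_equal(bs.counts, [1, 1])

    def test_counts_cover_all_points(self):
        rng = np.random.default_rng(4)
        F = rng.normal(size=(500, 2))
        bs = dd.bin_positions(F, r=0.21, store_samples=False)
        assert bs.counts.sum() == 500


def _j2_bruteforce(finals, r, anchor=None, scatter_about="overall_mean"):
    """Independent two-pass oracle: explicit loops over bins."""
    finals = np.asarray(finals, dtype=float)
    x1 = finals[:, 0]
    if anchor is None:
        anchor = x1.min()
    K = len(finals)
    ids = np.floor((x1 - anchor) / r).astype(int)
    ids[ids < 0] = 0
    bins = {}
    for i, b in enumerate(ids):
        bins.setdefault(b, []).append(finals[i, 1])
    mus = {b: np.mean(v) for b, v in bins.items()}
    Ps = {b: len(v) / K for b, v in bins.items()}
    mu0 = sum(Ps[b] * mus[b] for b in bins)
    Sw = Sb = 0.0
    for b, v in bins.items():
        centre = mu0 if scatter_about == "overall_mean" else mus[b]
        Si = np.mean([(x - centre) ** 2 for x in v])
        Sw += Ps[b] * Si
        Sb += Ps[b] * (mus[b] - mu0) ** 2
    return abs(Sw + Sb) / Sw


class TestJ2:
    def test_two_bin_hand_computation(self):
        # bins {0,0} and {1,1}: P = 1/2 each, mu0 = 1/2,
        # S_i about mu0 = 1/4 in both bins -> S_w = S_b = 1/4, J2 = 2
        F = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        assert dd.j2_criterion(F, r=0.5) == pytest.approx(2.0)

    def test_identical_bin_distributions_give_unity(self):
        # equal means across bins: S_b = 0, J2 = 1
        F = np.array([[0.05, 0.0], [0.05, 1.0], [0.15, 0.0], [0.15, 1.0]])
        assert dd.j2_criterion(F, r=0.1) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_data(self):
        rng = np.random.default_rng(11)
        F = rng.normal(size=(2000, 2)) * [1.0, 0.5] + [0.0, 0.3]
        for about in ("overall_mean", "bin_mean"):
            for r in (0.11, 0.37, 0.8):
                fast = dd.j2_criterion(F, r, scatter_about=about)
                slow = _j2_bruteforce(F, r, scatter_about=about)
                assert fast == pytest.approx(slow, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        same = np.array([[0.05, 1.0], [0.15, 1.0], [0.25, 1.0]])
        with pytest.raises(ValueError, match="S_w"):
            dd.j2_criterion(same, r=0.1)
        one_bin = np.array([[0.01, 1.0], [0.02, 2.0]])
        with pytest.raises(ValueError, match="2 occupied"):
            dd.j2_criterion(one_bin, r=5.0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), r=st.floats(0.05, 1.0))
    def test_j2_at_least_one(self, seed, r):
        # J2 = |S_w + S_b| / S_w >= 1 whenever S_w > 0 and S_b >= 0
        rng = np.random.default_rng(seed)
        F = rng.normal(size=(300, 2))
        try:
            assert dd.j2_criterion(F, r) >= 1.0
        except ValueError:
            pass  # degenerate draws are allowed to be rejected


class TestSweep:
    def test_identical_sets_give_zero_errors(self):
        rng = np.random.default_rng(12)
        F = rng.normal(size=(3000, 2))
        sweep = dd.j2_error_sweep(F, F, k_max=10)
        assert np.all(sweep.errors == 0.0)
        assert sweep.mean_error == 0.0

    def test_failure_reports_offending_bin_size(self):
        F = np.array([[0.05, 1.0], [0.15, 1.0]])
        with pytest.raises(ValueError, match="r = "):
            dd.j2_error_sweep(F, F, k_max=3)

    def test_shared_edges_anchor_at_pooled_minimum(self):
        rng = np.random.default_rng(13)
        A = rng.normal(size=(2000, 2))
        B = rng.normal(size=(2000, 2)) + 0.1
        sweep = dd.j2_error_sweep(A, B, k_max=5)
        anchor = min(A[:, 0].min(), B[:, 0].min())
        expect_a = dd.j2_criterion(A, sweep.r_values[0], anchor=anchor)
        assert sweep.j2_first[0] == pytest.approx(expect_a, rel=1e-12)


def _shoelace(v):
    x, y = v[:, 0], v[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


class TestConvexHull:
    def test_square_with_interior_points(self):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        interior = np.random.default_rng(14).uniform(0.1, 0.9, size=(50, 2))
        hull = dd.convex_hull_of_finals(np.vstack([corners, interior]))
        assert len(hull) == 4
        assert set(map(tuple, hull)) == set(map(tuple, corners))
        assert _shoelace(hull) > 0  # counter-clockwise

    def test_triangle_is_its_own_hull(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        hull = dd.convex_hull_of_finals(tri)
        assert set(map(tuple, hull)) == set(map(tuple, tri))

    def test_collinear_degenerate_hull(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.5, 0.5]])
        hull = dd.convex_hull_of_finals(line)
        assert set(map(tuple, hull)) == {(0.0, 0.0), (2.0, 2.0)}

    def test_hull_area_monotone_under_subsets(self):
        rng = np.random.default_rng(15)
        P = rng.normal(size=(1000, 2))
        full = abs(_shoelace(dd.convex_hull_of_finals(P)))
        for _ in range(5):
            sub = P[rng.choice(1000, size=200, replace=False)]
            assert abs(_shoelace(dd.convex_hull_of_finals(sub))) <= full + 1e-12


class TestDensityMismatch:
    def test_self_consistency_with_sampled_field(self):
        # sampling positions from the PDE density itself must drive the
        # mismatch toward zero; < 0.1 at K = 1e5
        grid = dd.Grid(-3.0, 3.0, 60)
        u = dd.gaussian_initial_condition(grid, 1.0, 1.0)
        p = (u.u / u.u.sum()).ravel()
        rng = np.random.default_rng(16)
        cells = rng.choice(p.size, size=100_000, p=p)
        i, j = np.unravel_index(cells, u.u.shape)
        jitter = rng.uniform(-0.5, 0.5, size=(100_000, 2)) * grid.h
        finals = np.stack([grid.centers[i], grid.centers[j]], axis=1) + jitter
        assert dd.density_mismatch(finals, u) < 0.1

    def test_disjoint_supports_saturate_at_two(self):
        grid = dd.Grid(-1.0, 1.0, 20)
        u = dd.gaussian_initial_condition(grid, 1.0, 30.0)
        finals = np.full((100, 2), 50.0)  # entirely off-grid
        assert dd.density_mismatch(finals, u) == pytest.approx(2.0)

    def test_zero_mass_field_rejected(self):
        from divdrift.pde import DensityField

        grid = dd.Grid(-1.0, 1.0, 10)
        empty = DensityField(grid=grid, t=0.0, u=np.zeros((10, 10)))
        with pytest.raises(ValueError, match="mass"):
            dd.density_mismatch(np.zeros((5, 2)), empty)
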