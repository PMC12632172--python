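"""Acquisition functions, multistart minimization, diverse batch assembly."""

import numpy as np
import pytest

from phasemap import (
    AcquisitionConfig,
    alpha,
    fit_surrogate,
    make_grid,
    minimize_acquisition,
    predict,
    select_batch,
)
from phasemap.acquisition import penalty_value
from phasemap.errors import UnknownMode


@pytest.fixture(scope="module")
def cfg():
    return AcquisitionConfig()


class TestAlpha:
    @pytest.mark.parametrize(
        "mode, mu, sigma, expected",
        [
            ("hybrid", 0.5, 0.5, -0.5),     # -(0.25)/(0 + 0.5)
            ("hybrid", 1.0, 0.5, -0.25),    # -(0.25)/(0.5 + 0.5)
            ("hybrid", 0.9, 0.0, 0.0),      # zero uncertainty annihilates
            ("exploit", 0.5, 0.3, 0.0),     # on-target global minimum
            ("exploit", 0.8, 0.3, 0.3),
            ("explore", 0.2, 0.4, -0.4),
        ],
    )
    def test_formula_values(self, cfg, mode, mu, sigma, expected):
        assert alpha(mode, mu, sigma, cfg) == pytest.approx(expected)

    def test_unknown_mode_rejected(self, cfg):
        with pytest.raises(UnknownMode):
            alpha("entropy", 0.5, 0.5, cfg)
        with pytest.raises(UnknownMode):
            AcquisitionConfig(mode="entropy")

    def test_random_mode_is_seeded_uniform(self, cfg):
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        a = alpha("random", np.zeros(5), np.zeros(5), cfg, rng=rng1)
        b = alpha("random", np.zeros(5), np.zeros(5), cfg, rng=rng2)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a < 1))


class TestHybridLimits:
    def test_large_epsilon_recovers_explore(self, fitted2d):
        """As epsilon grows the hybrid argmin converges to the explore argmin."""
        grid = make_grid(fitted2d.space, 41)
        field = predict(fitted2d, grid)
        cfg_big = AcquisitionConfig(mode="hybrid", epsilon=1e6)
        hybrid_vals = alpha("hybrid", field.mu, field.sigma, cfg_big)
        explore_vals = alpha("explore", field.mu, field.sigma, cfg_big)
        assert np.array_equal(
            grid[np.argmin(hybrid_vals)], grid[np.argmin(explore_vals)]
        )

    def test_constant_sigma_recovers_exploit(self, cfg):
        mu = np.linspace(0, 1, 101)
        sigma = np.full_like(mu, 0.3)
        hybrid_vals = alpha("hybrid", mu, sigma, cfg)
        exploit_vals = alpha("exploit", mu, sigma, cfg)
        assert np.argmin(hybrid_vals) == np.argmin(exploit_vals)


class TestMinimize:
    def test_exploit_finds_boundary_crossing_1d(self, space1d):
        """Exploit minimizer lands within one grid cell of |mu - 0.5| argmin."""
        X = np.linspace(0, 100, 9)[:, None]
        y = 1.0 / (1.0 + np.exp(-(X.ravel() - 47.0) / 8.0))
        state = fit_surrogate(X, y, space1d, seed=0)
        cfg = AcquisitionConfig(mode="exploit")
        x = minimize_acquisition(state, cfg, space1d, seed=0)
        grid = make_grid(space1d, 201)
        field = predict(state, grid)
        x_grid = grid[np.argmin(np.abs(field.mu - 0.5))]
        assert abs(x[0] - x_grid[0]) <= 0.5  # one cell of the 201-point grid

    def test_explore_runs_from_lone_training_point(self, space1d):
        """Variance grows with distance: explore heads to the far boundary."""
        from phasemap import KernelState

        with pytest.warns(UserWarning):
            state = fit_surrogate(
                np.array([[40.0]]), np.array([0.3]), space1d,
                kernel_state=KernelState(amplitude=1.0, length_scales=np.array([60.0])),
                normalize_y=False,
            )
        cfg = AcquisitionConfig(mode="explore")
        x = minimize_acquisition(state, cfg, space1d, seed=0)
        assert abs(x[0] - 100.0) < 1.0

    def test_deterministic_under_seed(self, fitted2d, cfg):
        a = minimize_acquisition(fitted2d, cfg, fitted2d.space, seed=9)
        b = minimize_acquisition(fitted2d, cfg, fitted2d.space, seed=9)
        assert np.array_equal(a, b)

    def test_returned_point_in_bounds(self, fitted2d):
        for mode in ("random", "exploit", "explore", "hybrid"):
            cfg = AcquisitionConfig(mode=mode)
            x = minimize_acquisition(fitted2d, cfg, fitted2d.space, seed=4)
            assert fitted2d.space.contains(x)


class TestBatch:
    def test_batch_size_one_equals_single_minimization(self, fitted2d):
        cfg = AcquisitionConfig(mode="hybrid", batch_size=1)
        sel = select_batch(fitted2d, cfg, fitted2d.space, seed=5)
        assert sel.points.shape == (1, 2)
        assert fitted2d.space.contains(sel.points[0])

    def test_flat_surrogate_batch_spreads_out(self, space1d):
        """Gaussian bumps force spatial diversity on a flat landscape."""
        X = np.linspace(0, 100, 5)[:, None]
        y = np.full(5, 0.5)
        state = fit_surrogate(X, y, space1d, seed=0)
        cfg = AcquisitionConfig(mode="exploit", batch_size=3, penalty_width_fraction=0.1)
        sel = select_batch(state, cfg, space1d, seed=1)
        z = (sel.points - space1d.lower) / space1d.ranges
        dists = [
            np.linalg.norm(z[i] - z[j])
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        assert min(dists) > cfg.penalty_width_fraction / 2

    def test_random_batch_reproducible(self, fitted2d):
        cfg = AcquisitionConfig(mode="random", batch_size=10)
        a = select_batch(fitted2d, cfg, fitted2d.space, seed=3)
        b = select_batch(fitted2d, cfg, fitted2d.space, seed=3)
        assert np.array_equal(a.points, b.points)
        assert a.points.shape == (10, 2)

    def test_all_batch_points_in_bounds_and_distinct(self, fitted2d):
        cfg = AcquisitionConfig(mode="hybrid", batch_size=6)
        sel = select_batch(fitted2d, cfg, fitted2d.space, seed=8)
        space = fitted2d.space
        for p in sel.points:
            assert space.contains(p)
        z = (sel.points - space.lower) / space.ranges
        diff = z[:, None, :] - z[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(len(z), k=1)
        assert d[iu].min() > 1e-6

    def test_penalty_is_gaussian_bump(self):
        placed = np.array([[0.5, 0.5]])
        widths = np.array([0.1, 0.1])
        at_center = penalty_value(np.array([[0.5, 0.5]]), placed, widths, 2.0)
        one_width = penalty_value(np.array([[0.6, 0.5]]), placed, widths, 2.0)
        assert at_center[0] == pytest.approx(2.0)
        assert one_width[0] == pytest.approx(2.0 * np.exp(-0.5))
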