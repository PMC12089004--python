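"""Stationary-FPE residual evaluation and the three-stage collocation fit."""

import numpy as np
import pytest

import grnscape as g
from grnscape.residual import (
    box_mass,
    fd_stationary_residual,
    residual_objective,
    sample_collocation,
    _gamma_pack,
    _gamma_unpack,
    _gauss_pack,
    _gauss_unpack,
    _objective_and_gradient,
    _spawn_rngs,
)


@pytest.fixture(scope="module")
def switch_fpe():
    net = g.make_toy_network("switch")
    model = g.build_continuous_model(net, hill_n=2.0, alpha0=0.0)
    return g.FPEModel(model, omega=50.0)


def small_gamma_mixture(d):
    rng = np.random.default_rng(17)
    n = 2
    return g.GammaMixture(
        np.array([0.4, 0.6]),
        rng.uniform(3, 20, size=(n, d)),
        rng.uniform(2, 15, size=(n, d)),
    )


class TestStationaryResidual:
    @pytest.mark.parametrize("dim", [1, 2])
    def test_matches_pure_finite_difference_evaluation(self, dim, single_gene_fpe,
                                                       switch_fpe):
        fpe = single_gene_fpe if dim == 1 else switch_fpe
        mix = small_gamma_mixture(dim)
        rng = np.random.default_rng(5)
        for p in rng.uniform(0.2, 2.0, size=(6, dim)):
            analytic = g.stationary_residual(fpe, mix, p)
            fd = fd_stationary_residual(fpe, lambda q: float(mix.pdf(q)), p)
            assert analytic == pytest.approx(fd, rel=1e-4)

    def test_boundary_points_rejected(self, single_gene_fpe):
        mix = small_gamma_mixture(1)
        with pytest.raises(ValueError, match="strictly inside"):
            g.stationary_residual(single_gene_fpe, mix, np.array([0.0]))

    def test_linear_in_the_density(self, single_gene_fpe):
        """R of a mixture is the weight-combination of per-component residuals."""
        mix = small_gamma_mixture(1)
        pts = np.random.default_rng(2).uniform(0.1, 3, size=(50, 1))
        parts = []
        for i in range(mix.n_components):
            solo = g.GammaMixture(np.array([1.0]), mix.shapes[i:i + 1], mix.rates[i:i + 1])
            parts.append(g.stationary_residual(single_gene_fpe, solo, pts))
        combined = mix.weights[0] * parts[0] + mix.weights[1] * parts[1]
        np.testing.assert_allclose(
            g.stationary_residual(single_gene_fpe, mix, pts), combined, rtol=1e-12
        )

    def test_grid_oracle_density_is_near_stationary(self, single_gene_fpe,
                                                    single_gene_grid):
        """The interpolated brute-force density nearly solves the FPE; a
        misplaced density does not."""
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(single_gene_grid.grid[0], single_gene_grid.density)
        far = g.GammaMixture(np.array([1.0]), np.array([[1.0]]), np.array([[0.4]]))
        pts = np.linspace(0.6, 1.4, 9)
        r_oracle = [
            abs(fd_stationary_residual(single_gene_fpe, lambda q: float(spline(q[0])),
                                       np.array([x]), h=1e-4))
            for x in pts
        ]
        r_far = [
            abs(fd_stationary_residual(single_gene_fpe, lambda q: float(far.pdf(q)),
                                       np.array([x]), h=1e-4))
            for x in pts
        ]
        assert max(r_oracle) * 10 < max(r_far)


class TestCollocationNorm:
    def test_nonnegative_and_seed_reproducible(self, single_gene_fpe):
        mix = small_gamma_mixture(1)
        cfg = g.CollocationConfig(n_points=2000, p_max=5.0, seed=3)
        a = g.collocation_residual_norm(single_gene_fpe, mix, cfg)
        b = g.collocation_residual_norm(single_gene_fpe, mix, cfg)
        assert a.norm >= 0 and a == b

    def test_monte_carlo_error_shrinks_like_inverse_sqrt_n(self, single_gene_fpe):
        mix = small_gamma_mixture(1)
        spread = {}
        for n in (500, 8000):
            vals = [
                g.collocation_residual_norm(
                    single_gene_fpe, mix, g.CollocationConfig(n, 5.0, seed=s)
                ).norm
                for s in range(25)
            ]
            spread[n] = np.std(vals)
        ratio = spread[500] / spread[8000]
        assert 4 / 1.8 < ratio < 4 * 1.8  # expect ~sqrt(16) = 4

    def test_oracle_shaped_density_beats_misplaced_density(self, single_gene_fpe):
        good = g.GammaMixture(np.array([1.0]), np.array([[50.84]]), np.array([[49.99]]))
        bad = g.GammaMixture(np.array([1.0]), np.array([[1.0]]), np.array([[0.4]]))
        cfg = g.CollocationConfig(n_points=5000, p_max=5.0, seed=0)
        assert (
            g.collocation_residual_norm(single_gene_fpe, good, cfg).norm
            < g.collocation_residual_norm(single_gene_fpe, bad, cfg).norm
        )


class TestGradients:
    @pytest.mark.parametrize("kind", ["gamma", "gauss"])
    def test_analytic_gradient_matches_central_differences(self, kind, switch_fpe):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.1, 2.5, size=(300, 2))
        box = np.array([3.0, 3.0])
        if kind == "gamma":
            mix = small_gamma_mixture(2)
            pack, unpack = _gamma_pack, _gamma_unpack
        else:
            mix = g.GaussianMixture(
                np.array([0.6, 0.4]),
                np.array([[0.3, 0.7], [0.7, 0.3]]),
                np.array([[0.02, 0.03], [0.015, 0.025]]),
            )
            pack, unpack = _gauss_pack, _gauss_unpack
        _, grad = _objective_and_gradient(switch_fpe, mix, pts, kind, "abs", box)
        theta = pack(mix)
        h = 1e-6
        fd = np.empty_like(theta)
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fp = residual_objective(switch_fpe, unpack(tp, 2, 2), pts, box)
            fm = residual_objective(switch_fpe, unpack(tm, 2, 2), pts, box)
            fd[k] = (fp - fm) / (2 * h)
        np.testing.assert_allclose(grad, fd, rtol=1e-3, atol=1e-9)

    def test_box_mass_matches_direct_cdf(self):
        from scipy.stats import gamma as gamma_dist

        mix = small_gamma_mixture(2)
        box = np.array([1.5, 2.0])
        direct = sum(
            w
            * gamma_dist.cdf(box[0], a[0], scale=1 / b[0])
            * gamma_dist.cdf(box[1], a[1], scale=1 / b[1])
            for w, a, b in zip(mix.weights, mix.shapes, mix.rates)
        )
        assert box_mass(mix, box) == pytest.approx(direct, rel=1e-10)


class TestStage1:
    def test_locates_the_single_gene_attractor(self, single_gene_fpe):
        cfg = g.CollocationConfig(n_points=2000, p_max=10.0)
        proxy = g.fit_stage1_global(single_gene_fpe, 1, budget=30, seed=0, colloc=cfg)
        assert abs(proxy.means[0, 0] - 1.0) < 0.5

    def test_never_worse_than_pure_random_search(self, single_gene_fpe):
        cfg = g.CollocationConfig(n_points=2000, p_max=10.0)
        budget = 30
        proxy = g.fit_stage1_global(single_gene_fpe, 1, budget, seed=1, colloc=cfg)
        rng_pts, rng_draw = _spawn_rngs(1, 2)
        pts = sample_collocation(cfg, 1, rng_pts)
        box = cfg.box(1)
        best_random = np.inf
        draw = np.random.default_rng(99)
        for _ in range(budget):
            cand = g.GaussianMixture(
                np.array([1.0]),
                draw.uniform(0, 10.0, size=(1, 1)),
                np.exp(draw.uniform(np.log(1e-2), np.log(25.0), size=(1, 1))),
            )
            best_random = min(best_random,
                              residual_objective(single_gene_fpe, cand, pts, box))
        assert residual_objective(single_gene_fpe, proxy, pts, box) <= best_random

    def test_zero_budget_rejected(self, single_gene_fpe):
        with pytest.raises(ValueError, match="budget"):
            g.fit_stage1_global(single_gene_fpe, 1, 0, seed=0)

    def test_seeded_determinism(self, single_gene_fpe):
        cfg = g.CollocationConfig(n_points=1000, p_max=10.0)
        a = g.fit_stage1_global(single_gene_fpe, 1, 10, seed=5, colloc=cfg)
        b = g.fit_stage1_global(single_gene_fpe, 1, 10, seed=5, colloc=cfg)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.variances, b.variances)


class TestStage2:
    def test_objective_never_worse_on_validation_set(self, single_gene_fpe):
        cfg = g.CollocationConfig(n_points=2000, p_max=10.0)
        proxy = g.GaussianMixture(np.array([1.0]), np.array([[2.5]]), np.array([[0.5]]))
        refined = g.fit_stage2_gaussian_refine(single_gene_fpe, proxy, cfg,
                                               n_iter=80, lr=0.05, seed=2)
        val_pts = sample_collocation(cfg, 1, _spawn_rngs(2, 2)[0])
        box = cfg.box(1)
        assert (
            residual_objective(single_gene_fpe, refined, val_pts, box)
            <= residual_objective(single_gene_fpe, proxy, val_pts, box)
        )
        assert abs(refined.means[0, 0] - 1.0) < 0.3

    def test_zero_learning_rate_leaves_proxy_unchanged(self, single_gene_fpe):
        cfg = g.CollocationConfig(n_points=500, p_max=10.0)
        proxy = g.GaussianMixture(np.array([1.0]), np.array([[1.2]]), np.array([[0.05]]))
        out = g.fit_stage2_gaussian_refine(single_gene_fpe, proxy, cfg,
                                           n_iter=10, lr=0.0, seed=0)
        np.testing.assert_allclose(out.means, proxy.means)
        np.testing.assert_allclose(out.variances, proxy.variances)


class TestStage3:
    def test_moment_matched_initialization_is_exact(self):
        proxy = g.GaussianMixture(np.array([1.0]), np.array([[2.0]]), np.array([[1.0]]))
        init = g.gamma_init_from_proxy(proxy)
        a, b = init.shapes[0, 0], init.rates[0, 0]
        assert a == pytest.approx(1 + 2 * (1 + np.sqrt(2)), abs=1e-10)  # ~5.828
        assert (a - 1) / b == pytest.approx(2.0, abs=1e-10)
        assert a / b**2 == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_proxy_means_are_clamped(self):
        proxy = g.GaussianMixture(np.array([1.0]), np.array([[-0.5]]), np.array([[0.1]]))
        init = g.gamma_init_from_proxy(proxy, eps=1e-3)
        assert init.modes()[0, 0] == pytest.approx(1e-3, rel=1e-6)

    def test_recovers_single_gene_mode_and_density(self, single_gene_fpe,
                                                   single_gene_grid):
        cfg = g.CollocationConfig(n_points=5000, p_max=10.0)
        proxy = g.GaussianMixture(np.array([1.0]), np.array([[1.1]]), np.array([[0.05]]))
        res = g.fit_stage3_gamma_finetune(single_gene_fpe, proxy, cfg, n_iter=200,
                                          lr=0.02, seed=3)
        grid_mode = single_gene_grid.mode()[0]
        assert abs(res.mixture.modes()[0, 0] - grid_mode) < 0.1
        ax = single_gene_grid.grid[0]
        h = ax[1] - ax[0]
        l1 = np.abs(res.mixture.pdf(ax[:, None]) - single_gene_grid.density).sum() * h
        assert l1 < 0.1
        assert res.residual_trace["stage3"][-1] <= res.residual_trace["stage3"][0]


class TestEndToEnd:
    def test_fit_is_bitwise_reproducible(self, single_gene_fpe):
        cfg = g.FitConfig(
            n_components=1,
            colloc=g.CollocationConfig(n_points=1000, p_max=10.0),
            stage1_budget=10, stage2_iters=20, stage3_iters=20, seed=11,
        )
        r1 = g.fit(single_gene_fpe, cfg)
        r2 = g.fit(single_gene_fpe, cfg)
        np.testing.assert_array_equal(r1.mixture.shapes, r2.mixture.shapes)
        np.testing.assert_array_equal(r1.mixture.rates, r2.mixture.rates)
        np.testing.assert_array_equal(r1.mixture.weights, r2.mixture.weights)
        assert r1.mean_abs_residual == r2.mean_abs_residual

    def test_component_count_defaults_to_boolean_fixed_points(self):
        net = g.make_toy_network("toggle")
        fpe = g.FPEModel(g.build_continuous_model(net), omega=50.0)
        cfg = g.FitConfig(colloc=g.CollocationConfig(n_points=500, p_max=5.0),
                          stage1_budget=5, stage2_iters=5, stage3_iters=5, seed=0)
        res = g.fit(fpe, cfg, network=net)
        assert res.mixture.n_components == 2

    def test_missing_component_count_and_network_rejected(self, single_gene_fpe):
        with pytest.raises(ValueError, match="n_components"):
            g.fit(single_gene_fpe, g.FitConfig())

    def test_trace_frame_lists_all_stages(self, single_gene_fpe):
        cfg = g.FitConfig(
            n_components=1,
            colloc=g.CollocationConfig(n_points=500, p_max=10.0),
            stage1_budget=5, stage2_iters=5, stage3_iters=5, seed=0,
        )
        res = g.fit(single_gene_fpe, cfg)
        frame = res.trace_frame()
        assert set(frame["stage"]) == {"stage2", "stage3"}
        assert np.isfinite(frame["mean_abs_residual"]).all()
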