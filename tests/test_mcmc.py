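"""Gibbs sampler: bookkeeping, conjugate limits, determinism, deviance."""

import numpy as np
import pytest
from scipy import sparse, stats

from starpanel.mcmc import (
    ChainConfig,
    PosteriorDraws,
    deviance,
    gibbs_run,
    potential_scale_reduction,
    retained_count,
)
from starpanel.star_model import Block, apply_constraints, build_vcm
from starpanel.synthetic_data import (
    default_true_parameters,
    make_lattice_graph,
    simulate_panel,
)

from conftest import make_toy_spec


class TestSchedule:
    @pytest.mark.parametrize(
        "iters,burn,thin,expected",
        [(22_000, 2_000, 20, 1_000), (100, 0, 1, 100), (105, 5, 10, 10)],
    )
    def test_retained_count(self, iters, burn, thin, expected):
        assert retained_count(ChainConfig(iters, burn, thin)) == expected

    def test_burnin_must_be_smaller(self):
        with pytest.raises(ValueError, match="exceed"):
            ChainConfig(iterations=100, burn_in=100)


class TestDeviance:
    def test_constructed_cancellation(self):
        # sigma2 = 1/(2 pi) makes the log-density term vanish at zero residual
        y = np.zeros(5)
        assert deviance(y, y, 1.0 / (2 * np.pi)) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_residuals(self):
        y = np.array([1.0, -2.0, 0.5])
        eta = np.zeros(3)
        assert deviance(2 * y, eta, 1.0) > deviance(y, eta, 1.0)

    def test_matches_direct_normal_logpdf_sum(self):
        rng = np.random.default_rng(0)
        y, eta, s2 = rng.standard_normal(40), rng.standard_normal(40), 0.37
        direct = -2.0 * stats.norm.logpdf(y, eta, np.sqrt(s2)).sum()
        assert deviance(y, eta, s2) == pytest.approx(direct, rel=1e-12)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            deviance(np.zeros(3), np.zeros(3), 0.0)


class TestConjugateLimits:
    def test_intercept_only_posterior_mean_is_sample_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(3.0, 0.5, size=200)
        spec = make_toy_spec(y)
        draws = gibbs_run(spec, ChainConfig(3_000, 500, 1, seed=2))
        mc_se = draws.draws["alpha"].std() / np.sqrt(200)  # generous ESS bound
        assert abs(draws.draws["alpha"].mean() - y.mean()) < 4 * mc_se + 0.01

    def test_block_posterior_matches_closed_form_gls(self):
        """Known-variance toy: empirical block moments vs the analytic
        Gaussian posterior (flat-prior intercept + one proper-prior block)."""
        rng = np.random.default_rng(7)
        n, p = 150, 4
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)  # near-orthogonal to the intercept: fast mixing
        theta_true = np.array([1.0, -0.5, 0.25, 0.0])
        sigma2, v = 0.5, 2.0
        y = 1.5 + X @ theta_true + rng.normal(0, np.sqrt(sigma2), n)

        block = Block(
            name="theta",
            design=sparse.csr_matrix(X),
            prior_precision=np.eye(p),
            prior_rank=p,
            variance_name="tau2_theta",
        )
        spec = make_toy_spec(y, blocks=[block])
        draws = gibbs_run(
            spec,
            ChainConfig(12_000, 2_000, 5, seed=11),
            fixed_variances={"theta": v},
            fixed_sigma2_e=sigma2,
        )
        # closed form for the joint (alpha, theta) posterior
        Xt = np.hstack([np.ones((n, 1)), X])
        P = Xt.T @ Xt / sigma2 + np.diag([0.0] + [1.0 / v] * p)
        cov = np.linalg.inv(P)
        mean = cov @ (Xt.T @ y / sigma2)

        samp = np.column_stack([draws.draws["alpha"], draws.draws["theta"]])
        S = samp.shape[0]
        emp_mean = samp.mean(axis=0)
        mc_se = np.sqrt(np.diag(cov) / S)
        np.testing.assert_array_less(np.abs(emp_mean - mean), 3 * mc_se)
        emp_var = samp.var(axis=0, ddof=1)
        var_se = np.diag(cov) * np.sqrt(2.0 / (S - 1))
        np.testing.assert_array_less(np.abs(emp_var - np.diag(cov)), 4 * var_se)

    def test_fixed_error_variance_is_respected(self):
        y = np.random.default_rng(0).standard_normal(50)
        spec = make_toy_spec(y)
        draws = gibbs_run(spec, ChainConfig(200, 50, 1, seed=0), fixed_sigma2_e=0.123)
        np.testing.assert_allclose(draws.draws["sigma2_e"], 0.123)


class TestFullModelRuns:
    @pytest.fixture(scope="class")
    def short_fit(self, vcm_panel):
        graph, true, panel, _ = vcm_panel
        spec = apply_constraints(build_vcm(panel, graph))
        cfg = ChainConfig(600, 100, 5, seed=3)
        return spec, cfg, gibbs_run(spec, cfg)

    def test_draw_count_and_positive_variances(self, short_fit):
        spec, cfg, draws = short_fit
        assert draws.n_draws == retained_count(cfg)
        for name in ("tau2_beta1", "tau2_beta2", "tau2_f", "sigma2_str",
                     "sigma2_unstr", "sigma2_e"):
            assert (draws.draws[name] > 0).all()

    def test_identical_seed_bitwise_identical(self, short_fit):
        spec, cfg, draws = short_fit
        again = gibbs_run(spec, cfg)
        for name, arr in draws.draws.items():
            np.testing.assert_array_equal(arr, again.draws[name])
        np.testing.assert_array_equal(draws.deviance, again.deviance)

    def test_centering_constraints_hold_in_every_draw(self, short_fit):
        spec, _, draws = short_fit
        s = draws.draws["s"]
        for b in spec.blocks:
            if b.name != "s":
                continue
            for grp in b.groups:
                np.testing.assert_allclose(
                    s[:, list(grp)].sum(axis=1), 0.0, atol=1e-9
                )
            for i in b.fixed_zero:
                np.testing.assert_allclose(s[:, i], 0.0)
        np.testing.assert_allclose(draws.draws["u"].sum(axis=1), 0.0, atol=1e-9)

    def test_save_load_round_trip(self, short_fit, tmp_path):
        _, _, draws = short_fit
        draws.save(tmp_path / "out")
        back = PosteriorDraws.load(tmp_path / "out")
        assert back.model_kind == draws.model_kind
        np.testing.assert_allclose(back.draws["beta1"], draws.draws["beta1"])
        np.testing.assert_allclose(back.deviance, draws.deviance)
        assert back.config == draws.config

    def test_unconstrained_spec_rejected(self, vcm_panel):
        graph, _, panel, _ = vcm_panel
        spec = build_vcm(panel, graph)
        with pytest.raises(ValueError, match="apply_constraints"):
            gibbs_run(spec, ChainConfig(10, 1, 1))


class TestPermutationEquivariance:
    def test_variance_posteriors_invariant_to_county_relabeling(self):
        """Relabeling counties permutes designs but leaves the variance-
        component posteriors unchanged in distribution."""
        graph = make_lattice_graph(4, 4, seed=0)
        true = default_true_parameters(T=8, seed=5)
        panel, _ = simulate_panel(graph, true)
        spec = apply_constraints(build_vcm(panel, graph))

        perm = np.random.default_rng(0).permutation(graph.n_counties)
        ids_p = tuple(graph.county_ids[i] for i in perm)
        from starpanel.spatial_graph import AdjacencyGraph

        inv = {old: new for new, old in enumerate(perm)}
        graph_p = AdjacencyGraph(
            ids_p,
            tuple(
                frozenset(inv[j] for j in graph.neighbors[perm[i]])
                for i in range(graph.n_counties)
            ),
        )
        order = {cid: k for k, cid in enumerate(ids_p)}
        df = panel.data.copy()
        df = df.sort_values(
            "county_id", key=lambda s: s.map(order), kind="stable"
        ).reset_index(drop=True)
        from starpanel.star_model import CountyPanel

        panel_p = CountyPanel.from_dataframe(df)
        spec_p = apply_constraints(build_vcm(panel_p, graph_p))

        # exact equivariance of the conjugate-update inputs: the CAR
        # quadratic form is invariant under consistent relabeling
        from starpanel.spatial_graph import car_precision

        rng = np.random.default_rng(4)
        theta = rng.standard_normal(graph.n_counties)
        Q1 = car_precision(graph).toarray()
        Q2 = car_precision(graph_p).toarray()
        theta_p = np.empty_like(theta)
        theta_p[[inv[i] for i in range(len(theta))]] = theta
        assert theta @ Q1 @ theta == pytest.approx(theta_p @ Q2 @ theta_p)

        # distributional check on the well-identified error variance
        cfg = ChainConfig(2_000, 400, 2, seed=9)
        d1 = gibbs_run(spec, cfg)
        d2 = gibbs_run(spec_p, cfg)
        m1, m2 = d1.draws["sigma2_e"].mean(), d2.draws["sigma2_e"].mean()
        assert m2 == pytest.approx(m1, rel=0.15)


class TestDiagnosticsPlumbing:
    def test_split_rhat_near_one_for_iid_chains(self):
        rng = np.random.default_rng(0)
        chains = [rng.standard_normal(500) for _ in range(3)]
        assert potential_scale_reduction(chains) == pytest.approx(1.0, abs=0.05)

    def test_split_rhat_large_for_divergent_chains(self):
        rng = np.random.default_rng(1)
        chains = [rng.standard_normal(500), 10 + rng.standard_normal(500)]
        assert potential_scale_reduction(chains) > 2.0
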