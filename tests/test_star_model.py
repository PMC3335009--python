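"""Model assembly: outcome transform, designs, constraints, identifiability."""

import numpy as np
import pandas as pd
import pytest

from starpanel.star_model import (
    CountyPanel,
    ModelConfig,
    apply_constraints,
    build_rem,
    build_vcm,
    transform_outcome,
)
from starpanel.synthetic_data import make_lattice_graph


def _tiny_panel(graph, T=6, seed=0):
    rng = np.random.default_rng(seed)
    C = graph.n_counties
    years = np.arange(1988, 1988 + T)
    df = pd.DataFrame(
        {
            "county_id": np.repeat(graph.county_ids, T),
            "year": np.tile(years, C),
            "rate_per_100k": rng.uniform(50, 300, C * T),
            "pcp_per_100k": rng.uniform(20, 120, C * T),
            "deprivation_index": np.repeat(rng.standard_normal(C), T),
        }
    )
    return CountyPanel.from_dataframe(df)


@pytest.fixture
def small_graph():
    return make_lattice_graph(3, 4, n_components=2, seed=0)


@pytest.fixture
def small_panel(small_graph):
    return _tiny_panel(small_graph)


class TestTransformOutcome:
    def test_rate_100k_zero_log(self, small_panel):
        df = small_panel.data.copy()
        df["rate_per_100k"] = 100_000.0
        p = CountyPanel.from_dataframe(df)
        y = transform_outcome(p, offset=1e-9)
        np.testing.assert_allclose(y, 0.0, atol=1e-10)

    def test_zero_rate_with_offset(self, small_panel):
        df = small_panel.data.copy()
        df["rate_per_100k"] = 0.0
        p = CountyPanel.from_dataframe(df)
        y = transform_outcome(p, offset=0.5)
        np.testing.assert_allclose(y, np.log(0.5 / 100_000.0))

    def test_monotone_in_rate(self, small_panel):
        y = transform_outcome(small_panel)
        rates = small_panel.column("rate_per_100k")
        order = np.argsort(rates)
        assert (np.diff(y[order]) > 0).all()

    def test_nonpositive_offset_rejected(self, small_panel):
        with pytest.raises(ValueError, match="offset"):
            transform_outcome(small_panel, offset=0.0)


class TestPanelValidation:
    def test_incomplete_panel_rejected(self, small_panel):
        with pytest.raises(ValueError, match="complete"):
            CountyPanel.from_dataframe(small_panel.data.iloc[:-1])

    def test_negative_rate_rejected(self, small_panel):
        df = small_panel.data.copy()
        df.loc[0, "rate_per_100k"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            CountyPanel.from_dataframe(df)

    def test_county_order_is_first_appearance(self, small_graph, small_panel):
        assert small_panel.county_ids == small_graph.county_ids


class TestDesigns:
    def test_vcm_eta_matches_direct_formula(self, small_graph, small_panel):
        """Oracle equivalence: sparse-design eta == term-by-term evaluation."""
        cfg = ModelConfig()
        spec = build_vcm(small_panel, small_graph, cfg)
        T, C = small_panel.n_years, small_panel.n_counties
        rng = np.random.default_rng(3)
        params = {
            "alpha": 0.7,
            "beta1": rng.standard_normal(T),
            "beta2": rng.standard_normal(T),
            "f": rng.standard_normal(spec.block("f").dim),
            "s": rng.standard_normal(C),
            "u": rng.standard_normal(C),
        }
        eta = spec.linear_predictor(params)
        from starpanel.model_components import bspline_basis

        ps = bspline_basis(T, cfg.spline_degree, cfg.spline_inner_knots)
        c_idx, t_idx = small_panel.indices()
        x1 = small_panel.column("pcp_per_100k") / cfg.x1_scale
        x2 = small_panel.column("deprivation_index")
        direct = np.array(
            [
                params["alpha"]
                + x1[i] * params["beta1"][t_idx[i]]
                + x2[i] * params["beta2"][t_idx[i]]
                + ps.basis[t_idx[i]] @ params["f"]
                + params["s"][c_idx[i]]
                + params["u"][c_idx[i]]
                for i in range(spec.n_obs)
            ]
        )
        np.testing.assert_allclose(eta, direct, rtol=1e-12)

    def test_rem_eta_matches_direct_formula(self, small_graph, small_panel):
        cfg = ModelConfig()
        spec = build_rem(small_panel, small_graph, cfg)
        C = small_panel.n_counties
        rng = np.random.default_rng(4)
        params = {
            "alpha": -6.0,
            "b1": rng.standard_normal(C),
            "b2": rng.standard_normal(C),
            "f": np.zeros(spec.block("f").dim),
            "s": np.zeros(C),
            "u": np.zeros(C),
        }
        eta = spec.linear_predictor(params)
        c_idx, _ = small_panel.indices()
        x1 = small_panel.column("pcp_per_100k") / cfg.x1_scale
        x2 = small_panel.column("deprivation_index")
        direct = (
            params["alpha"] + x1 * params["b1"][c_idx] + x2 * params["b2"][c_idx]
        )
        np.testing.assert_allclose(eta, direct, rtol=1e-12)

    def test_vcm_beta_design_one_nonzero_per_row(self, small_graph, small_panel):
        spec = build_vcm(small_panel, small_graph)
        X = spec.block("beta1").design
        assert X.shape[1] == small_panel.n_years  # 1 x T temporal effect vector
        assert (np.diff(X.indptr) == 1).all()
        _, t_idx = small_panel.indices()
        x1 = small_panel.column("pcp_per_100k") / 1000.0
        np.testing.assert_allclose(X.data, x1)
        np.testing.assert_array_equal(X.indices, t_idx)

    def test_rem_slope_design_one_nonzero_per_row(self, small_graph, small_panel):
        spec = build_rem(small_panel, small_graph)
        X = spec.block("b1").design
        assert X.shape[1] == small_panel.n_counties
        assert (np.diff(X.indptr) == 1).all()
        c_idx, _ = small_panel.indices()
        np.testing.assert_array_equal(X.indices, c_idx)

    def test_all_zero_terms_reduce_to_intercept(self, small_graph, small_panel):
        spec = build_vcm(small_panel, small_graph)
        params = {b.name: np.zeros(b.dim) for b in spec.blocks}
        params["alpha"] = 1.23
        np.testing.assert_allclose(
            spec.linear_predictor(params), 1.23, atol=1e-14
        )

    def test_reduced_rem_drops_blocks(self, small_graph, small_panel):
        spec = build_rem(small_panel, small_graph, drop_b1=True, drop_b2=True)
        assert {b.name for b in spec.blocks} == {"f", "s", "u"}
        assert spec.kind == "REM-reduced(b1,b2)"

    def test_county_mismatch_rejected(self, small_panel):
        other = make_lattice_graph(2, 2, seed=0)
        with pytest.raises(ValueError, match="count"):
            build_vcm(small_panel, other)


class TestConstraints:
    def test_shift_aliasing_between_f_and_intercept(self, small_graph, small_panel):
        spec = build_vcm(small_panel, small_graph)
        rng = np.random.default_rng(5)
        params = {b.name: rng.standard_normal(b.dim) for b in spec.blocks}
        params["alpha"] = 0.4
        eta1 = spec.linear_predictor(params)
        shifted = dict(params)
        shifted["f"] = params["f"] + 0.9  # partition of unity: fitted f shifts by 0.9
        shifted["alpha"] = params["alpha"] - 0.9
        np.testing.assert_allclose(eta1, spec.linear_predictor(shifted), atol=1e-10)

    def test_constraint_counts_per_component(self, small_graph, small_panel):
        spec = apply_constraints(build_vcm(small_panel, small_graph))
        s = spec.block("s")
        n_comp_constraints = s.constraint_matrix().shape[0]
        from starpanel.spatial_graph import connected_components

        comps = connected_components(small_graph)
        non_island = [c for c in comps if len(c) > 1]
        islands = [c for c in comps if len(c) == 1]
        assert n_comp_constraints == len(non_island) + len(islands)
        assert spec.block("u").constraint_matrix().shape[0] == 1
        assert spec.block("f").constraint_matrix().shape[0] == 1

    def test_stacked_design_full_rank_after_constraints(self, small_graph, small_panel):
        """With the structured/unstructured county blocks merged (they share
        the indicator design and are separated by their priors, not the
        likelihood), the constrained design has full column rank.  Both
        covariates must vary over time for this: a time-constant x2 would
        alias the level of beta2 with the county effects."""
        rng = np.random.default_rng(8)
        df = small_panel.data.copy()
        df["deprivation_index"] = rng.standard_normal(len(df))
        panel = CountyPanel.from_dataframe(df)
        cfg = ModelConfig(spline_inner_knots=3)  # keep spline dim <= T
        spec = apply_constraints(build_vcm(panel, small_graph, cfg))
        cols = [np.ones((spec.n_obs, 1))]
        for b in spec.blocks:
            if b.name == "u":
                continue  # same design as s; only s+u is likelihood-identified
            X = b.design.toarray()
            A = b.constraint_matrix()
            if b.name == "s":
                # merged county effect: one global sum-to-zero constraint
                A = np.ones((1, b.dim))
            if A.shape[0]:
                _, _, vt = np.linalg.svd(A)
                X = X @ vt[np.linalg.matrix_rank(A):].T
            cols.append(X)
        M = np.hstack(cols)
        assert np.linalg.matrix_rank(M) == M.shape[1]

    def test_unconstrained_design_is_rank_deficient(self, small_graph, small_panel):
        cfg = ModelConfig(spline_inner_knots=3)
        spec = build_vcm(small_panel, small_graph, cfg)
        X = spec.stacked_design(constrained=False)
        assert np.linalg.matrix_rank(X) < X.shape[1]

    def test_apply_constraints_records_metadata(self, small_graph, small_panel):
        spec = apply_constraints(build_vcm(small_panel, small_graph))
        assert spec.constraints_applied
        assert any("s:" in line for line in spec.metadata["constraints"])
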