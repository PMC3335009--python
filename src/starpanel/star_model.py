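"""Assembly of the structured additive regression models for county panels.

Two model kinds share a common backbone.  For a complete county-year panel
of standardized rates (counties c = 1..C, years t = 1..T) with two
county-level covariates x1 (primary-care-physician availability per
100,000, rescaled) and x2 (socioeconomic deprivation score), the response
is the log-transformed rate and the linear predictor is

* varying-coefficient model (VCM)::

      eta_ct = alpha + x1_ct * beta1_t + x2_ct * beta2_t + f(t) + s_c + u_c

  where beta1, beta2 are T-vectors of time-varying effects under RW2
  smoothness priors — at T = 21 these are temporal effect vectors of
  dimension 1 x 21;

* random-effects model (REM)::

      eta_ct = alpha + x1_ct * b1_c + x2_ct * b2_c + f(t) + s_c + u_c

  where b1, b2 are county-specific random slopes under exchangeable normal
  priors, read as the log relative risk per covariate increment in county
  c.  Reduced REMs drop b1, b2, or both.

Shared blocks: f(t) is a P-spline time smoother, s_c a CAR-structured
spatial effect, u_c an exchangeable unstructured effect.  Every variance
component gets an inverse-gamma (0.001, 0.001) hyperprior; the intercept is
flat.  Identifiability is restored by sum-to-zero constraints (f over time,
u globally, s within each connected graph component; island s fixed at 0),
enforced by centering during sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .model_components import bspline_basis, exchangeable_precision, rw2_precision
from .spatial_graph import AdjacencyGraph, car_precision, connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "CountyPanel",
    "ModelConfig",
    "Block",
    "ModelSpec",
    "transform_outcome",
    "build_vcm",
    "build_rem",
    "apply_constraints",
]

PANEL_COLUMNS = ["county_id", "year", "rate_per_100k", "pcp_per_100k", "deprivation_index"]


@dataclass(frozen=True)
class CountyPanel:
    """Complete C x T table of outcome rates and the two covariates.

    ``data`` holds one row per (county, year) with columns
    ``county_id, year, rate_per_100k, pcp_per_100k, deprivation_index``
    (an optional ``indicator`` column names the outcome).  Counties keep
    their first-appearance order; years are sorted ascending.
    """

    data: pd.DataFrame
    county_ids: tuple[str, ...]
    years: tuple[int, ...]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountyPanel":
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        df = df.copy()
        df["county_id"] = df["county_id"].astype(str)
        df["year"] = df["year"].astype(int)
        county_ids = tuple(dict.fromkeys(df["county_id"]))
        years = tuple(int(y) for y in sorted(df["year"].unique()))
        C, T = len(county_ids), len(years)
        if len(df) != C * T:
            raise ValueError(
                f"panel is not complete: {len(df)} rows for {C} counties x "
                f"{T} years"
            )
        if df.duplicated(["county_id", "year"]).any():
            raise ValueError("panel has duplicate (county, year) rows")
        if (df["rate_per_100k"] < 0).any():
            bad = df.loc[df["rate_per_100k"] < 0].index[0]
            raise ValueError(f"negative outcome rate at row {bad}")
        for col in ("rate_per_100k", "pcp_per_100k", "deprivation_index"):
            if not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite values in column {col!r}")
        order = {cid: i for i, cid in enumerate(county_ids)}
        df = df.sort_values(
            ["county_id", "year"],
            key=lambda s: s.map(order) if s.name == "county_id" else s,
            kind="stable",
        ).reset_index(drop=True)
        return cls(data=df, county_ids=county_ids, years=years)

    @classmethod
    def from_csv(cls, path) -> "CountyPanel":
        return cls.from_dataframe(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row-aligned (county index, year index) arrays."""
        cmap = {cid: i for i, cid in enumerate(self.county_ids)}
        tmap = {yr: i for i, yr in enumerate(self.years)}
        c_idx = self.data["county_id"].map(cmap).to_numpy()
        t_idx = self.data["year"].map(tmap).to_numpy()
        return c_idx, t_idx

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class ModelConfig:
    """Run-level settings recorded in every fit's metadata.

    ``offset`` is the small positive rate added before the log transform so
    zero county-year rates stay finite; ``x1_scale`` divides the raw PCP
    availability (per 100,000) so effect sizes land on an interpretable
    log-relative-risk scale; spline settings control the time smoother.
    """

    offset: float = 0.5
    x1_scale: float = 1000.0
    spline_degree: int = 3
    spline_inner_knots: int = 18
    hyper_a: float = 0.001
    hyper_b: float = 0.001


@dataclass(frozen=True)
class Block:
    """One Gaussian coefficient block of the additive predictor.

    ``design`` maps the block's coefficients into observation space;
    ``prior_precision`` is the unscaled penalty K with rank ``prior_rank``
    (the inverse-gamma shape update uses the rank, not the dimension,
    because RW2 and CAR penalties are partially improper).  ``centering``
    names the identifiability treatment applied after each draw:
    ``none``, ``global`` (subtract coefficient mean), ``components``
    (subtract per-group means, fix ``fixed_zero`` entries at 0), or
    ``fitted`` (subtract the mean fitted value from all coefficients —
    valid for partition-of-unity bases).
    """

    name: str
    design: sparse.csr_matrix = field(repr=False)
    prior_precision: np.ndarray = field(repr=False)
    prior_rank: int
    variance_name: str
    centering: str = "none"
    groups: tuple[tuple[int, ...], ...] = ()
    fixed_zero: tuple[int, ...] = ()

    @property
    def dim(self) -> int:
        return self.design.shape[1]

    def constraint_matrix(self) -> np.ndarray:
        """Rows A such that the constrained block satisfies A @ theta = 0."""
        rows: list[np.ndarray] = []
        p = self.dim
        if self.centering == "global":
            rows.append(np.ones(p))
        elif self.centering == "components":
            for grp in self.groups:
                ind = np.zeros(p)
                ind[list(grp)] = 1.0
                rows.append(ind)
            for i in self.fixed_zero:
                e = np.zeros(p)
                e[i] = 1.0
                rows.append(e)
        elif self.centering == "fitted":
            # sum of fitted values over the design rows of one full sweep of
            # the index; column sums of the basis give the same null space
            rows.append(np.asarray(self.design.sum(axis=0)).ravel())
        return np.array(rows) if rows else np.empty((0, p))


@dataclass(frozen=True)
class ModelSpec:
    """Sampler-ready model: response, blocks, hyperpriors, metadata."""

    kind: str
    y: np.ndarray = field(repr=False)
    blocks: tuple[Block, ...]
    hyper_a: float
    hyper_b: float
    county_ids: tuple[str, ...]
    years: tuple[int, ...]
    constraints_applied: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def variance_names(self) -> list[str]:
        return [b.variance_name for b in self.blocks]

    def linear_predictor(self, params: dict[str, np.ndarray]) -> np.ndarray:
        """eta = alpha + sum_j X_j theta_j for given parameter values."""
        eta = np.full(self.n_obs, float(params.get("alpha", 0.0)))
        for b in self.blocks:
            theta = np.asarray(params[b.name], dtype=float)
            if theta.shape != (b.dim,):
                raise ValueError(
                    f"block {b.name!r} expects shape ({b.dim},), got {theta.shape}"
                )
            eta += b.design @ theta
        return eta

    def stacked_design(self, constrained: bool = True) -> np.ndarray:
        """Dense [1 | X_1 N_1 | X_2 N_2 | ...] design for rank checks.

        With ``constrained=True`` each block's design is post-multiplied by
        an orthonormal basis N_j of its constraint null space.
        """
        cols = [np.ones((self.n_obs, 1))]
        for b in self.blocks:
            X = b.design.toarray()
            if constrained:
                A = b.constraint_matrix()
                if A.shape[0]:
                    _, _, vt = np.linalg.svd(A)
                    N = vt[np.linalg.matrix_rank(A):].T
                    X = X @ N
            cols.append(X)
        return np.hstack(cols)


def transform_outcome(panel: CountyPanel, offset: float = 0.5) -> np.ndarray:
    """Per-observation response y_ct = log((rate_ct + offset) / 100,000)."""
    if offset <= 0:
        raise ValueError(f"offset must be positive, got {offset}")
    rate = panel.column("rate_per_100k")
    if (rate < 0).any():
        raise ValueError("negative rates in panel")
    return np.log((rate + offset) / 100_000.0)


def _check_counties(panel: CountyPanel, graph: AdjacencyGraph) -> None:
    if tuple(panel.county_ids) != tuple(graph.county_ids):
        p, g = set(panel.county_ids), set(graph.county_ids)
        if p != g:
            raise ValueError(
                f"county sets differ: {sorted(p - g)[:5]} only in panel, "
                f"{sorted(g - p)[:5]} only in graph"
            )
        raise ValueError("panel and graph counties are ordered differently")


def _varying_coefficient_design(
    x: np.ndarray, idx: np.ndarray, p: int
) -> sparse.csr_matrix:
    """n x p design with x[i] in column idx[i] of row i (one nonzero/row)."""
    n = x.shape[0]
    return sparse.csr_matrix((x, (np.arange(n), idx)), shape=(n, p))


def _shared_blocks(
    panel: CountyPanel, graph: AdjacencyGraph, config: ModelConfig
) -> list[Block]:
    c_idx, t_idx = panel.indices()
    C, T = panel.n_counties, panel.n_years
    n = C * T

    ps = bspline_basis(T, config.spline_degree, config.spline_inner_knots)
    f_design = sparse.csr_matrix(ps.basis[t_idx, :])
    f_block = Block(
        name="f",
        design=f_design,
        prior_precision=ps.penalty,
        prior_rank=ps.n_coef - 2,
        variance_name="tau2_f",
        centering="fitted",
    )

    comps = connected_components(graph)
    islands = tuple(graph.islands)
    non_island_groups = tuple(
        tuple(comp) for comp in comps if len(comp) > 1
    )
    ones = np.ones(n)
    ind = _varying_coefficient_design(ones, c_idx, C)
    Q = car_precision(graph).toarray()
    s_block = Block(
        name="s",
        design=ind,
        prior_precision=Q,
        prior_rank=C - len(comps),
        variance_name="sigma2_str",
        centering="components",
        groups=non_island_groups,
        fixed_zero=islands,
    )
    u_block = Block(
        name="u",
        design=ind.copy(),
        prior_precision=exchangeable_precision(C),
        prior_rank=C,
        variance_name="sigma2_unstr",
        centering="global",
    )
    return [f_block, s_block, u_block]


def _scaled_covariates(
    panel: CountyPanel, config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    x1 = panel.column("pcp_per_100k") / config.x1_scale
    x2 = panel.column("deprivation_index")
    return x1, x2


def build_vcm(
    panel: CountyPanel, graph: AdjacencyGraph, config: ModelConfig | None = None
) -> ModelSpec:
    """Assemble the varying-coefficient model for a panel and its graph."""
    config = config or ModelConfig()
    _check_counties(panel, graph)
    x1, x2 = _scaled_covariates(panel, config)
    _, t_idx = panel.indices()
    T = panel.n_years
    K = rw2_precision(T)
    blocks = [
        Block(
            name="beta1",
            design=_varying_coefficient_design(x1, t_idx, T),
            prior_precision=K,
            prior_rank=T - 2,
            variance_name="tau2_beta1",
        ),
        Block(
            name="beta2",
            design=_varying_coefficient_design(x2, t_idx, T),
            prior_precision=K.copy(),
            prior_rank=T - 2,
            variance_name="tau2_beta2",
        ),
    ]
    blocks += _shared_blocks(panel, graph, config)
    return ModelSpec(
        kind="VCM",
        y=transform_outcome(panel, config.offset),
        blocks=tuple(blocks),
        hyper_a=config.hyper_a,
        hyper_b=config.hyper_b,
        county_ids=panel.county_ids,
        years=panel.years,
        metadata={
            "offset": config.offset,
            "x1_scale": config.x1_scale,
            "spline_degree": config.spline_degree,
            "spline_inner_knots": config.spline_inner_knots,
        },
    )


def build_rem(
    panel: CountyPanel,
    graph: AdjacencyGraph,
    config: ModelConfig | None = None,
    drop_b1: bool = False,
    drop_b2: bool = False,
) -> ModelSpec:
    """Assemble the random-effects model; drop flags give the reduced REMs."""
    config = config or ModelConfig()
    _check_counties(panel, graph)
    x1, x2 = _scaled_covariates(panel, config)
    c_idx, _ = panel.indices()
    C = panel.n_counties
    blocks: list[Block] = []
    if not drop_b1:
        blocks.append(
            Block(
                name="b1",
                design=_varying_coefficient_design(x1, c_idx, C),
                prior_precision=exchangeable_precision(C),
                prior_rank=C,
                variance_name="tau2_b1",
            )
        )
    if not drop_b2:
        blocks.append(
            Block(
                name="b2",
                design=_varying_coefficient_design(x2, c_idx, C),
                prior_precision=exchangeable_precision(C),
                prior_rank=C,
                variance_name="tau2_b2",
            )
        )
    blocks += _shared_blocks(panel, graph, config)
    kind = "REM"
    if drop_b1 or drop_b2:
        dropped = [n for n, d in (("b1", drop_b1), ("b2", drop_b2)) if d]
        kind = f"REM-reduced({','.join(dropped)})"
    return ModelSpec(
        kind=kind,
        y=transform_outcome(panel, config.offset),
        blocks=tuple(blocks),
        hyper_a=config.hyper_a,
        hyper_b=config.hyper_b,
        county_ids=panel.county_ids,
        years=panel.years,
        metadata={
            "offset": config.offset,
            "x1_scale": config.x1_scale,
            "spline_degree": config.spline_degree,
            "spline_inner_knots": config.spline_inner_knots,
            "drop_b1": drop_b1,
            "drop_b2": drop_b2,
        },
    )


def apply_constraints(spec: ModelSpec) -> ModelSpec:
    """Activate the sum-to-zero constraints and log what they pin down.

    f is centered over time (the intercept absorbs its level), u over all
    counties, s within every connected component; island s-effects are
    fixed at 0.  beta/b blocks need no constraint: they multiply
    non-constant covariates.
    """
    lines = []
    for b in spec.blocks:
        k = b.constraint_matrix().shape[0]
        if k:
            lines.append(f"{b.name}: {k} constraint(s) [{b.centering}]")
    for line in lines:
        logger.info("constraint %s", line)
    meta = dict(spec.metadata)
    meta["constraints"] = lines
    return replace(spec, constraints_applied=True, metadata=meta)
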