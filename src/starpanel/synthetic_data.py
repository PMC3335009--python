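"""Synthetic county panels, graphs, census tables and stratified counts.

Generators for every input the pipeline consumes, drawn forward from the
same generative models the samplers fit, with known ("true") parameters —
so every stage is testable end to end without external data.  The default
scenario mirrors the study setting the package targets: about 200 counties
spread over 9 mutually disconnected registry areas (islands included), 21
yearly observations per county, a primary-care availability covariate
(log-normal, median near 60 per 100,000) and a time-stable standardized
deprivation score with near-zero mutual correlation, log-rate outcomes
with CAR-structured spatial heterogeneity dominating exchangeable county
noise, a smooth common time trend, and time-varying covariate effects
declining over the study period.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial_graph import AdjacencyGraph, car_precision, connected_components
from .standardization import default_strata
from .star_model import CountyPanel

__all__ = [
    "TrueParameters",
    "default_true_parameters",
    "make_lattice_graph",
    "simulate_spatial_field",
    "simulate_covariates",
    "simulate_panel",
    "simulate_census",
    "simulate_stratified_counts",
]


@dataclass(frozen=True)
class TrueParameters:
    """Ground truth for the generative side of the panel models.

    ``beta1``/``beta2`` are the time-varying effects (VCM scenarios);
    ``tau2_b1``/``tau2_b2`` the random-slope variances (REM scenarios);
    ``f`` the common time trend (centered); variances are on the log-rate
    scale.  ``alpha`` anchors the overall level: exp(alpha) x 100,000 is
    the baseline rate per 100,000.
    """

    alpha: float
    beta1: np.ndarray
    beta2: np.ndarray
    f: np.ndarray
    sigma2_str: float
    sigma2_unstr: float
    sigma2_e: float
    tau2_b1: float = 0.13
    tau2_b2: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        T = len(self.beta1)
        if not (len(self.beta2) == len(self.f) == T):
            raise ValueError("beta1, beta2 and f must share length T")
        for name in ("sigma2_str", "sigma2_unstr", "sigma2_e", "tau2_b1", "tau2_b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_years(self) -> int:
        return len(self.beta1)


def default_true_parameters(T: int = 21, seed: int = 0) -> TrueParameters:
    """Study-condition truth: declining effects, dominant structured variance.

    The availability effect declines linearly from 3.72 to 2.45 (per scaled
    covariate unit) and the deprivation effect rises from -0.25 to 0 over
    the T years; f(t) is a gentle centered sinusoid; spatial variances
    (2.26 structured, 0.56 unstructured) favour geographic clustering; the
    residual log-rate variance is 0.05.
    """
    t = np.linspace(0.0, 1.0, T)
    f = 0.1 * np.sin(2.0 * np.pi * t)
    f = f - f.mean()
    return TrueParameters(
        alpha=np.log(150.0 / 100_000.0),
        beta1=3.72 + (2.45 - 3.72) * t,
        beta2=-0.25 + 0.25 * t,
        f=f,
        sigma2_str=2.26,
        sigma2_unstr=0.56,
        sigma2_e=0.05,
        seed=seed,
    )


def make_lattice_graph(
    rows: int,
    cols: int,
    n_components: int = 1,
    island_fraction: float = 0.0,
    seed: int = 0,
) -> AdjacencyGraph:
    """Rook-adjacency lattice split into disconnected blocks, with islands.

    The ``rows x cols`` lattice is cut into ``n_components`` contiguous
    column bands (edges across band boundaries removed); then a random
    ``island_fraction`` of counties is stripped of all edges.  County ids
    are ``r{row}c{col}`` in row-major order.
    """
    n = rows * cols
    if n < 1:
        raise ValueError("lattice must have at least one cell")
    if not 1 <= n_components <= cols:
        raise ValueError(
            f"cannot split {cols} columns into {n_components} components"
        )
    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    band = np.array_split(np.arange(cols), n_components)
    band_of = np.empty(cols, dtype=int)
    for k, cols_k in enumerate(band):
        if len(cols_k) == 0:
            raise ValueError("component split leaves an empty band")
        band_of[cols_k] = k
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols and band_of[c] == band_of[c + 1]:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    rng = np.random.default_rng(seed)
    n_islands = int(round(island_fraction * n))
    island_set = set(rng.choice(n, size=n_islands, replace=False)) if n_islands else set()
    edges = [(a, b) for a, b in edges if a not in island_set and b not in island_set]
    return AdjacencyGraph.from_edges(ids, edges)


def simulate_spatial_field(
    graph: AdjacencyGraph,
    var_str: float,
    var_unstr: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (s, u): a CAR-structured field and exchangeable county noise.

    s is sampled from the intrinsic CAR prior constrained to sum to zero
    within every connected component (islands get s = 0), via the spectral
    decomposition of the precision restricted to its row space; u is
    i.i.d. normal with variance ``var_unstr``.
    """
    rng = np.random.default_rng(seed)
    C = graph.n_counties
    s = np.zeros(C)
    if var_str > 0:
        Q = car_precision(graph).toarray()
        for comp in connected_components(graph):
            if len(comp) < 2:
                continue
            idx = np.array(comp)
            evals, evecs = np.linalg.eigh(Q[np.ix_(idx, idx)])
            pos = evals > 1e-10 * evals.max()
            z = rng.standard_normal(pos.sum())
            s[idx] = evecs[:, pos] @ (z * np.sqrt(var_str / evals[pos]))
            s[idx] -= s[idx].mean()  # exact zero sum within the component
    u = rng.normal(0.0, np.sqrt(var_unstr), size=C) if var_unstr > 0 else np.zeros(C)
    return s, u


def simulate_covariates(
    graph: AdjacencyGraph,
    T: int,
    seed: int = 0,
    x1_median: float = 60.0,
    x1_log_sd: float = 0.4,
    x1_year_log_sd: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """(x1, x2): availability per 100,000 (C x T) and a static index (C,).

    x1 is log-normal around a county-level base (median ~60 per 100,000)
    with small independent yearly wiggle; x2 is a standardized
    deprivation-like score, time-constant, generated independently of x1
    (mirroring the near-zero covariate correlation of the target setting).
    """
    rng = np.random.default_rng(seed)
    C = graph.n_counties
    base = np.log(x1_median) + x1_log_sd * rng.standard_normal(C)
    wiggle = x1_year_log_sd * rng.standard_normal((C, T))
    x1 = np.exp(base[:, None] + wiggle)
    x2 = rng.standard_normal(C)
    x2 = (x2 - x2.mean()) / x2.std(ddof=0)
    return x1, x2


def simulate_panel(
    graph: AdjacencyGraph,
    true: TrueParameters,
    scenario: str = "VCM",
    x1_scale: float = 1000.0,
    start_year: int = 1988,
) -> tuple[CountyPanel, dict]:
    """Draw a complete county-year panel from the VCM or REM forward model.

    Returns the panel (rates back-transformed to the per-100,000 scale)
    and a truth bundle with every latent quantity, including the
    realized spatial fields and (for REM) the county slopes.  The fitted
    models read x1 on the same ``x1_scale``.
    """
    if scenario not in ("VCM", "REM"):
        raise ValueError(f"scenario must be 'VCM' or 'REM', got {scenario!r}")
    T = true.n_years
    C = graph.n_counties
    ss = np.random.SeedSequence(true.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    s, u = simulate_spatial_field(graph, true.sigma2_str, true.sigma2_unstr, seeds[0])
    x1, x2 = simulate_covariates(graph, T, seeds[1])
    rng = np.random.default_rng(seeds[2])

    x1s = x1 / x1_scale
    truth: dict = {
        "scenario": scenario,
        "alpha": true.alpha,
        "f": true.f.tolist(),
        "s": s.tolist(),
        "u": u.tolist(),
        "sigma2_str": true.sigma2_str,
        "sigma2_unstr": true.sigma2_unstr,
        "sigma2_e": true.sigma2_e,
        "x1_scale": x1_scale,
        "seed": true.seed,
    }
    if scenario == "VCM":
        eff = x1s * true.beta1[None, :] + x2[:, None] * true.beta2[None, :]
        truth["beta1"] = true.beta1.tolist()
        truth["beta2"] = true.beta2.tolist()
    else:
        b1 = rng.normal(0.0, np.sqrt(true.tau2_b1), size=C)
        b2 = rng.normal(0.0, np.sqrt(true.tau2_b2), size=C)
        eff = x1s * b1[:, None] + x2[:, None] * b2[:, None]
        truth.update(
            {
                "b1": b1.tolist(),
                "b2": b2.tolist(),
                "tau2_b1": true.tau2_b1,
                "tau2_b2": true.tau2_b2,
            }
        )
    eta = true.alpha + eff + true.f[None, :] + (s + u)[:, None]
    noise = rng.normal(0.0, np.sqrt(true.sigma2_e), size=(C, T))
    log_rate = eta + noise
    rates = 100_000.0 * np.exp(log_rate)

    years = np.arange(start_year, start_year + T)
    df = pd.DataFrame(
        {
            "county_id": np.repeat(graph.county_ids, T),
            "year": np.tile(years, C),
            "rate_per_100k": rates.ravel(),
            "pcp_per_100k": x1.ravel(),
            "deprivation_index": np.repeat(x2, T),
        }
    )
    return CountyPanel.from_dataframe(df), truth


def simulate_census(
    C: int,
    loadings: np.ndarray | None = None,
    noise_sd: float | np.ndarray | None = None,
    seed: int = 0,
    variables: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One-factor census table on percentage scales.

    Items are generated as lambda_v * F + e mapped affinely onto plausible
    percentage ranges; with the default strong loadings (0.85) the implied
    reliability is high.  ``noise_sd`` defaults to sqrt(1 - lambda^2) so
    standardized items have unit variance.
    """
    from .deprivation_index import DEFAULT_ITEMS

    variables = variables or DEFAULT_ITEMS
    lam = np.full(len(variables), 0.85) if loadings is None else np.asarray(loadings, float)
    if len(lam) != len(variables):
        raise ValueError("one loading per variable required")
    if ((lam <= 0) | (lam >= 1)).any():
        raise ValueError("loadings must lie in (0, 1)")
    sd = np.sqrt(1.0 - lam**2) if noise_sd is None else np.broadcast_to(
        np.asarray(noise_sd, float), lam.shape
    )
    rng = np.random.default_rng(seed)
    F = rng.standard_normal(C)
    Z = lam[None, :] * F[:, None] + sd[None, :] * rng.standard_normal((C, len(lam)))
    # map standard scores onto percentage scales typical of county tables
    centers = np.linspace(10.0, 20.0, len(lam))
    spreads = np.linspace(3.0, 6.0, len(lam))
    pct = np.clip(centers[None, :] + spreads[None, :] * Z, 0.0, 100.0)
    df = pd.DataFrame(pct, columns=list(variables))
    df.insert(0, "county_id", [f"c{i:04d}" for i in range(C)])
    return df


def simulate_stratified_counts(
    panel_rates: pd.DataFrame,
    populations: pd.Series | float,
    strata_scheme: list[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Binomial stratified counts consistent with county-year target rates.

    ``panel_rates`` has columns county_id, year, rate_per_100k;
    ``populations`` gives each county's total woman-years (scalar or
    per-county Series), split evenly over the strata.  Every stratum's
    case count is binomial at the county-year rate, so standardizing with
    the generating weights recovers the target rate in expectation.
    Returns (counts table, standard-population weights).
    """
    strata = strata_scheme or default_strata()
    S = len(strata)
    weights = pd.Series(1.0 / S, index=strata)
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in panel_rates.iterrows():
        cid, year = str(rec["county_id"]), int(rec["year"])
        rate = float(rec["rate_per_100k"])
        if rate < 0:
            raise ValueError("negative target rate")
        pop_total = float(
            populations[cid] if isinstance(populations, pd.Series) else populations
        )
        pop_s = max(int(pop_total // S), 1)
        p = min(rate / 100_000.0, 1.0)
        cases = rng.binomial(pop_s, p, size=S)
        for lab, cs in zip(strata, cases):
            age, race = lab.split("|")
            rows.append(
                {
                    "county_id": cid,
                    "year": year,
                    "age_group": age,
                    "race": race,
                    "cases": int(cs),
                    "population": pop_s,
                }
            )
    return pd.DataFrame(rows), weights
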