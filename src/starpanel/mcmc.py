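"""Block Gibbs sampler for the structured additive county-panel models.

Every coefficient block of a :class:`~starpanel.star_model.ModelSpec` has a
Gaussian full conditional because the likelihood is Gaussian and every
prior is (possibly partially improper) Gaussian: with unscaled penalty K_j,
variance component v_j, design X_j and partial residual r_j,

    theta_j | rest ~ N(P_j^{-1} X_j' r_j / sigma2_e,  P_j^{-1}),
    P_j = K_j / v_j + X_j' X_j / sigma2_e,

drawn by a Cholesky factorization of P_j.  Identifiability constraints are
enforced by centering each draw (per-component for the CAR block, globally
for the exchangeable block, over fitted values for the spline block);
variance components have conjugate inverse-gamma full conditionals whose
shape uses the *rank* of K_j, and the error variance is conjugate
inverse-gamma in the residual sum of squares.  One fixed sweep per
iteration; a per-draw deviance trace is kept for DIC.

The default chain schedule retains 1,000 draws: 22,000 iterations, 2,000
burn-in, every 20th kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .star_model import Block, ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "retained_count",
    "gibbs_run",
    "deviance",
    "potential_scale_reduction",
]

_VARIANCE_FLOOR = 1e-12
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule: total iterations, burn-in, thinning stride, seed."""

    iterations: int = 22_000
    burn_in: int = 2_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.thin < 1:
            raise ValueError("burn_in must be >= 0 and thin >= 1")
        if self.iterations <= self.burn_in:
            raise ValueError(
                f"iterations ({self.iterations}) must exceed burn_in "
                f"({self.burn_in})"
            )


def retained_count(config: ChainConfig) -> int:
    """Number of retained draws: floor((iterations - burn_in) / thin)."""
    return (config.iterations - config.burn_in) // config.thin


@dataclass
class PosteriorDraws:
    """Retained draws per parameter block plus the deviance trace."""

    draws: dict[str, np.ndarray] = field(repr=False)
    deviance: np.ndarray = field(repr=False)
    config: ChainConfig = field(default_factory=ChainConfig)
    model_kind: str = ""
    county_ids: tuple[str, ...] = ()
    years: tuple[int, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[0]

    def mean(self, name: str) -> np.ndarray | float:
        m = self.draws[name].mean(axis=0)
        return float(m) if np.ndim(m) == 0 else m

    def save(self, outdir) -> None:
        """Persist as per-block CSVs plus a JSON metadata file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.draws.items():
            a = np.atleast_2d(arr.T).T  # (n_draws, dim)
            pd.DataFrame(a).to_csv(outdir / f"draws_{name}.csv", index=False)
        pd.DataFrame({"deviance": self.deviance}).to_csv(
            outdir / "deviance.csv", index=False
        )
        meta = {
            "config": asdict(self.config),
            "model_kind": self.model_kind,
            "county_ids": list(self.county_ids),
            "years": list(self.years),
            "metadata": self.metadata,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        outdir = Path(outdir)
        meta = json.loads((outdir / "metadata.json").read_text())
        draws = {}
        for f in sorted(outdir.glob("draws_*.csv")):
            name = f.stem[len("draws_"):]
            arr = pd.read_csv(f).to_numpy(dtype=float)
            draws[name] = arr.ravel() if arr.shape[1] == 1 else arr
        dev = pd.read_csv(outdir / "deviance.csv")["deviance"].to_numpy(dtype=float)
        return cls(
            draws=draws,
            deviance=dev,
            config=ChainConfig(**meta["config"]),
            model_kind=meta["model_kind"],
            county_ids=tuple(meta["county_ids"]),
            years=tuple(meta["years"]),
            metadata=meta["metadata"],
        )


def deviance(y: np.ndarray, eta: np.ndarray, sigma2_e: float) -> float:
    """-2 x Gaussian log-likelihood of y given the linear predictor."""
    if sigma2_e <= 0:
        raise ValueError(f"error variance must be positive, got {sigma2_e}")
    resid = y - eta
    n = y.shape[0]
    return float(n * (_LOG_2PI + np.log(sigma2_e)) + resid @ resid / sigma2_e)


def _center(block: Block, theta: np.ndarray) -> np.ndarray:
    if block.centering == "global":
        return theta - theta.mean()
    if block.centering == "components":
        out = theta.copy()
        for grp in block.groups:
            idx = list(grp)
            out[idx] -= out[idx].mean()
        for i in block.fixed_zero:
            out[i] = 0.0
        return out
    if block.centering == "fitted":
        colsum = np.asarray(block.design.sum(axis=0)).ravel()
        n = block.design.shape[0]
        return theta - float(colsum @ theta) / n
    return theta


def _draw_inverse_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    g = rng.gamma(shape, 1.0 / rate)
    v = 1.0 / g if g > 0 else np.inf
    if not np.isfinite(v) or v < _VARIANCE_FLOOR:
        logger.debug("variance draw floored at %g", _VARIANCE_FLOOR)
        v = max(v, _VARIANCE_FLOOR)
        if not np.isfinite(v):
            v = _VARIANCE_FLOOR
    return float(v)


def gibbs_run(
    spec: ModelSpec,
    config: ChainConfig,
    fixed_variances: dict[str, float] | None = None,
    fixed_sigma2_e: float | None = None,
) -> PosteriorDraws:
    """Fit a constrained :class:`ModelSpec` by block Gibbs sampling.

    The sweep order is fixed: intercept, coefficient blocks in spec order,
    their variance components, then the error variance; the order is
    recorded in the returned metadata.  Each block consumes draws from its
    own RNG substream spawned from the seed, so runs are bit-reproducible.

    ``fixed_variances`` (keyed by block name) and ``fixed_sigma2_e`` pin
    chosen variance components instead of sampling them — useful for
    known-variance checks against closed-form posteriors.
    """
    if not spec.constraints_applied:
        raise ValueError("run apply_constraints(spec) before sampling")
    y = spec.y
    n = y.shape[0]
    if not np.isfinite(y).all():
        raise FloatingPointError("non-finite response; check the panel and offset")

    blocks = spec.blocks
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * len(blocks) + 2)
    rng_alpha = np.random.default_rng(children[0])
    rng_coef = {b.name: np.random.default_rng(children[1 + i]) for i, b in enumerate(blocks)}
    rng_var = {
        b.name: np.random.default_rng(children[1 + len(blocks) + i])
        for i, b in enumerate(blocks)
    }
    rng_sigma = np.random.default_rng(children[-1])

    # precomputed per-block quantities (designs are fixed)
    Xt = {b.name: b.design.T.tocsr() for b in blocks}
    XtX = {b.name: (b.design.T @ b.design).toarray() for b in blocks}

    fixed_variances = fixed_variances or {}
    # initial state: intercept at the response mean, everything else neutral
    alpha = float(y.mean())
    theta = {b.name: np.zeros(b.dim) for b in blocks}
    eta_b = {b.name: np.zeros(n) for b in blocks}
    variances = {b.name: fixed_variances.get(b.name, 0.1) for b in blocks}
    sigma2_e = fixed_sigma2_e if fixed_sigma2_e is not None else 0.1

    n_keep = retained_count(config)
    kept = {b.name: np.empty((n_keep, b.dim)) for b in blocks}
    kept["alpha"] = np.empty(n_keep)
    kept_var = {b.variance_name: np.empty(n_keep) for b in blocks}
    kept_sigma = np.empty(n_keep)
    dev_trace = np.empty(n_keep)

    eta_total = np.full(n, alpha)
    k = 0
    for it in range(config.iterations):
        # intercept (flat prior): normal around the residual mean
        r = y - (eta_total - alpha)
        alpha_new = rng_alpha.normal(r.mean(), np.sqrt(sigma2_e / n))
        eta_total += alpha_new - alpha
        alpha = alpha_new

        for b in blocks:
            name = b.name
            r = y - (eta_total - eta_b[name])
            P = b.prior_precision / variances[name] + XtX[name] / sigma2_e
            rhs = (Xt[name] @ r) / sigma2_e
            try:
                L = sla.cholesky(P, lower=True, check_finite=False)
            except sla.LinAlgError as exc:  # pragma: no cover - degenerate input
                raise FloatingPointError(
                    f"non-positive-definite full conditional in block {name!r} "
                    f"at iteration {it}"
                ) from exc
            mu = sla.cho_solve((L, True), rhs, check_finite=False)
            z = rng_coef[name].standard_normal(b.dim)
            draw = mu + sla.solve_triangular(
                L, z, trans="T", lower=True, check_finite=False
            )
            draw = _center(b, draw)
            new_eta = b.design @ draw
            eta_total += new_eta - eta_b[name]
            eta_b[name] = new_eta
            theta[name] = draw

        for b in blocks:
            if b.name in fixed_variances:
                continue
            quad = float(theta[b.name] @ (b.prior_precision @ theta[b.name]))
            variances[b.name] = _draw_inverse_gamma(
                rng_var[b.name],
                spec.hyper_a + 0.5 * b.prior_rank,
                spec.hyper_b + 0.5 * quad,
            )

        resid = y - eta_total
        rss = float(resid @ resid)
        if fixed_sigma2_e is None:
            sigma2_e = _draw_inverse_gamma(
                rng_sigma, spec.hyper_a + 0.5 * n, spec.hyper_b + 0.5 * rss
            )
        if not np.isfinite(rss):
            raise FloatingPointError(
                f"non-finite residual sum of squares at iteration {it}"
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and k < n_keep:
            for b in blocks:
                kept[b.name][k] = theta[b.name]
                kept_var[b.variance_name][k] = variances[b.name]
            kept["alpha"][k] = alpha
            kept_sigma[k] = sigma2_e
            dev_trace[k] = deviance(y, eta_total, sigma2_e)
            k += 1

    draws: dict[str, np.ndarray] = dict(kept)
    draws.update(kept_var)
    draws["sigma2_e"] = kept_sigma
    return PosteriorDraws(
        draws=draws,
        deviance=dev_trace,
        config=config,
        model_kind=spec.kind,
        county_ids=spec.county_ids,
        years=spec.years,
        metadata={
            **spec.metadata,
            "update_order": ["alpha"]
            + [b.name for b in blocks]
            + [b.variance_name for b in blocks]
            + ["sigma2_e"],
            "seed": config.seed,
        },
    )


def potential_scale_reduction(chains: list[np.ndarray]) -> float:
    """Split-chain potential scale reduction (R-hat) for a scalar trace.

    Each chain is split in half; R-hat compares between- and within-half
    variances (values near 1 indicate mixing).  Plumbing for multi-seed
    convergence checks; nothing in the pipeline asserts a threshold.
    """
    halves = []
    for ch in chains:
        ch = np.asarray(ch, dtype=float)
        h = ch.shape[0] // 2
        if h < 2:
            raise ValueError("chains too short to split")
        halves.append(ch[:h])
        halves.append(ch[h: 2 * h])
    a = np.stack(halves)  # (m, n)
    m, n = a.shape
    means = a.mean(axis=1)
    B = n * means.var(ddof=1)
    W = a.var(axis=1, ddof=1).mean()
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))
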