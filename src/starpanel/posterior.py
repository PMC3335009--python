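"""Posterior summaries: DIC, variance proportions, spatial classification.

Turns retained draws into the quantities a disease-mapping analysis
reports: posterior means with equal-tailed 95% credible intervals,
deviance information criterion (DIC = posterior mean deviance D(theta)
plus effective parameter count p_d), the share rho of structured spatial
variance in total spatial variance, the 80%-posterior-probability
classification of county spatial effects, quintile map bins, relative-risk
transforms, and the percent-change / flagged-share arithmetic used when
summarizing time-varying effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws, deviance
from .star_model import ModelSpec

__all__ = [
    "SpatialClassification",
    "PosteriorSummary",
    "dic",
    "dic_from_draws",
    "spatial_variance_proportion",
    "classify_spatial",
    "credible_interval",
    "percent_change",
    "flagged_share",
    "quintile_bins",
    "rr_transform",
    "summarize",
]


def dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float, float]:
    """(D(theta), p_d, DIC) from a deviance trace and the plug-in deviance.

    D(theta) is the posterior mean of the deviance; p_d = D(theta) minus
    the deviance at the posterior means; DIC = D(theta) + p_d.
    """
    d = np.asarray(deviance_draws, dtype=float)
    if d.size == 0:
        raise ValueError("empty deviance trace")
    d_bar = float(d.mean())
    p_d = d_bar - float(deviance_at_mean)
    return d_bar, p_d, d_bar + p_d


def dic_from_draws(spec: ModelSpec, draws: PosteriorDraws) -> tuple[float, float, float]:
    """DIC evaluated from a fit: plug-in deviance at the posterior means."""
    params = {"alpha": draws.mean("alpha")}
    for b in spec.blocks:
        params[b.name] = np.atleast_1d(draws.mean(b.name))
    eta_bar = spec.linear_predictor(params)
    sigma2_bar = float(np.mean(draws.draws["sigma2_e"]))
    return dic(draws.deviance, deviance(spec.y, eta_bar, sigma2_bar))


def spatial_variance_proportion(var_str: float, var_unstr: float) -> float:
    """rho = sigma2_str / (sigma2_str + sigma2_unstr)."""
    if var_str < 0 or var_unstr < 0:
        raise ValueError("variance components must be non-negative")
    total = var_str + var_unstr
    if total == 0:
        raise ValueError("both spatial variances are zero; proportion undefined")
    return var_str / total


@dataclass(frozen=True)
class SpatialClassification:
    """Per-county labels under the 80% posterior-probability rule."""

    county_ids: tuple[str, ...]
    labels: tuple[str, ...]
    prob_positive: np.ndarray
    threshold: float = 0.80

    def counts(self) -> dict[str, int]:
        out = {"positive": 0, "negative": 0, "nonsignificant": 0}
        for lab in self.labels:
            out[lab] += 1
        return out


def classify_spatial(
    draws_by_county: np.ndarray,
    county_ids: tuple[str, ...] | None = None,
    threshold: float = 0.80,
) -> SpatialClassification:
    """Classify each county's spatial effect by posterior probability.

    ``draws_by_county`` is (n_draws, C).  A county is *positive* when at
    least ``threshold`` of its posterior mass lies above zero, *negative*
    when at least that much lies below zero, otherwise *nonsignificant*
    (so a posterior probability of 0.79 at the default cutoff stays
    nonsignificant).
    """
    arr = np.atleast_2d(np.asarray(draws_by_county, dtype=float))
    if arr.shape[0] == 0:
        raise ValueError("no draws")
    p_pos = (arr > 0).mean(axis=0)
    p_neg = (arr < 0).mean(axis=0)
    labels = []
    for pp, pn in zip(p_pos, p_neg):
        if pp >= threshold:
            labels.append("positive")
        elif pn >= threshold:
            labels.append("negative")
        else:
            labels.append("nonsignificant")
    if county_ids is None:
        county_ids = tuple(str(i) for i in range(arr.shape[1]))
    return SpatialClassification(
        county_ids=tuple(county_ids),
        labels=tuple(labels),
        prob_positive=p_pos,
        threshold=threshold,
    )


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of a draw vector."""
    d = np.asarray(draws, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 draws for an interval")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(d, [tail, 100.0 - tail])
    return float(lo), float(hi)


def percent_change(effect_start: float, effect_end: float) -> float:
    """Percent decline from a start to an end effect, one decimal.

    100 * (start - end) / start; e.g. a log relative risk falling from
    3.72 to 2.45 over the study period is a 34.1% decline.
    """
    if effect_start == 0:
        raise ValueError("percent change undefined for zero starting effect")
    return round(100.0 * (effect_start - effect_end) / effect_start, 1)


def flagged_share(n_flagged: int, n_total: int) -> float:
    """Percentage of counties flagged, one decimal (e.g. 34/200 -> 17.0)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_flagged <= n_total:
        raise ValueError("n_flagged must lie in [0, n_total]")
    return round(100.0 * n_flagged / n_total, 1)


def quintile_bins(effects: np.ndarray) -> np.ndarray:
    """Quintile bin (1..5) per county, ties resolved to the lower bin.

    Cutpoints are the 20/40/60/80 linear-interpolation percentiles; a value
    exactly on a cutpoint falls in the lower bin, so constant inputs all
    land in bin 1.
    """
    v = np.asarray(effects, dtype=float)
    if v.size < 5:
        raise ValueError(f"need at least 5 values for quintiles, got {v.size}")
    cuts = np.percentile(v, [20, 40, 60, 80])
    return 1 + (v[:, None] > cuts[None, :]).sum(axis=1)


def rr_transform(log_effect_draws: np.ndarray) -> dict[str, float]:
    """Relative-risk summaries of a log-effect draw vector.

    Returns both the posterior mean of exp(draws) (``rr_mean``) and the
    exponentiated posterior mean (``rr_at_mean``), plus the exponentiated
    equal-tailed 95% interval.
    """
    d = np.asarray(log_effect_draws, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite log-effect draws")
    lo, hi = credible_interval(d) if d.size >= 2 else (float(d), float(d))
    return {
        "rr_mean": float(np.exp(d).mean()),
        "rr_at_mean": float(np.exp(d.mean())),
        "rr_ci_low": float(np.exp(lo)),
        "rr_ci_high": float(np.exp(hi)),
    }


def area_rr_summary(rr_by_county: np.ndarray) -> dict[str, float]:
    """Range, mean and variance of per-county relative risks in one area."""
    rr = np.asarray(rr_by_county, dtype=float)
    return {
        "rr_min": float(rr.min()),
        "rr_max": float(rr.max()),
        "rr_mean": float(rr.mean()),
        "rr_var": float(rr.var(ddof=1)) if rr.size > 1 else 0.0,
    }


@dataclass(frozen=True)
class PosteriorSummary:
    """Tabular posterior summaries of one fit plus headline diagnostics."""

    parameters: pd.DataFrame
    counties: pd.DataFrame
    diagnostics: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.parameters.to_csv(outdir / "summary.csv", index=False)
        self.counties.to_csv(outdir / "county.csv", index=False)
        (outdir / "diagnostics.json").write_text(
            json.dumps(self.diagnostics, indent=2)
        )


def _round2(x: float) -> float:
    return round(float(x), 2)


def summarize(spec: ModelSpec, draws: PosteriorDraws) -> PosteriorSummary:
    """Full posterior summary of a fit.

    The parameter table has one row per scalar coefficient (posterior mean,
    95% CI, relative-risk transforms); the county table carries the
    structured spatial effect, its positive posterior probability, the
    80%-rule classification, and the quintile map bin; diagnostics hold
    D(theta), p_d, DIC, the spatial variance components with CIs, and rho.
    """
    rows = []
    scalar_blocks = {"alpha": draws.draws["alpha"]}
    for b in spec.blocks:
        arr = np.atleast_2d(draws.draws[b.name].T).T
        if b.name in ("beta1", "beta2", "f"):
            names = [f"{b.name}[{yr}]" for yr in spec.years] if arr.shape[1] == len(
                spec.years
            ) else [f"{b.name}[{j}]" for j in range(arr.shape[1])]
        else:
            names = [f"{b.name}[{cid}]" for cid in spec.county_ids]
        for j, nm in enumerate(names):
            col = arr[:, j]
            lo, hi = credible_interval(col)
            rr = rr_transform(col)
            rows.append(
                {
                    "parameter": nm,
                    "mean": col.mean(),
                    "ci_low": lo,
                    "ci_high": hi,
                    "rr_mean": rr["rr_mean"],
                    "rr_ci_low": rr["rr_ci_low"],
                    "rr_ci_high": rr["rr_ci_high"],
                }
            )
    for nm, col in scalar_blocks.items():
        lo, hi = credible_interval(col)
        rows.insert(
            0,
            {
                "parameter": nm,
                "mean": col.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "rr_mean": np.nan,
                "rr_ci_low": np.nan,
                "rr_ci_high": np.nan,
            },
        )
    parameters = pd.DataFrame(rows)

    s_draws = draws.draws["s"]
    cls = classify_spatial(s_draws, spec.county_ids)
    s_mean = s_draws.mean(axis=0)
    counties = pd.DataFrame(
        {
            "county_id": spec.county_ids,
            "s_mean": s_mean,
            "prob_positive": cls.prob_positive,
            "classification": cls.labels,
            "quintile_bin": quintile_bins(s_mean)
            if len(s_mean) >= 5
            else np.ones(len(s_mean), dtype=int),
        }
    )

    d_bar, p_d, dic_val = dic_from_draws(spec, draws)
    var_str = draws.draws["sigma2_str"]
    var_unstr = draws.draws["sigma2_unstr"]
    str_lo, str_hi = credible_interval(var_str)
    un_lo, un_hi = credible_interval(var_unstr)
    rho = spatial_variance_proportion(
        float(var_str.mean()), float(var_unstr.mean())
    )
    diagnostics = {
        "model_kind": spec.kind,
        "D_theta": _round2(d_bar),
        "p_d": _round2(p_d),
        "DIC": _round2(d_bar + p_d),
        "sigma2_str": _round2(var_str.mean()),
        "sigma2_str_ci": [_round2(str_lo), _round2(str_hi)],
        "sigma2_unstr": _round2(var_unstr.mean()),
        "sigma2_unstr_ci": [_round2(un_lo), _round2(un_hi)],
        "rho": _round2(rho),
        "n_positive": cls.counts()["positive"],
        "n_negative": cls.counts()["negative"],
        "share_positive_pct": flagged_share(
            cls.counts()["positive"], len(spec.county_ids)
        ),
    }
    return PosteriorSummary(parameters=parameters, counties=counties, diagnostics=diagnostics)
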