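"""Direct rate standardization and area-level summary tables.

County-year outcome rates are directly standardized: stratum-specific
rates (cases / population within age-group x race cells) are averaged with
the stratum weights of a fixed standard population, then scaled to a
per-100,000 basis.  Area summaries aggregate county-year frequencies to
registry-area totals and report the median of county-year standardized
crude rates per area.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "load_standard_population",
    "direct_standardize",
    "standardize_panel",
    "area_totals",
    "area_median_rate",
    "default_strata",
]

COUNTS_COLUMNS = ["county_id", "year", "age_group", "race", "cases", "population"]


def default_strata(races: tuple[str, ...] = ("white", "black", "other")) -> list[str]:
    """Default stratum labels: 5-year age groups from 40 to 85+ by race."""
    ages = [f"{a}-{a + 4}" for a in range(40, 85, 5)] + ["85+"]
    return [f"{age}|{race}" for age in ages for race in races]


def load_standard_population(path) -> pd.Series:
    """Standard-population weights from a CSV with age_group, race, weight."""
    df = pd.read_csv(path, dtype={"age_group": str, "race": str})
    weights = pd.Series(
        df["weight"].to_numpy(dtype=float),
        index=df["age_group"].astype(str) + "|" + df["race"].astype(str),
    )
    return validate_standard_population(weights)


def validate_standard_population(weights: pd.Series) -> pd.Series:
    if (weights < 0).any():
        raise ValueError("standard-population weights must be non-negative")
    total = weights.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"standard-population weights sum to {total}, not 1")
    return weights


def direct_standardize(counts: pd.DataFrame, std_weights: pd.Series) -> float:
    """Directly standardized rate per 100,000 for one county-year.

    ``counts`` holds one row per stratum with ``age_group``, ``race``,
    ``cases`` and ``population``; ``std_weights`` is indexed by
    ``"age_group|race"`` and sums to one.  Strata with zero population are
    dropped with a warning and the weights renormalized over the rest.
    """
    labels = counts["age_group"].astype(str) + "|" + counts["race"].astype(str)
    unknown = set(labels) - set(std_weights.index)
    if unknown:
        raise ValueError(f"strata missing from standard population: {sorted(unknown)}")
    pop = counts["population"].to_numpy(dtype=float)
    cases = counts["cases"].to_numpy(dtype=float)
    if (cases < 0).any():
        raise ValueError("negative case counts")
    if (cases > pop).any():
        raise ValueError("cases exceed population in some stratum")
    keep = pop > 0
    if not keep.any():
        raise ValueError("no stratum with positive population")
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} zero-population stratum(s) dropped; standard "
            "weights renormalized",
            stacklevel=2,
        )
    w = std_weights.loc[labels[keep]].to_numpy(dtype=float)
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("all overlapping standard weights are zero")
    w = w / wsum
    stratum_rates = cases[keep] / pop[keep]
    return float(100_000.0 * (w * stratum_rates).sum())


def standardize_panel(counts: pd.DataFrame, std_weights: pd.Series) -> pd.DataFrame:
    """Standardize every county-year in a long stratified-counts table."""
    missing = [c for c in COUNTS_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table is missing columns {missing}")
    rows = []
    for (cid, year), grp in counts.groupby(["county_id", "year"], sort=True):
        rows.append(
            {
                "county_id": str(cid),
                "year": int(year),
                "rate_per_100k": direct_standardize(grp, std_weights),
            }
        )
    return pd.DataFrame(rows)


def area_totals(
    frequencies: pd.Series | dict[str, float], area_map: dict[str, str] | None = None
) -> pd.Series:
    """Per-area frequency totals plus a ``Total`` grand-total row.

    ``frequencies`` is indexed by county (or already by area when
    ``area_map`` is None, in which case values are summed per index label).
    """
    s = pd.Series(frequencies, dtype=float)
    if area_map is not None:
        unmapped = [c for c in s.index if c not in area_map]
        if unmapped:
            raise ValueError(f"counties missing from area map: {unmapped[:5]}")
        s = s.groupby([area_map[c] for c in s.index]).sum()
    else:
        s = s.groupby(level=0).sum()
    out = s.copy()
    out.loc["Total"] = s.sum()
    return out


def area_median_rate(
    rates: pd.DataFrame, area_map: dict[str, str], rate_col: str = "rate_per_100k"
) -> pd.Series:
    """Median of county-year standardized crude rates within each area."""
    unmapped = sorted(set(rates["county_id"].astype(str)) - set(area_map))
    if unmapped:
        raise ValueError(f"counties missing from area map: {unmapped[:5]}")
    areas = rates["county_id"].astype(str).map(area_map)
    med = rates.groupby(areas)[rate_col].median()
    if (rates.groupby(areas).size() == 0).any():  # pragma: no cover
        raise ValueError("empty area")
    return med
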