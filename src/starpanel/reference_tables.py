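"""Bundled reference tables for the nine-area, 1988-2008 study setting.

Two small CSVs ship with the package:

* ``area_frequencies.csv`` — per-registry-area case frequencies and median
  standardized crude rates for the three breast cancer indicators
  (early-stage incidence, advanced-stage incidence, mortality);
* ``model_diagnostics.csv`` — published model diagnostics for the VCM and
  REM fits of each indicator: posterior mean deviance D(theta), effective
  parameter count p_d, DIC, the structured and unstructured spatial
  variance components with 95% CIs, and the structured-variance proportion
  rho.

They serve as fixed inputs for the derived-arithmetic operations
(aggregation totals, DIC identities, variance proportions) and as the
reference scale for the synthetic-data defaults.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_area_frequencies", "load_model_diagnostics"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("starpanel.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_area_frequencies() -> pd.DataFrame:
    """Per-area frequencies/rates table (9 areas x 3 indicators)."""
    return _read("area_frequencies.csv")


def load_model_diagnostics() -> pd.DataFrame:
    """Model-diagnostics table (6 rows: {early, advanced, mortality} x {VCM, REM})."""
    return _read("model_diagnostics.csv")
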