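"""Prior building blocks: RW2 penalties, P-spline bases, exchangeable priors.

Three smoothness structures recur in the county-panel models:

* a second-order random-walk (RW2) prior on an ordered coefficient sequence,
  whose precision penalizes squared second differences and leaves constant
  and linear trends unpenalized (used for the time-varying covariate
  effects);
* a Bayesian P-spline — a B-spline basis over the year grid with an RW2
  penalty on its coefficients (used for the common time smoother f(t),
  whose main role is absorbing autoregressive correlation in the panel);
* an exchangeable (i.i.d.) normal prior, whose unscaled precision is the
  identity (used for unstructured county effects and random slopes).

All precisions here are *unscaled*: the sampler divides by the block's
variance component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["PSplineBasis", "rw2_precision", "bspline_basis", "exchangeable_precision"]


def rw2_precision(T: int) -> np.ndarray:
    """RW2 penalty matrix K = D2' D2 for a length-``T`` sequence.

    D2 is the (T-2) x T second-difference operator, so v' K v equals the sum
    of squared second differences of v.  K is symmetric PSD with rank T - 2;
    the two zero rows of the implied random-walk start act as diffuse
    initial values (partially improper prior).
    """
    if T < 3:
        raise ValueError(f"RW2 prior needs at least 3 points, got T={T}")
    d2 = np.diff(np.eye(T), n=2, axis=0)
    return d2.T @ d2


@dataclass(frozen=True)
class PSplineBasis:
    """B-spline design over a time grid plus the RW2 coefficient penalty.

    ``basis`` is T x m with non-negative rows summing to one (partition of
    unity); ``penalty`` is the m x m RW2 matrix on the spline coefficients.
    """

    times: np.ndarray
    degree: int
    n_inner_knots: int
    basis: np.ndarray
    penalty: np.ndarray

    @property
    def n_coef(self) -> int:
        return self.basis.shape[1]

    def evaluate(self, coef: np.ndarray) -> np.ndarray:
        return self.basis @ np.asarray(coef, dtype=float)


def bspline_basis(T: int, degree: int = 3, n_inner_knots: int = 18) -> PSplineBasis:
    """Clamped uniform B-spline basis on the year grid 1..T.

    ``n_inner_knots`` is the number of equal-width knot intervals spanning
    [1, T]; the basis then has m = n_inner_knots + degree columns.  The
    coefficient penalty is ``rw2_precision(m)``.
    """
    if degree < 1:
        raise ValueError(f"spline degree must be >= 1, got {degree}")
    if n_inner_knots < 1:
        raise ValueError(f"need at least 1 knot interval, got {n_inner_knots}")
    if T < degree + 2:
        raise ValueError(
            f"too few time points (T={T}) for degree-{degree} spline; need "
            f"T >= {degree + 2}"
        )
    times = np.arange(1, T + 1, dtype=float)
    breakpoints = np.linspace(1.0, float(T), n_inner_knots + 1)
    knots = np.r_[[1.0] * degree, breakpoints, [float(T)] * degree]
    basis = BSpline.design_matrix(times, knots, degree, extrapolate=False).toarray()
    m = basis.shape[1]
    if rw2_precision(m).shape != (m, m):  # pragma: no cover - shape sanity
        raise AssertionError
    return PSplineBasis(
        times=times,
        degree=degree,
        n_inner_knots=n_inner_knots,
        basis=basis,
        penalty=rw2_precision(m),
    )


def exchangeable_precision(C: int) -> np.ndarray:
    """Unscaled precision of C i.i.d. normal effects: the identity."""
    if C < 1:
        raise ValueError(f"need at least one unit, got C={C}")
    return np.eye(C)
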