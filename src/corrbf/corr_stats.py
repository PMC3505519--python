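"""Sample (partial) correlations, coefficients of determination, and t tests.

This module implements the classical side of the correlation problem: the
Pearson product-moment correlation ``r``, the first-order partial correlation
``r_XY|Z`` obtained from the three pairwise correlations, the associated
Student-t statistics (``df = n - 2`` for a correlation, ``df = n - 3`` for a
partial correlation), two-sided p values, and the coefficients of
determination that feed the nested-regression-model Bayes factors.

All computation is done in full double precision; any rounding is left to
presentation layers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SampleMoments",
    "CorrelationTestResult",
    "PartialCorrelationTestResult",
    "pearson_r",
    "partial_r",
    "t_from_r",
    "t_from_partial_r",
    "p_from_t",
    "r_squared_pair",
    "r1_squared_from_partial",
]

# slack for floating-point excursions of |r| beyond 1
_R_EPS = 1e-12


@dataclass(frozen=True)
class SampleMoments:
    """First and second moments of a paired sample.

    ``cross_sum`` is the centred cross-product sum
    ``sum_i (x_i - mean_x)(y_i - mean_y)``; together with the unbiased
    variances it determines the sample correlation
    ``r = cross_sum / ((n - 1) * s_X * s_Y)``.
    """

    n: int
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    cross_sum: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 paired observations, got n={self.n}")
        if self.var_x < 0 or self.var_y < 0:
            raise ValueError("sample variances must be non-negative")
        bound = (self.n - 1) * math.sqrt(self.var_x * self.var_y)
        if abs(self.cross_sum) > bound * (1 + 1e-9) + _R_EPS:
            raise ValueError(
                "cross_sum violates the Cauchy-Schwarz bound "
                f"|{self.cross_sum}| > {bound}"
            )

    @classmethod
    def from_data(cls, x: Sequence[float], y: Sequence[float]) -> "SampleMoments":
        x = _as_1d(x, "x")
        y = _as_1d(y, "y")
        if x.size != y.size:
            raise ValueError(f"length mismatch: len(x)={x.size}, len(y)={y.size}")
        n = int(x.size)
        if n < 2:
            raise ValueError(f"need at least 2 paired observations, got n={n}")
        mx, my = float(x.mean()), float(y.mean())
        return cls(
            n=n,
            mean_x=mx,
            mean_y=my,
            var_x=float(x.var(ddof=1)),
            var_y=float(y.var(ddof=1)),
            cross_sum=float(np.dot(x - mx, y - my)),
        )

    @property
    def r(self) -> float:
        """Sample correlation implied by the moments."""
        denom = (self.n - 1) * math.sqrt(self.var_x * self.var_y)
        if denom == 0.0:
            raise ValueError("correlation undefined: zero variance in x or y")
        return float(np.clip(self.cross_sum / denom, -1.0, 1.0))


@dataclass(frozen=True)
class CorrelationTestResult:
    """Full record of a two-variable correlation test.

    Combines the frequentist summary (``t`` on ``df = n - 2`` degrees of
    freedom, two-sided ``p``) with the default Bayesian summary (``bf10`` and
    its verbal evidence ``label``).
    """

    r: float
    n: int
    t: float
    df: int
    p: float
    bf10: float
    label: str

    def __post_init__(self) -> None:
        if self.df != self.n - 2:
            raise ValueError("df must equal n - 2 for a correlation test")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p value must lie in [0, 1]")
        if not self.bf10 > 0:
            raise ValueError("bf10 must be positive")

    @property
    def bf01(self) -> float:
        return math.inf if self.bf10 == 0 else 1.0 / self.bf10


@dataclass(frozen=True)
class PartialCorrelationTestResult:
    """Full record of a partial-correlation test (one control variable).

    ``r0_sq``/``r1_sq`` are the coefficients of determination of the null
    model (control variable only, ``p0`` regression coefficients) and the
    alternative model (control plus variable of interest, ``p1``
    coefficients); ``df = n - 3``.
    """

    r_partial: float
    n: int
    r0_sq: float
    r1_sq: float
    p0: int
    p1: int
    t: float
    df: int
    p: float
    bf10: float
    label: str

    def __post_init__(self) -> None:
        if self.df != self.n - 3:
            raise ValueError("df must equal n - 3 for a partial-correlation test")
        if self.r1_sq < self.r0_sq - _R_EPS:
            raise ValueError("R1^2 must be >= R0^2 (nested models)")
        if not self.p1 > self.p0 >= 0:
            raise ValueError("need p1 > p0 >= 0")

    @property
    def bf01(self) -> float:
        return math.inf if self.bf10 == 0 else 1.0 / self.bf10


def _as_1d(seq: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(seq, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length sequences.

    Uses the centred cross-product sum over ``(n - 1) * s_X * s_Y`` with
    unbiased standard deviations. Requires ``n >= 3`` (so the associated test
    has at least one degree of freedom) and nonzero variance in both inputs.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: len(x)={x.size}, len(y)={y.size}")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got n={x.size}")
    m = SampleMoments.from_data(x, y)
    if m.var_x == 0.0 or m.var_y == 0.0:
        raise ValueError("correlation undefined: zero variance in x or y")
    return m.r


def partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Partial correlation of X and Y controlling for Z.

    Computed from the three pairwise correlations as
    ``(r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))``.

    Raises if a control correlation is +/-1 (zero denominator) or if the
    result falls outside [-1, 1], which means the input triple is not a valid
    (positive-semidefinite) correlation structure.
    """
    for name, val in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [-1, 1]")
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("partial correlation undefined: |r_xz| or |r_yz| equals 1")
    value = (r_xy - r_xz * r_yz) / math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if abs(value) > 1.0 + _R_EPS:
        raise ValueError(
            f"inconsistent correlation triple: partial correlation {value:.6g} "
            "outside [-1, 1] (matrix not positive semidefinite)"
        )
    return float(np.clip(value, -1.0, 1.0))


def t_from_r(r: float, n: int) -> float:
    """t statistic for H0: rho = 0, ``t = r * sqrt((n - 2) / (1 - r^2))``.

    Follows Student's t with ``n - 2`` degrees of freedom. ``|r| = 1`` yields
    a signed infinity (with a warning); ``n < 3`` is an error.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got n={n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r={r} outside [-1, 1]")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: t statistic is infinite", RuntimeWarning, stacklevel=2)
        return math.copysign(math.inf, r)
    return r * math.sqrt((n - 2) / (1.0 - r * r))


def t_from_partial_r(r_partial: float, n: int) -> float:
    """t statistic for a partial correlation, ``df = n - 3``.

    ``t = r_partial * sqrt((n - 3) / (1 - r_partial^2))``; needs ``n >= 4``.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got n={n}")
    if not -1.0 <= r_partial <= 1.0:
        raise ValueError(f"r_partial={r_partial} outside [-1, 1]")
    if abs(r_partial) == 1.0:
        warnings.warn(
            "|r_partial| = 1: t statistic is infinite", RuntimeWarning, stacklevel=2
        )
        return math.copysign(math.inf, r_partial)
    return r_partial * math.sqrt((n - 3) / (1.0 - r_partial * r_partial))


def p_from_t(t: float, df: int) -> float:
    """Two-sided p value of a Student-t statistic."""
    if df < 1:
        raise ValueError(f"need df >= 1, got df={df}")
    if math.isinf(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), df))


def r_squared_pair(
    r: float | None = None,
    *,
    ss_err: float | None = None,
    ss_tot: float | None = None,
) -> float:
    """Coefficient of determination R^2.

    Either square a sample correlation, or compute ``1 - SS_err / SS_tot``
    from residual and total sums of squares of a regression fit.
    """
    if r is not None:
        if ss_err is not None or ss_tot is not None:
            raise ValueError("pass either r or (ss_err, ss_tot), not both")
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"r={r} outside [-1, 1]")
        return r * r
    if ss_err is None or ss_tot is None:
        raise ValueError("need both ss_err and ss_tot when r is not given")
    if ss_err < 0 or ss_tot < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_tot == 0:
        raise ValueError("SS_tot is zero: R^2 undefined")
    if ss_err > ss_tot * (1 + 1e-9):
        raise ValueError("SS_err exceeds SS_tot: not a least-squares fit with intercept")
    return max(0.0, 1.0 - ss_err / ss_tot)


def r1_squared_from_partial(r_partial: float, r_control: float) -> float:
    """R^2 of the two-predictor model from the partial and control correlations.

    ``R1^2 = r_partial^2 * (1 - r_control^2) + r_control^2``, which is always
    at least ``r_control^2`` (adding a predictor cannot reduce fit).
    """
    for name, val in (("r_partial", r_partial), ("r_control", r_control)):
        if not -1.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [-1, 1]")
    rc2 = r_control * r_control
    return r_partial * r_partial * (1.0 - rc2) + rc2
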