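"""Sequential monitoring of the correlation Bayes factor.

Because the Bayes factor quantifies evidence rather than controlling a
long-run error rate, it may legitimately be inspected after every new
observation: no correction for the sampling plan is required. This module
recomputes the JZS correlation Bayes factor on every growing prefix of a
paired data stream and reports the trajectory. No stopping rule is imposed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corr_stats import pearson_r
from .evidence import classify_bf
from .jzs import jzs_bf_correlation

__all__ = ["BFTrajectory", "sequential_bf"]

#: default first sample size evaluated; the integral is defined from n = 3
#: but very small windows produce noisy, divergence-prone values
DEFAULT_MIN_N = 5


@dataclass(frozen=True)
class BFTrajectory:
    """Ordered (sample size, BF10) pairs from sequential monitoring."""

    entries: tuple[tuple[int, float], ...]
    min_n: int = field(default=DEFAULT_MIN_N)

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.entries]
        if any(b <= a for a, b in zip(ns, ns[1:], strict=False)):
            raise ValueError("sample sizes must be strictly increasing")
        if any(bf <= 0 for _, bf in self.entries):
            raise ValueError("all Bayes factors must be positive")

    @property
    def final_bf10(self) -> float:
        return self.entries[-1][1]

    def to_frame(self) -> pd.DataFrame:
        """Columns n, bf10, log_bf10, label."""
        rows = [
            {
                "n": n,
                "bf10": bf,
                "log_bf10": math.log(bf) if bf > 0 else -math.inf,
                "label": str(classify_bf(bf)),
            }
            for n, bf in self.entries
        ]
        return pd.DataFrame(rows, columns=["n", "bf10", "log_bf10", "label"])

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def to_json(self) -> str:
        return json.dumps(
            {"min_n": self.min_n, "entries": self.to_frame().to_dict(orient="records")}
        )


def sequential_bf(
    x: Sequence[float], y: Sequence[float], min_n: int = DEFAULT_MIN_N
) -> BFTrajectory:
    """JZS correlation Bayes factor on every growing prefix of (x, y).

    The trajectory contains one entry per prefix size m = min_n .. len(x);
    prefixes in which either variable has zero variance (the correlation is
    undefined) are skipped with a warning. The final entry equals the
    full-sample Bayes factor.
    """
    if min_n < 3:
        raise ValueError(f"need min_n >= 3, got {min_n}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional with equal length")
    if x.size < min_n:
        raise ValueError(f"need at least min_n={min_n} observations, got {x.size}")

    entries: list[tuple[int, float]] = []
    skipped = 0
    for m in range(min_n, x.size + 1):
        xs, ys = x[:m], y[:m]
        if xs.var() == 0.0 or ys.var() == 0.0:
            skipped += 1
            continue
        r = pearson_r(xs, ys)
        entries.append((m, jzs_bf_correlation(r, m).bf10))
    if skipped:
        warnings.warn(
            f"skipped {skipped} prefix window(s) with zero variance",
            RuntimeWarning,
            stacklevel=2,
        )
    if not entries:
        raise ValueError("no prefix window had nonzero variance in both variables")
    return BFTrajectory(entries=tuple(entries), min_n=min_n)
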