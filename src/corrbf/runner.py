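"""Orchestration: assemble full test records from raw data or summary stats.

Both entry modes produce identical records when the summary statistics are
computed from the same data. Raw-data mode reads delimited text (CSV/TSV,
header row, delimiter sniffed unless forced) and applies complete-case
deletion within the tested variable set, logging the number of dropped rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from .corr_stats import (
    CorrelationTestResult,
    PartialCorrelationTestResult,
    p_from_t,
    partial_r,
    pearson_r,
    r1_squared_from_partial,
    r_squared_pair,
    t_from_partial_r,
    t_from_r,
)
from .evidence import classify_bf, posterior_from_bf
from .jzs import fixed_g_bf_correlation, jzs_bf_correlation, jzs_bf_partial

__all__ = [
    "RunConfig",
    "read_table",
    "run_corr_from_stats",
    "run_corr_from_data",
    "run_pcorr_from_stats",
    "run_pcorr_from_data",
    "record_to_json",
    "record_to_tsv",
]

logger = logging.getLogger("corrbf")


@dataclass(frozen=True)
class RunConfig:
    """Options shared by the run_* entry points."""

    prior_h1: float = 0.5
    fixed_g: float | None = None  # None -> JZS mixture prior
    fmt: Literal["json", "tsv"] = "json"
    delimiter: str | None = None  # None -> sniff
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_h1 < 1.0:
            raise ValueError("prior_h1 must lie strictly in (0, 1)")
        if self.fixed_g is not None and self.fixed_g <= 0:
            raise ValueError("fixed_g must be positive")


def read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited text table with a header row (UTF-8)."""
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    return pd.read_csv(path, sep=delimiter, encoding="utf-8")


def _complete_cases(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    dropped = len(sub) - len(kept)
    if dropped:
        logger.info("dropped %d row(s) with missing/non-numeric values", dropped)
    return kept


def _bf_for_correlation(r: float, n: int, config: RunConfig) -> float:
    if config.fixed_g is not None:
        return fixed_g_bf_correlation(r, n, config.fixed_g).bf10
    return jzs_bf_correlation(r, n).bf10


def run_corr_from_stats(
    r: float, n: int, config: RunConfig | None = None
) -> CorrelationTestResult:
    """Correlation test from the sample correlation r and sample size n."""
    config = config or RunConfig()
    t = t_from_r(r, n)
    bf10 = _bf_for_correlation(r, n, config)
    return CorrelationTestResult(
        r=r,
        n=n,
        t=t,
        df=n - 2,
        p=p_from_t(t, n - 2),
        bf10=bf10,
        label=str(classify_bf(bf10)),
    )


def run_corr_from_data(
    data: pd.DataFrame | str | Path,
    col_x: str,
    col_y: str,
    config: RunConfig | None = None,
) -> CorrelationTestResult:
    """Correlation test from raw paired observations."""
    config = config or RunConfig()
    df = data if isinstance(data, pd.DataFrame) else read_table(data, config.delimiter)
    kept = _complete_cases(df, [col_x, col_y])
    if len(kept) < 3:
        raise ValueError(f"fewer than 3 complete rows (got {len(kept)})")
    x = kept[col_x].to_numpy(float)
    y = kept[col_y].to_numpy(float)
    # perfectly collinear columns: r = +/-1, divergent Bayes factor
    r = pearson_r(x, y)
    return run_corr_from_stats(r, len(kept), config)


def run_pcorr_from_stats(
    r_xy: float,
    r_xz: float,
    r_yz: float,
    n: int,
    config: RunConfig | None = None,
) -> PartialCorrelationTestResult:
    """Partial-correlation test from the three pairwise correlations and n.

    The null model regresses X on the control Z alone (p0 = 1,
    R0^2 = r_xz^2); the alternative adds Y (p1 = 2, R1^2 from the partial
    correlation).
    """
    config = config or RunConfig()
    rp = partial_r(r_xy, r_xz, r_yz)
    r0_sq = r_squared_pair(r_xz)
    r1_sq = r1_squared_from_partial(rp, r_xz)
    t = t_from_partial_r(rp, n)
    bf10 = jzs_bf_partial(r0_sq, r1_sq, 1, 2, n).bf10
    return PartialCorrelationTestResult(
        r_partial=rp,
        n=n,
        r0_sq=r0_sq,
        r1_sq=r1_sq,
        p0=1,
        p1=2,
        t=t,
        df=n - 3,
        p=p_from_t(t, n - 3),
        bf10=bf10,
        label=str(classify_bf(bf10)),
    )


def run_pcorr_from_data(
    data: pd.DataFrame | str | Path,
    col_x: str,
    col_y: str,
    col_z: str,
    config: RunConfig | None = None,
) -> PartialCorrelationTestResult:
    """Partial-correlation test from raw triples (Z is the control)."""
    config = config or RunConfig()
    df = data if isinstance(data, pd.DataFrame) else read_table(data, config.delimiter)
    kept = _complete_cases(df, [col_x, col_y, col_z])
    if len(kept) < 4:
        raise ValueError(f"fewer than 4 complete rows (got {len(kept)})")
    x = kept[col_x].to_numpy(float)
    y = kept[col_y].to_numpy(float)
    z = kept[col_z].to_numpy(float)
    r_xy = pearson_r(x, y)
    r_xz = pearson_r(x, z)
    r_yz = pearson_r(y, z)
    return run_pcorr_from_stats(r_xy, r_xz, r_yz, len(kept), config)


def _record_dict(
    result: CorrelationTestResult | PartialCorrelationTestResult,
    config: RunConfig,
) -> dict:
    rec = dataclasses.asdict(result)
    rec["bf01"] = result.bf01
    probs = posterior_from_bf(result.bf10, config.prior_h1)
    rec["prior_h1"] = probs.prior_h1
    rec["posterior_h1"] = probs.posterior_h1
    rec["posterior_h0"] = probs.posterior_h0
    # presentation rounding kept separate from the full-precision fields
    rec["display"] = {
        k: (round(rec[k], 2) if isinstance(rec[k], float) and math.isfinite(rec[k]) else rec[k])
        for k in rec
        if k != "display" and not isinstance(rec[k], dict)
    }
    return rec


def record_to_json(
    result: CorrelationTestResult | PartialCorrelationTestResult,
    config: RunConfig | None = None,
) -> str:
    """Serialize a result record as JSON at full float precision."""
    config = config or RunConfig()
    return json.dumps(_record_dict(result, config))


def record_to_tsv(
    result: CorrelationTestResult | PartialCorrelationTestResult,
    config: RunConfig | None = None,
) -> str:
    """Serialize a result record as a two-line TSV (header + values)."""
    config = config or RunConfig()
    rec = _record_dict(result, config)
    rec.pop("display")
    keys = list(rec)
    vals = [repr(v) if isinstance(v, float) else str(v) for v in rec.values()]
    return "\t".join(keys) + "\n" + "\t".join(vals) + "\n"
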