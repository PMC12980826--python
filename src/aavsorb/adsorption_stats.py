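"""Adsorption-ratio computation and replicate statistics.

The adsorption assay incubates a virus suspension with a solid surface
and quantifies genomic titers (vg/mL, digital PCR) before and after:

    A (%) = (titer_before − titer_after) / titer_before × 100

A negative ratio is a measurement error and is clamped to 0 % (per
replicate, before averaging).  Group comparisons use the two-tailed
unpaired Student's t-test (pooled variance) with conventional star
annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdsorptionObservation",
    "ReplicateSummary",
    "TTestResult",
    "adsorption_ratio",
    "summarize_replicates",
    "student_t_test",
    "significance_stars",
    "read_observation_table",
    "summarize_observations",
    "pairwise_tests",
]


@dataclass(frozen=True)
class AdsorptionObservation:
    """One replicate of one serotype × surface × buffer condition."""

    serotype: str
    surface_id: str
    buffer_id: str
    titer_before: float  # vg/mL
    titer_after: float  # vg/mL
    ratio: float = float("nan")  # percent, clamped to [0, 100]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ratio", adsorption_ratio(self.titer_before, self.titer_after)
        )


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float  # percent
    sd: float  # percent, sample sd (n−1); 0 when n = 1
    n: int


class TTestResult(NamedTuple):
    t: float
    p: float
    stars: str


def adsorption_ratio(titer_before: float, titer_after: float) -> float:
    """Percent titer loss, clamped below at 0 (negative = measurement error)."""
    before = np.asarray(titer_before, dtype=float)
    after = np.asarray(titer_after, dtype=float)
    if (before <= 0).any():
        raise ValueError("titer_before must be positive")
    if (after < 0).any():
        raise ValueError("titer_after must be non-negative")
    ratio = 100.0 * (before - after) / before
    # lower clamp is the measurement-error rule; the upper cap only
    # guards against fp overshoot (after >= 0 already bounds it at 100)
    ratio = np.clip(ratio, 0.0, 100.0)
    return float(ratio) if ratio.ndim == 0 else ratio


def summarize_replicates(ratios: Sequence[float]) -> ReplicateSummary:
    """Mean and sample standard deviation (n−1 denominator) of replicates."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates to summarize")
    sd = 0.0 if arr.size == 1 else float(np.std(arr, ddof=1))
    return ReplicateSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def student_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-tailed unpaired Student's t-test (pooled variance).

    Degenerate case: both groups constant with equal means → t = 0, p = 1;
    constant groups with different means → infinite t, p = 0.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, "")
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t, 0.0, significance_stars(0.0))
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), significance_stars(float(p)))


# ---------------------------------------------------------------------------
# tidy-table interface

GROUP_KEYS = ["serotype", "surface_id", "buffer_id"]


def read_observation_table(path) -> pd.DataFrame:
    """Read replicate observations; computes the clamped ratio from
    titers when a precomputed ``ratio_percent`` column is absent."""
    df = pd.read_csv(path)
    if "ratio_percent" not in df.columns:
        for col in ("titer_before_vg_ml", "titer_after_vg_ml"):
            if col not in df.columns:
                raise ValueError(f"observation table needs {col} or ratio_percent")
        df["ratio_percent"] = adsorption_ratio(
            df["titer_before_vg_ml"].to_numpy(), df["titer_after_vg_ml"].to_numpy()
        )
    return df


def summarize_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean ± sd (n) of replicate adsorption ratios."""
    def _agg(g: pd.Series) -> pd.Series:
        s = summarize_replicates(g.to_numpy())
        return pd.Series({"mean_percent": s.mean, "sd_percent": s.sd, "n": s.n})

    out = df.groupby(GROUP_KEYS, sort=True)["ratio_percent"].apply(_agg).unstack()
    out["n"] = out["n"].astype(int)
    return out.reset_index()


def pairwise_tests(
    df: pd.DataFrame, compare: str = "surface_id"
) -> pd.DataFrame:
    """Student's t-test between every pair of levels of ``compare``
    within each combination of the remaining grouping keys."""
    other = [k for k in GROUP_KEYS if k != compare]
    rows = []
    for keys, sub in df.groupby(other, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        levels = sorted(sub[compare].unique())
        for i, la in enumerate(levels):
            for lb in levels[i + 1 :]:
                ga = sub.loc[sub[compare] == la, "ratio_percent"]
                gb = sub.loc[sub[compare] == lb, "ratio_percent"]
                if len(ga) < 2 or len(gb) < 2:
                    continue
                res = student_t_test(ga, gb)
                rows.append(
                    dict(zip(other, keys))
                    | {f"{compare}_a": la, f"{compare}_b": lb,
                       "t": res.t, "p": res.p, "stars": res.stars}
                )
    return pd.DataFrame(rows)
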