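"""Normative comparison statistics.

* z-scores of patient measures against eccentricity-matched normative
  means/SDs, with the abnormality rule ``z < -2`` (strict);
* two-sample Wilcoxon rank-sum test with midranks for ties, exact
  small-sample p-values by complete enumeration of rank assignments,
  or a continuity-corrected normal approximation with tie-corrected
  variance;
* intrarater reliability as ICC(A,1) — two-way model, absolute
  agreement, single rater — with the F-distribution 95% confidence
  interval of McGraw & Wong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormativeTable",
    "ZScoreResult",
    "ICCResult",
    "zscore",
    "wilcoxon_rank_sum",
    "icc_a1",
]

MEASURES = ("cone_density", "rpe_density", "rt", "orl", "rpe_area")


@dataclass
class NormativeTable:
    """Healthy-control means/SDs indexed by measure, eccentricity, meridian."""

    table: pd.DataFrame  # columns: measure, eccentricity_mm, meridian, mean, sd, n

    REQUIRED = ("measure", "eccentricity_mm", "meridian", "mean", "sd", "n")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"normative table missing columns {missing}")
        if (self.table["sd"] <= 0).any():
            raise ValueError("normative SDs must be positive")
        if (self.table["n"] < 2).any():
            raise ValueError("normative n must be >= 2")
        keys = self.table[["measure", "eccentricity_mm", "meridian"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (measure, eccentricity, meridian) keys")

    @classmethod
    def from_csv(cls, path) -> "NormativeTable":
        return cls(pd.read_csv(path))

    def lookup(
        self,
        measure: str,
        eccentricity_mm: float,
        meridian: str,
        tolerance_mm: float = 0.15,
    ) -> tuple[float, float]:
        sub = self.table[
            (self.table["measure"] == measure)
            & (self.table["meridian"] == meridian)
        ]
        if sub.empty:
            raise KeyError(
                f"no normative rows for ({measure}, {meridian}); available: "
                f"{sorted(set(zip(self.table['measure'], self.table['meridian'])))}"
            )
        d = (sub["eccentricity_mm"] - eccentricity_mm).abs()
        i = d.idxmin()
        if d[i] > tolerance_mm:
            raise KeyError(
                f"no normative eccentricity within {tolerance_mm} mm of "
                f"{eccentricity_mm} mm for ({measure}, {meridian}); rows at "
                f"{sorted(sub['eccentricity_mm'])}"
            )
        return float(sub.loc[i, "mean"]), float(sub.loc[i, "sd"])


@dataclass(frozen=True)
class ZScoreResult:
    value: float
    normal_mean: float
    normal_sd: float
    z: float
    abnormal: bool


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way, absolute agreement, single rater"


def zscore(
    value: float,
    table: NormativeTable,
    measure: str,
    eccentricity_mm: float,
    meridian: str,
    tolerance_mm: float = 0.15,
) -> ZScoreResult:
    """Number of normative SDs a measure lies from the normal mean.

    ``abnormal`` is True iff ``z < -2`` (strict inequality).
    """
    mean, sd = table.lookup(measure, eccentricity_mm, meridian, tolerance_mm)
    z = (value - mean) / sd
    return ZScoreResult(
        value=value, normal_mean=mean, normal_sd=sd, z=z, abnormal=bool(z < -2.0)
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank sum

@lru_cache(maxsize=32)
def _exact_null_pmf(ranks: tuple[float, ...], n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the x-sample rank sum by complete enumeration.

    Enumerates all C(n+m, n) assignments of the (mid)ranks to the first
    sample; returns (unique rank sums, probabilities).
    """
    r = np.asarray(ranks)
    sums = np.fromiter(
        (sum(c) for c in combinations(r, n)), dtype=float,
        count=math.comb(len(r), n),
    )
    vals, counts = np.unique(np.round(sums, 9), return_counts=True)
    return vals, counts / counts.sum()


def wilcoxon_rank_sum(
    x, y, mode: str = "exact"
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (two-sided).

    Returns ``(W, p)`` where W is the rank sum of ``x`` using midranks
    for ties.  ``mode="exact"`` enumerates all rank assignments
    (feasible for combined n <= 20); ``mode="normal_approx"`` uses the
    continuity-corrected normal approximation with tie-corrected
    variance.  The two-sided exact p is the null probability of a rank
    sum at least as far from its mean as observed.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(n * (n + m + 1) / 2.0), 1.0
    ranks = sps.rankdata(combined)  # midranks
    w = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0
    if mode == "exact":
        if n + m > 20:
            raise ValueError("exact mode feasible only for combined n <= 20")
        vals, probs = _exact_null_pmf(tuple(np.sort(ranks)), n)
        dev = abs(w - mu)
        p = float(probs[np.abs(vals - mu) >= dev - 1e-9].sum())
        return w, min(p, 1.0)
    if mode == "normal_approx":
        # tie-corrected variance
        _, counts = np.unique(combined, return_counts=True)
        tie = float((counts**3 - counts).sum())
        nm = n + m
        var = n * m / 12.0 * ((nm + 1) - tie / (nm * (nm - 1)))
        if var <= 0:
            return w, 1.0
        d = w - mu
        d -= math.copysign(0.5, d) if d != 0 else 0.0  # continuity correction
        z = d / math.sqrt(var)
        return w, float(2.0 * sps.norm.sf(abs(z)))
    raise ValueError("mode must be 'exact' or 'normal_approx'")


# ---------------------------------------------------------------------------
# ICC(A,1)

def icc_a1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single rater.

    ``ratings`` is subjects x sessions with no missing cells.  The
    point estimate is ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)``
    from the two-way ANOVA mean squares (rows = subjects, columns =
    sessions); the confidence interval follows McGraw & Wong's
    F-distribution method.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (subjects >= 2) x (sessions >= 2)")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must have no missing cells")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr <= mse and msc <= mse and math.isclose(denom, 0.0)):
        raise ValueError("zero between-subject variance: ICC undefined")
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1)
    if mse == 0 and msc == 0:
        return ICCResult(icc=icc, ci_low=icc, ci_high=icc)
    r = icc
    a = k * r / (n * (1.0 - r)) if r < 1 else float("inf")
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r < 1 else float("inf")
    if math.isinf(a) or math.isinf(b):
        return ICCResult(icc=icc, ci_low=icc, ci_high=icc)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (
        n * (msr - f_u * mse)
        / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    hi = (
        n * (f_l * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    )
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi))
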