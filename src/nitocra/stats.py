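"""Exact contingency-table statistics and verification comparisons.

The categorical endpoints of the life-cycle experiments — stage mortality
(alive/dead) and sex ratio (female/male) per treatment — are compared with
the Fisher-Freeman-Halton exact test: the extension of Fisher's exact test
to r x c tables by complete enumeration of all tables sharing the observed
margins.  The two-sided p-value is the total multivariate hypergeometric
probability of tables no more probable than the observed one (the
convention of mainstream statistical software, e.g. R's ``fisher.test``),
with a relative tie tolerance of 1e-7.

Also here: summary descriptors (mean, sample SD, n; the copepodite-to-
naupliar duration ratio Dc/Dn), the one-sided one-sample t-test used to
compare simulated reproduction output with its theoretical values, and the
fraction of observations covered by a Monte-Carlo confidence band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable", "fisher_exact_rxc", "enumerate_table_probabilities",
    "SummaryDescriptors", "summary_descriptors", "dc_dn_ratio",
    "TTestResult", "one_sample_t", "ci_coverage",
]

#: Guard on the number of candidate tables enumerated.
ENUMERATION_GUARD = 10_000_000


@dataclass(frozen=True)
class ContingencyTable:
    """An r x 2 table of non-negative integer counts.

    Rows are treatments; the two columns are the outcome categories
    (alive/dead or female/male).
    """

    counts: tuple
    row_labels: Optional[tuple] = None
    column_labels: Optional[tuple] = None

    @classmethod
    def from_array(cls, counts, row_labels=None, column_labels=None
                   ) -> "ContingencyTable":
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError(f"expected an r x 2 table with r >= 2, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = arr.astype(int)
        return cls(counts=tuple(map(tuple, arr.tolist())),
                   row_labels=tuple(row_labels) if row_labels else None,
                   column_labels=tuple(column_labels) if column_labels else None)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def _as_array(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.to_array()
    return ContingencyTable.from_array(table).to_array()


def _log_choose(n: float, k: float) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _iter_first_column(rows: Sequence[int], col1: int):
    """All vectors k with 0 <= k_i <= rows[i] and sum(k) = col1."""
    r = len(rows)
    suffix = np.concatenate([np.cumsum(rows[::-1])[::-1][1:], [0]])

    def rec(i, remaining, acc):
        if i == r - 1:
            if 0 <= remaining <= rows[i]:
                yield acc + (remaining,)
            return
        lo = max(0, remaining - int(suffix[i]))
        hi = min(rows[i], remaining)
        for k in range(lo, hi + 1):
            yield from rec(i + 1, remaining - k, acc + (k,))

    yield from rec(0, col1, ())


def _count_tables(rows: Sequence[int], col1: int) -> float:
    """Number of margin-preserving tables (bounded compositions of `col1`
    over the row totals), by dynamic programming.  Float64 precision is
    ample for the guard comparison."""
    dp = np.zeros(col1 + 1)
    dp[0] = 1.0
    for cap in rows:
        new = np.zeros_like(dp)
        running = np.concatenate([[0.0], np.cumsum(dp)])
        for s in range(col1 + 1):
            lo = max(0, s - cap)
            new[s] = running[s + 1] - running[lo]
        dp = new
    return float(dp[col1])


def enumerate_table_probabilities(table) -> pd.DataFrame:
    """Enumerate every r x 2 table with the observed margins and its
    multivariate hypergeometric probability.  The probabilities sum to 1;
    this is the building block of :func:`fisher_exact_rxc` and is exposed
    for verification."""
    arr = _as_array(table)
    if arr[:, 0].sum() > arr[:, 1].sum():
        arr = arr[:, ::-1]  # enumerate over the smaller column margin
    rows = arr.sum(axis=1)
    col1 = int(arr[:, 0].sum())
    n = int(rows.sum())
    candidates = _count_tables([int(r) for r in rows], col1)
    if candidates > ENUMERATION_GUARD:
        raise ValueError(
            f"enumeration guard exceeded: ~{candidates:.3g} candidate tables "
            f"(limit {ENUMERATION_GUARD})")
    denom = _log_choose(n, col1)
    records = []
    for ks in _iter_first_column([int(r) for r in rows], col1):
        logp = sum(_log_choose(r, k) for r, k in zip(rows, ks)) - denom
        records.append({"first_column": ks, "log_probability": logp,
                        "probability": math.exp(logp)})
    return pd.DataFrame(records)


def fisher_exact_rxc(table, tie_tolerance: float = 1e-7) -> float:
    """Two-sided Fisher-Freeman-Halton exact p-value of an r x 2 table.

    Sums the probabilities of all margin-preserving tables whose
    multivariate hypergeometric probability does not exceed the observed
    table's (within `tie_tolerance` relative, to absorb floating-point
    ties).  For 2 x 2 input this equals the classical hypergeometric
    construction.
    """
    arr = _as_array(table)
    enum = enumerate_table_probabilities(arr)
    rows = arr.sum(axis=1)
    col1 = int(arr[:, 0].sum())
    n = int(rows.sum())
    denom = _log_choose(n, col1)
    log_obs = sum(_log_choose(int(r), int(k)) for r, k in zip(rows, arr[:, 0])) - denom
    threshold = log_obs + math.log1p(tie_tolerance)
    p = float(enum.loc[enum["log_probability"] <= threshold, "probability"].sum())
    return min(p, 1.0)


class SummaryDescriptors(NamedTuple):
    mean: float
    sd: Optional[float]
    n: int


def summary_descriptors(values: Iterable[float]) -> SummaryDescriptors:
    """Arithmetic mean, sample standard deviation (n-1 denominator; ``None``
    for a single value) and n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return SummaryDescriptors(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def dc_dn_ratio(mean_copepodite: float, mean_naupliar: float) -> float:
    """Copepodite-to-naupliar mean duration ratio Dc/Dn; its constancy
    across temperatures is termed equiproportionality."""
    if mean_naupliar <= 0:
        raise ValueError("naupliar mean duration must be > 0")
    return mean_copepodite / mean_naupliar


class TTestResult(NamedTuple):
    p_value: float
    t_statistic: float
    side: str           # "less" | "greater" — alternative actually tested
    degenerate: bool    # zero-variance sample


def one_sample_t(sample: Iterable[float], theoretical_mean: float,
                 side: str = "auto") -> TTestResult:
    """One-sided one-sample t-test of a simulated sample against a
    theoretical value.

    ``side="auto"`` tests in the direction of the observed deviation (the
    direction of a reported one-sided comparison is ambiguous; testing the
    observed direction is the conservative reading — both explicit
    ``"less"``/``"greater"`` are accepted).  A sample identical to the
    theoretical constant is a degenerate pass (p = 1); zero variance with a
    non-zero deviation yields p = 0, flagged degenerate.
    """
    arr = np.asarray(list(sample), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two observations")
    if side not in ("auto", "less", "greater"):
        raise ValueError(f"side must be 'auto', 'less' or 'greater', got {side!r}")
    mean = arr.mean()
    if side == "auto":
        side = "less" if mean < theoretical_mean else "greater"
    if arr.std(ddof=1) == 0.0:
        if mean == theoretical_mean:
            return TTestResult(p_value=1.0, t_statistic=0.0, side=side, degenerate=True)
        return TTestResult(p_value=0.0,
                           t_statistic=math.copysign(math.inf, mean - theoretical_mean),
                           side=side, degenerate=True)
    res = sps.ttest_1samp(arr, popmean=theoretical_mean, alternative=side)
    return TTestResult(p_value=float(res.pvalue), t_statistic=float(res.statistic),
                       side=side, degenerate=False)


def ci_coverage(summary, observations: pd.DataFrame) -> float:
    """Fraction of observed (day, stage, count) points inside the
    Monte-Carlo 95% band of `summary`.

    `observations` needs columns ``day``, ``stage``, ``count``.  Returns
    NaN (with a warning) for an empty observation set.
    """
    required = {"day", "stage", "count"}
    if not required <= set(observations.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    if len(observations) == 0:
        warnings.warn("empty observation set: coverage undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    day_index = {int(d): i for i, d in enumerate(summary.days)}
    inside = 0
    for _, obs in observations.iterrows():
        day = int(obs["day"])
        if day not in day_index:
            raise ValueError(f"day {day} outside the simulated range")
        i = day_index[day]
        stage = obs["stage"]
        if summary.lower[stage][i] <= obs["count"] <= summary.upper[stage][i]:
            inside += 1
    return inside / len(observations)
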