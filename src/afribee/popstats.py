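"""Statistical layer: goodness-of-fit chi-squares, pooled t-tests,
the binomial site-heterogeneity test, and mitotype frequency estimation.

All chi-square tests are computed without continuity correction.  The
hive and feral-colony comparisons are one-sample goodness-of-fit tests
of an observed count against a reference proportion (two cells, df=1).
The site-heterogeneity test compares the observed counts of sites with
0..k African bees against the binomial expectation at the pooled
frequency; by the field convention reproduced here its default df is k,
although a stricter convention (df = k-1, since the frequency is
estimated from the same data) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .types import Call, DomainError, MarkerCall


class Tails(str, Enum):
    ONE = "one"
    TWO = "two"


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p_value: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float
    tails: Tails


@dataclass(frozen=True)
class FrequencyEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    n: int
    n_excluded: int


def _chi2_from_cells(observed: Sequence[float], expected: Sequence[float], df: int) -> GofResult:
    observed = tuple(float(o) for o in observed)
    expected = tuple(float(e) for e in expected)
    if any(e == 0 for e in expected):
        raise DomainError(f"expected cell is zero: {expected}")
    if any(e < 5 for e in expected):
        import warnings

        warnings.warn(
            f"expected cell below 5 ({expected}); chi-square approximation "
            "may be poor",
            stacklevel=3,
        )
    chi2 = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    return GofResult(
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        observed=observed,
        expected=expected,
    )


def gof_chisq(k_observed: int, n: int, p0: float) -> GofResult:
    """Two-cell goodness-of-fit of k successes in n against proportion p0.

    chi2 = (k - n·p0)²/(n·p0) + ((n-k) - n·(1-p0))²/(n·(1-p0)), df = 1,
    no continuity correction.
    """
    if not 0 <= k_observed <= n:
        raise DomainError(f"k={k_observed} outside [0, n={n}]")
    if not 0 < p0 < 1:
        raise DomainError(f"p0={p0} outside (0, 1)")
    return _chi2_from_cells(
        observed=(k_observed, n - k_observed),
        expected=(n * p0, n * (1 - p0)),
        df=1,
    )


def pooled_t(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    tails: Tails = Tails.TWO,
) -> TTestResult:
    """Pooled-variance two-sample t-test; df = n_a + n_b - 2.

    The one-tailed p-value is the tail probability beyond |t| (the test
    in the direction of the observed difference).  Zero pooled variance
    with equal means gives t = 0 by convention; with unequal means it is
    a domain error (infinite t).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    n_a, n_b = len(a), len(b)
    # One group of size 1 is tolerated when the other supplies >= 2
    # observations, so the pooled variance (hence df >= 1) is defined.
    if min(n_a, n_b) < 1 or max(n_a, n_b) < 2 or n_a + n_b < 3:
        raise DomainError(
            f"need at least (1, 2) observations across the groups (got {n_a}, {n_b})"
        )
    df = n_a + n_b - 2
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ss = float(((a - mean_a) ** 2).sum() + ((b - mean_b) ** 2).sum())
    sp2 = ss / df
    if sp2 == 0:
        if mean_a == mean_b:
            t = 0.0
        else:
            raise DomainError("zero pooled variance with unequal means: t is infinite")
    else:
        t = (mean_a - mean_b) / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
    if tails is Tails.TWO:
        p = 2 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(abs(t), df))
    p = min(p, 1.0)
    return TTestResult(t=t, df=df, p_value=p, mean_a=mean_a, mean_b=mean_b, tails=tails)


class DfConvention(str, Enum):
    #: df = k, as conventionally printed for this test in the field.
    PAPER = "paper"
    #: df = k - 1, accounting for p_hat being estimated from the same data.
    CONSERVATIVE = "conservative"


def heterogeneity_chisq(
    category_counts: Sequence[int],
    p_hat: float,
    df_convention: DfConvention = DfConvention.PAPER,
) -> GofResult:
    """Binomial site-heterogeneity test.

    ``category_counts[j]`` is the number of sites at which exactly j of
    the k sampled bees carried the African mitotype (k+1 cells).  The
    expected count for cell j is N_sites · C(k,j) · p̂ʲ(1-p̂)^(k-j).
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise DomainError("category_counts must be a 1-D array of k+1 cells")
    if not 0 < p_hat < 1:
        raise DomainError(f"p_hat={p_hat} outside (0, 1)")
    k = len(counts) - 1
    n_sites = counts.sum()
    expected = n_sites * stats.binom.pmf(np.arange(k + 1), k, p_hat)
    df = k if df_convention is DfConvention.PAPER else k - 1
    return _chi2_from_cells(counts, expected, df)


def estimate_frequency(calls: Iterable[MarkerCall]) -> FrequencyEstimate:
    """African-mitotype frequency with a Wilson 95% confidence interval.

    Only confident African/European calls enter the estimate;
    indeterminate or unresolvable calls are excluded and counted in
    ``n_excluded``.
    """
    n_african = n = n_excluded = 0
    for c in calls:
        mito = c.mitotype if c.confident else None
        if mito is None:
            n_excluded += 1
            continue
        n += 1
        if mito is Call.AFRICAN:
            n_african += 1
    if n == 0:
        raise DomainError("no confident mitotype calls to estimate from")
    lo, hi = proportion_confint(n_african, n, alpha=0.05, method="wilson")
    return FrequencyEstimate(
        p_hat=n_african / n,
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        n_excluded=n_excluded,
    )
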