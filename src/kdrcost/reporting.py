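"""Assembled reversion analysis: per-interval tests, global statistics, trend.

Mirrors the layout of a cage-study report table: one row per cage per sampled
generation with observed genotype frequencies, same-generation Hardy-Weinberg
expected frequencies, allele frequencies, the sequential HWE p-value against
the previous sampled generation, and the Monte-Carlo drift p-value; plus
Fisher-combined global statistics and an OLS trend of allele frequency on
generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drift import DriftConfig, drift_scan
from .genotype_data import CageSeries, allele_frequency, genotype_frequencies, round2
from .hwe import (
    CombinedTestResult,
    TrendFit,
    fisher_combined,
    hw_expected_freqs,
    sequential_hwe_test,
    trend_regression,
)


@dataclass(frozen=True)
class ReversionReport:
    rows: pd.DataFrame
    hwe_global: CombinedTestResult
    drift_global: CombinedTestResult
    trend: TrendFit

    def final_mean_allele_freq(self) -> float:
        """R-allele frequency at the last sampled generation, averaged over cages."""
        last = self.rows[self.rows.generation == self.rows.generation.max()]
        return float(last.p_R.mean())

    def initial_mean_allele_freq(self) -> float:
        first = self.rows[self.rows.generation == self.rows.generation.min()]
        return float(first.p_R.mean())


def reversion_analysis(
    series_list: list[CageSeries],
    drift_cfg: DriftConfig | None = None,
    hwe_df: int = 1,
) -> ReversionReport:
    """Run the full selection-vs-drift screen on a set of cage series.

    Randomness (the drift Monte-Carlo) flows from a single generator seeded by
    ``drift_cfg.seed``, consumed cage by cage in input order, intervals
    ascending, so a fixed seed reproduces the report exactly.
    """
    if drift_cfg is None:
        drift_cfg = DriftConfig()
    rng = np.random.default_rng(drift_cfg.seed)
    rows = []
    hwe_ps: list[float] = []
    drift_ps: list[float] = []
    trend_points: list[tuple[float, float]] = []
    for series in series_list:
        drift_results = {r.generation: r for r in drift_scan(series, drift_cfg, rng)}
        for i, counts in enumerate(series):
            gf = genotype_frequencies(counts)
            af = allele_frequency(counts)
            ef = hw_expected_freqs(af)
            trend_points.append((counts.generation, af.p_R))
            row = {
                "cage_id": series.cage_id,
                "generation": counts.generation,
                "n": counts.n,
                "f_SS": gf.f_SS, "f_RS": gf.f_RS, "f_RR": gf.f_RR,
                "e_SS": ef.f_SS, "e_RS": ef.f_RS, "e_RR": ef.f_RR,
                "p_S": af.p_S, "p_R": af.p_R,
                "hwe_chi2": np.nan, "hwe_p": np.nan, "drift_p": np.nan,
            }
            if i > 0:
                hwe = sequential_hwe_test(series.samples[i - 1], counts, df=hwe_df)
                row["hwe_chi2"], row["hwe_p"] = hwe.chi2, hwe.p
                hwe_ps.append(hwe.p)
                drift = drift_results[counts.generation]
                row["drift_p"] = drift.p
                drift_ps.append(drift.p)
            rows.append(row)
    frame = pd.DataFrame(rows)
    return ReversionReport(
        rows=frame,
        hwe_global=fisher_combined(hwe_ps),
        drift_global=fisher_combined(drift_ps),
        trend=trend_regression(trend_points),
    )


def render_display_table(report: ReversionReport) -> pd.DataFrame:
    """The report rows with frequencies rounded to the 2-dp display convention."""
    disp = report.rows.copy()
    for col in ("f_SS", "f_RS", "f_RR", "e_SS", "e_RS", "e_RR", "p_S", "p_R"):
        disp[col] = disp[col].map(round2)
    for col in ("hwe_p", "drift_p"):
        disp[col] = disp[col].map(lambda p: np.nan if pd.isna(p) else round(p, 3))
    return disp


def report_summary(report: ReversionReport) -> dict:
    """Machine-readable global summary (Fisher statistics and trend)."""
    return {
        "hwe_global": {
            "k": report.hwe_global.k,
            "chi2": report.hwe_global.chi2,
            "df": report.hwe_global.df,
            "p": report.hwe_global.global_p,
        },
        "drift_global": {
            "k": report.drift_global.k,
            "chi2": report.drift_global.chi2,
            "df": report.drift_global.df,
            "p": report.drift_global.global_p,
        },
        "trend_ols": {
            "slope_per_generation": report.trend.slope,
            "intercept": report.trend.intercept,
            "r_squared": report.trend.r_squared,
            "F": report.trend.f_stat,
            "df": list(report.trend.df),
            "p": report.trend.p,
        },
        "mean_allele_freq": {
            "initial": report.initial_mean_allele_freq(),
            "final": report.final_mean_allele_freq(),
        },
    }
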