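"""Fitness-cost analyses for insecticide-resistance alleles in *Aedes aegypti*.

Two complementary analyses of the cost of pyrethroid resistance:

* **Allele competition (cage reversion)** — sequential Hardy-Weinberg
  chi-square tests, a Wright-Fisher drift Monte-Carlo null, Fisher's combined
  probability, and allele-frequency trend regression
  (:mod:`~kdrcost.genotype_data`, :mod:`~kdrcost.hwe`, :mod:`~kdrcost.drift`,
  :mod:`~kdrcost.reporting`).
* **Life table / population growth** — R0, the Euler-Lotka intrinsic rate of
  increase, generation time, fitness-cost ratios, an additivity ANOVA, and
  mating-competition paternity inference (:mod:`~kdrcost.lifetable`,
  :mod:`~kdrcost.mating`).

:mod:`~kdrcost.simulate` generates synthetic versions of all three data
streams with known ground truth.
"""

from importlib import resources
from pathlib import Path

from .drift import DriftConfig, DriftTestResult, FitnessSpec, drift_pvalue, drift_scan, wright_fisher_trajectory
from .genotype_data import (
    AlleleFreq,
    CageSeries,
    GenotypeCounts,
    GenotypeFreqs,
    allele_frequency,
    counts_from_frequencies,
    genotype_frequencies,
    read_genotype_table,
    round2,
    write_genotype_table,
)
from .hwe import fisher_combined, hw_expected_freqs, sequential_hwe_test, trend_regression
from .lifetable import (
    DailyCohortRecord,
    GrowthSummary,
    LifeSchedule,
    StrainVitals,
    additivity_anova,
    build_schedule,
    fitness_cost_ratio,
    generation_time,
    growth_summary,
    intrinsic_rate,
    kaplan_meier_survivorship,
    net_reproductive_rate,
)
from .mating import MatingTrial, SireTally, infer_sire, preference_test, read_mating_table, tally_sires
from .reporting import ReversionReport, render_display_table, report_summary, reversion_analysis
from .simulate import (
    CageSimConfig,
    CohortSimConfig,
    MatingSimConfig,
    simulate_cage_experiment,
    simulate_life_table,
    simulate_mating_trials,
)

__version__ = "0.1.0"


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture CSV (``kr_table2.csv``, ``ckr_table3.csv``, ...)."""
    return Path(resources.files("kdrcost") / "data" / name)
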