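"""Paternity inference and mate-preference testing for mating-competition trials.

*Aedes aegypti* females mate once, so the genotypes of a female's offspring at
the *kdr* locus identify her mate's class.  A homozygous-susceptible (SS)
mother produces only RS offspring by a *kdr*-homozygous (RR) sire and only SS
offspring by a susceptible sire; an RR mother produces only RR or only RS
offspring respectively.  Offspring sets impossible under single mating are
flagged as inconsistent, excluded from tallies, and counted.  Only the
kdr-carrier vs non-carrier distinction is observable: CYP-mediated resistance
has no trackable marker.

Preference is tested with an exact two-sided binomial test of the resistant-
sired fraction against a null proportion (default 0.5, no preference).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, SchemaError, ValidationError

GENOTYPES = ("SS", "RS", "RR")
#: offspring genotypes possible for (mother genotype, sire class)
_EXPECTED_OFFSPRING = {
    ("SS", "susceptible"): "SS",
    ("SS", "resistant"): "RS",
    ("RR", "susceptible"): "RS",
    ("RR", "resistant"): "RR",
}
_MOTHER_GENOTYPE = {"susceptible": "SS", "resistant": "RR"}


@dataclass(frozen=True)
class MatingTrial:
    """One replicate cage: per-female offspring genotype sets."""

    replicate: str
    female_strain: str  # "susceptible" or "resistant"
    offspring: tuple[tuple[str, ...], ...]  # one inner tuple per female

    def __post_init__(self) -> None:
        if self.female_strain not in _MOTHER_GENOTYPE:
            raise ValidationError(
                f"female_strain must be 'susceptible' or 'resistant', got {self.female_strain!r}"
            )
        if any(len(o) < 1 for o in self.offspring):
            raise ValidationError("every female needs at least one genotyped offspring")


@dataclass(frozen=True)
class SireTally:
    n_resistant_sired: int = 0
    n_susceptible_sired: int = 0
    n_inconsistent: int = 0

    def __add__(self, other: "SireTally") -> "SireTally":
        return SireTally(
            self.n_resistant_sired + other.n_resistant_sired,
            self.n_susceptible_sired + other.n_susceptible_sired,
            self.n_inconsistent + other.n_inconsistent,
        )

    @property
    def n_informative(self) -> int:
        return self.n_resistant_sired + self.n_susceptible_sired


@dataclass(frozen=True)
class PreferenceTestResult:
    proportion_resistant: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    null_prop: float


def infer_sire(female_strain: str, offspring_genotypes: Sequence[str]) -> str:
    """Classify a female's mate as 'resistant', 'susceptible' or 'inconsistent'.

    Deterministic and order-invariant in the offspring.  Any offspring
    genotype impossible from the mother under single mating, or a mixture of
    classes implying two sires, yields 'inconsistent'.
    """
    if female_strain not in _MOTHER_GENOTYPE:
        raise ValidationError(f"unknown female strain {female_strain!r}")
    mother = _MOTHER_GENOTYPE[female_strain]
    seen = set(offspring_genotypes)
    if not seen:
        raise DegenerateInputError("no offspring genotypes supplied")
    bad = seen - set(GENOTYPES)
    if bad:
        raise ValidationError(f"unknown genotype token(s): {sorted(bad)}")
    for sire in ("resistant", "susceptible"):
        if seen == {_EXPECTED_OFFSPRING[(mother, sire)]}:
            return sire
    return "inconsistent"


def tally_sires(trials: Iterable[MatingTrial]) -> SireTally:
    """Pool sire classifications over trials, counting excluded inconsistencies."""
    tally = SireTally()
    for trial in trials:
        for offspring in trial.offspring:
            sire = infer_sire(trial.female_strain, offspring)
            tally = tally + SireTally(
                n_resistant_sired=int(sire == "resistant"),
                n_susceptible_sired=int(sire == "susceptible"),
                n_inconsistent=int(sire == "inconsistent"),
            )
    return tally


def preference_test(t: SireTally, null_prop: float = 0.5) -> PreferenceTestResult:
    """Exact two-sided binomial test of the resistant-sired fraction.

    Two-sided in the minimum-likelihood sense (outcomes with probability at
    most that of the observed count are summed), with an exact (Clopper-
    Pearson) 95% CI on the proportion.
    """
    if t.n_informative < 1:
        raise DegenerateInputError("no informative females (all inconsistent or empty)")
    if not (0.0 < null_prop < 1.0):
        raise ValidationError("null_prop must be in (0,1)")
    res = stats.binomtest(t.n_resistant_sired, t.n_informative, null_prop)
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return PreferenceTestResult(
        proportion_resistant=t.n_resistant_sired / t.n_informative,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p=float(res.pvalue),
        n=t.n_informative,
        null_prop=null_prop,
    )


def read_mating_table(path: str | Path) -> list[MatingTrial]:
    """Read mating-trial CSV: replicate,female_strain,female_id,offspring1_genotype,offspring2_genotype,...

    Any number of ``offspring<i>_genotype`` columns is accepted; blank cells
    are allowed as long as each female keeps at least one genotyped offspring.
    """
    df = pd.read_csv(path)
    required = ("replicate", "female_strain", "female_id")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    off_cols = [c for c in df.columns if c.startswith("offspring") and c.endswith("_genotype")]
    if not off_cols:
        raise SchemaError(f"{path}: no offspring<i>_genotype columns")
    trials = []
    for (rep, strain), grp in df.groupby(["replicate", "female_strain"], sort=False):
        offspring = []
        for _, row in grp.iterrows():
            genos = tuple(str(row[c]) for c in off_cols if pd.notna(row[c]))
            offspring.append(genos)
        trials.append(MatingTrial(replicate=str(rep), female_strain=str(strain), offspring=tuple(offspring)))
    return trials
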