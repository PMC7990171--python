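"""Synthetic-data generators with known ground truth for the three study designs.

Each generator emulates one data stream of the fitness-cost study — replicate
cage populations under genotype-dependent viability selection plus binomial
drift with periodic genotyping subsamples; daily adult-female cohort schedules
with an analytically known net reproductive rate; and single-mating
competition trials with a known preference parameter — and returns both the
observable records (compatible with the package's CSV readers) and the hidden
truth, powering parameter-recovery and calibration tests.

All generators follow the seed contract: identical (config, seed) gives
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drift import FitnessSpec, NEUTRAL
from .errors import ValidationError
from .genotype_data import CageSeries, GenotypeCounts, _largest_remainder
from .lifetable import DailyCohortRecord, LifeSchedule, StrainVitals, intrinsic_rate, net_reproductive_rate
from .mating import MatingTrial, GENOTYPES

#: founder genotype compositions (f_SS, f_RS, f_RR) of the two reciprocal-cross
#: designs: a clean F1 (all heterozygous) and one with the ~7% homozygous-
#: susceptible contamination seen when the resistant parent strain is not
#: fully homozygous.
FOUNDER_PRESETS = {
    "CKR-cross": (0.0, 1.0, 0.0),
    "KR-cross": (0.07, 0.93, 0.0),
}


@dataclass(frozen=True)
class CageSimConfig:
    N: int = 800
    founder: tuple[float, float, float] = FOUNDER_PRESETS["CKR-cross"]
    fitness: FitnessSpec = NEUTRAL
    sampled_generations: tuple[int, ...] = (1, 3, 5, 7, 9)
    sample_size: int = 90
    n_cages: int = 4
    seed: int | None = None
    #: "viability" applies selection before reproduction each generation;
    #: "fecundity" weights gamete contributions instead (same allele-frequency
    #: recursion, provided for explicitness).
    selection_mode: str = "viability"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if abs(sum(self.founder) - 1.0) > 1e-9:
            raise ValidationError("founder frequencies must sum to 1")
        if self.sample_size > 2 * self.N:
            raise ValidationError("sample size exceeds available individuals")
        if self.selection_mode not in ("viability", "fecundity"):
            raise ValidationError("selection_mode must be 'viability' or 'fecundity'")
        if any(g < 1 for g in self.sampled_generations) or list(self.sampled_generations) != sorted(
            set(self.sampled_generations)
        ):
            raise ValidationError("sampled generations must be strictly increasing and >= 1")


@dataclass(frozen=True)
class CohortSimConfig:
    """Adult-female cohort generator: Gompertz daily mortality, periodic oviposition.

    The daily death hazard is h(x) = a*exp(b*x) (capped at 1); eggs are laid
    every ``oviposition_interval`` days (the gonotrophic cycle set by the
    blood-feeding cadence), Poisson(``eggs_per_event``) per living female.
    """

    n0: int = 50
    gompertz_a: float = 0.01
    gompertz_b: float = 0.08
    oviposition_interval: int = 3
    eggs_per_event: float = 80.0
    egg_viability: float = 0.75
    sex_ratio_female: float = 0.5
    replicates: int = 3
    max_days: int = 80
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n0 < 1 or self.replicates < 1 or self.max_days < 1:
            raise ValidationError("n0, replicates, max_days must be >= 1")
        if self.gompertz_a < 0 or self.gompertz_b < 0:
            raise ValidationError("hazard parameters must be non-negative")
        if not (0 <= self.egg_viability <= 1 and 0 <= self.sex_ratio_female <= 1):
            raise ValidationError("viability and sex ratio must be proportions")

    def hazard(self, day: np.ndarray | float) -> np.ndarray:
        return np.minimum(1.0, self.gompertz_a * np.exp(self.gompertz_b * np.asarray(day, dtype=float)))

    def analytic_schedule(self) -> LifeSchedule:
        """The expectation schedule implied by the parameters (no sampling noise)."""
        days = np.arange(1, self.max_days + 1)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - self.hazard(days))])[: self.max_days]
        m = np.where(days % self.oviposition_interval == 0, self.eggs_per_event, 0.0)
        m = m * self.egg_viability * self.sex_ratio_female
        return LifeSchedule(tuple(int(d) for d in days), tuple(surv), tuple(m))

    def true_R0(self) -> float:
        return net_reproductive_rate(self.analytic_schedule())

    def true_r(self) -> float:
        return intrinsic_rate(self.analytic_schedule())


@dataclass(frozen=True)
class MatingSimConfig:
    females_per_replicate: int = 25
    replicates: int = 14
    theta: float = 0.5  # probability a female mates a resistant male
    offspring_per_female: int = 2
    female_strain: str = "susceptible"
    error_rate: float = 0.0  # per-female probability of an inconsistent offspring set
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValidationError("theta must be in [0,1]")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValidationError("error_rate must be in [0,1]")
        if self.females_per_replicate < 1 or self.replicates < 1 or self.offspring_per_female < 1:
            raise ValidationError("counts must be >= 1")


def _pair_gametes(n_R: int, N: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly pair 2N allele copies (n_R of them R) into N diploid genotypes.

    Returns counts (n_SS, n_RS, n_RR).
    """
    alleles = np.zeros(2 * N, dtype=np.int8)
    alleles[:n_R] = 1
    rng.shuffle(alleles)
    g = alleles[0::2] + alleles[1::2]
    return np.bincount(g, minlength=3)


def simulate_cage_experiment(cfg: CageSimConfig) -> tuple[list[CageSeries], dict]:
    """Replicate cage populations under selection + drift with genotyping subsamples.

    Each cage generation: viability selection reweights the current genotype
    proportions, gametes form at the post-selection allele frequency, 2N
    allele copies are drawn binomially (drift) and paired at random into N
    zygotes.  At sampled generations a genotyping subsample of ``sample_size``
    individuals is drawn multinomially from the current genotype proportions.

    Returns the observable cage series plus a truth ledger with the true
    R-allele frequency per cage per generation.
    """
    rng = np.random.default_rng(cfg.seed)
    series: list[CageSeries] = []
    truth: dict = {"allele_freq": {}, "config": cfg}
    w = cfg.fitness
    for cage_idx in range(cfg.n_cages):
        cage_id = f"C{cage_idx + 1}"
        # founders are released in fixed numbers, not sampled
        counts = np.asarray(_largest_remainder(cfg.founder, cfg.N), dtype=np.int64)
        samples = []
        true_freqs = {}
        weights = np.array([w.w_SS, w.w_RS, w.w_RR])
        for gen in range(1, max(cfg.sampled_generations) + 1):
            props = counts / cfg.N
            # viability selection acts on zygotes before adults are genotyped
            # or reproduce; in fecundity mode the adults genotyped are the
            # unselected zygotes and the weights act on gamete output only
            wprops = props * weights
            if wprops.sum() == 0:
                raise ValidationError("selection eliminated the whole population")
            props_sel = wprops / wprops.sum()
            adult_props = props if cfg.selection_mode == "fecundity" else props_sel
            p_gamete = props_sel[2] + 0.5 * props_sel[1]
            true_freqs[gen] = float(adult_props[2] + 0.5 * adult_props[1])
            if gen in cfg.sampled_generations:
                obs = rng.multinomial(cfg.sample_size, adult_props)
                samples.append(
                    GenotypeCounts(cage_id=cage_id, generation=gen,
                                   n_SS=int(obs[0]), n_RS=int(obs[1]), n_RR=int(obs[2]))
                )
            if gen == max(cfg.sampled_generations):
                break
            n_R = rng.binomial(2 * cfg.N, p_gamete)
            counts = _pair_gametes(int(n_R), cfg.N, rng)
        series.append(CageSeries(cage_id=cage_id, samples=tuple(samples)))
        truth["allele_freq"][cage_id] = true_freqs
    return series, truth


def simulate_life_table(
    cfg: CohortSimConfig,
) -> tuple[list[list[DailyCohortRecord]], StrainVitals, dict]:
    """Daily cohort records for each replicate, plus vitals and analytic truth.

    Individual lifespans are drawn from the discretised Gompertz hazard; on
    every oviposition day each living female lays Poisson-distributed eggs.
    The truth dict carries the analytic R0 and r implied by the parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    replicates = []
    for _ in range(cfg.replicates):
        alive = np.ones(cfg.n0, dtype=bool)
        records = []
        for day in range(1, cfg.max_days + 1):
            n_alive = int(alive.sum())
            if n_alive == 0:
                break
            eggs = 0.0
            if day % cfg.oviposition_interval == 0:
                eggs = float(rng.poisson(cfg.eggs_per_event, size=n_alive).sum())
            records.append(DailyCohortRecord(day=day, n_alive=n_alive, eggs=eggs))
            dies = rng.random(cfg.n0) < float(cfg.hazard(day))
            alive &= ~dies
        replicates.append(records)
    vitals = StrainVitals(
        egg_viability=cfg.egg_viability, sex_ratio_female=cfg.sex_ratio_female, n0=cfg.n0
    )
    truth = {"R0": cfg.true_R0(), "r": cfg.true_r(), "config": cfg}
    return replicates, vitals, truth


def simulate_mating_trials(cfg: MatingSimConfig) -> tuple[list[MatingTrial], dict]:
    """Mating-competition trials: each female's sire is Bernoulli(theta) resistant.

    Offspring genotypes follow Mendelian rules from (mother strain, sire
    class); with probability ``error_rate`` a female's offspring set is
    corrupted into an inconsistent one (a genotyping-error stand-in).
    """
    rng = np.random.default_rng(cfg.seed)
    mother = "SS" if cfg.female_strain == "susceptible" else "RR"
    trials = []
    n_resistant_true = 0
    for rep in range(cfg.replicates):
        offspring = []
        for _ in range(cfg.females_per_replicate):
            resistant_sire = rng.random() < cfg.theta
            n_resistant_true += int(resistant_sire)
            if mother == "SS":
                geno = "RS" if resistant_sire else "SS"
            else:
                geno = "RR" if resistant_sire else "RS"
            genos = [geno] * cfg.offspring_per_female
            if cfg.error_rate and rng.random() < cfg.error_rate:
                # corrupt one offspring to a genotype impossible for the cross
                impossible = [g for g in GENOTYPES if g != geno]
                genos[int(rng.integers(len(genos)))] = impossible[int(rng.integers(len(impossible)))]
            offspring.append(tuple(genos))
        trials.append(
            MatingTrial(replicate=f"R{rep + 1}", female_strain=cfg.female_strain, offspring=tuple(offspring))
        )
    truth = {"theta": cfg.theta, "n_resistant_sired_true": n_resistant_true, "config": cfg}
    return trials, truth
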