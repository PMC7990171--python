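"""Wright-Fisher forward simulation and the Monte-Carlo genetic-drift null test.

The null model for a cage interval is a diploid, panmictic population of fixed
census size N (default 800, the cage census) evolving neutrally: each
generation the 2N allele copies of the next generation are drawn binomially at
the current allele frequency.  Genotyping happened every other cage
generation, so one genotyping interval spans two Wright-Fisher generations by
default.  The empirical p-value for an interval is the fraction of simulated
endpoints at least as extreme as the observed final frequency, in the
direction of the observed change; ties count as extreme.  The genotyping
subsample's binomial noise is deliberately NOT added on top of drift — the
pure-drift null is the convention this test calibrates against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .genotype_data import CageSeries, allele_frequency


@dataclass(frozen=True)
class DriftConfig:
    """Null-model settings for the drift test."""

    N: int = 800
    n_sims: int = 10_000
    generations_per_interval: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError(f"N must be >= 1, got {self.N}")
        if self.n_sims < 1:
            raise ValidationError(f"n_sims must be >= 1, got {self.n_sims}")
        if self.generations_per_interval < 1:
            raise ValidationError("generations_per_interval must be >= 1")


@dataclass(frozen=True)
class FitnessSpec:
    """Relative viabilities of the three genotypes (w_SS, w_RS, w_RR)."""

    w_SS: float = 1.0
    w_RS: float = 1.0
    w_RR: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_SS, self.w_RS, self.w_RR) < 0 or max(self.w_SS, self.w_RS, self.w_RR) <= 0:
            raise ValidationError("fitnesses must be non-negative with max > 0")

    @property
    def is_neutral(self) -> bool:
        return self.w_SS == self.w_RS == self.w_RR


NEUTRAL = FitnessSpec()


@dataclass(frozen=True)
class DriftTestResult:
    cage_id: str
    generation: int  # generation label at the end of the interval
    p0: float
    p_obs: float
    direction: str  # "increase" | "decrease" | "none"
    p: float
    n_sims: int
    config: DriftConfig = field(repr=False, default=DriftConfig())


def _selection_step(p: np.ndarray | float, w: FitnessSpec):
    """Deterministic viability selection on Hardy-Weinberg genotype proportions.

    Returns the post-selection R-allele frequency. p is the R frequency.
    """
    q = 1.0 - p
    wbar = p * p * w.w_RR + 2 * p * q * w.w_RS + q * q * w.w_SS
    return np.where(wbar > 0, (p * p * w.w_RR + p * q * w.w_RS) / np.where(wbar > 0, wbar, 1.0), p)


def wright_fisher_trajectory(
    p0: float,
    cfg: DriftConfig,
    w: FitnessSpec = NEUTRAL,
    rng: np.random.Generator | None = None,
    generations: int | None = None,
) -> np.ndarray:
    """Simulate one allele-frequency trajectory of the Wright-Fisher model.

    Each generation applies deterministic viability selection (a no-op when
    ``w`` is neutral) and then resamples 2N allele copies binomially.  The
    returned array has ``generations + 1`` entries starting at ``p0``.
    Frequencies 0 and 1 are absorbing.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValidationError(f"p0 must be in [0,1], got {p0}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gens = cfg.generations_per_interval if generations is None else generations
    traj = np.empty(gens + 1)
    traj[0] = p = p0
    two_n = 2 * cfg.N
    for t in range(1, gens + 1):
        if p in (0.0, 1.0):
            traj[t:] = p
            break
        p_sel = float(_selection_step(p, w))
        p = rng.binomial(two_n, p_sel) / two_n
        traj[t] = p
    return traj


def simulate_final_freqs(
    p0: float,
    cfg: DriftConfig,
    rng: np.random.Generator,
    w: FitnessSpec = NEUTRAL,
) -> np.ndarray:
    """Vectorised final frequencies of ``cfg.n_sims`` Wright-Fisher runs."""
    two_n = 2 * cfg.N
    p = np.full(cfg.n_sims, p0)
    for _ in range(cfg.generations_per_interval):
        p_sel = p if w.is_neutral else _selection_step(p, w)
        p = rng.binomial(two_n, p_sel) / two_n
    return p


def drift_pvalue(
    p0: float,
    p_obs: float,
    cfg: DriftConfig,
    rng: np.random.Generator | None = None,
    *,
    cage_id: str = "",
    generation: int = 0,
) -> DriftTestResult:
    """Monte-Carlo probability that neutral drift moves the frequency as far as observed.

    Simulates ``n_sims`` neutral trajectories of ``generations_per_interval``
    generations from ``p0`` and counts endpoints at least as extreme as
    ``p_obs`` in the direction of the observed change (ties qualify).  A zero
    count is floored at ``1/(2 n_sims)`` so downstream Fisher combination is
    defined; no observed change defaults to the upper tail (the result is
    ~0.5 either way).
    """
    for name, v in (("p0", p0), ("p_obs", p_obs)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0,1], got {v}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    finals = simulate_final_freqs(p0, cfg, rng)
    if p_obs < p0:
        direction = "decrease"
        count = int(np.count_nonzero(finals <= p_obs))
    else:
        direction = "increase" if p_obs > p0 else "none"
        count = int(np.count_nonzero(finals >= p_obs))
    p = count / cfg.n_sims
    if p == 0.0:
        p = 1.0 / (2 * cfg.n_sims)
    return DriftTestResult(
        cage_id=cage_id,
        generation=generation,
        p0=p0,
        p_obs=p_obs,
        direction=direction,
        p=p,
        n_sims=cfg.n_sims,
        config=cfg,
    )


def drift_scan(series: CageSeries, cfg: DriftConfig, rng: np.random.Generator | None = None) -> list[DriftTestResult]:
    """Drift test for every consecutive pair of sampled generations in a cage.

    A single seeded generator is consumed in ascending-interval order, so a
    fixed (seed, config) pair reproduces results bit for bit.
    """
    if len(series) < 2:
        if len(series) < 1:
            raise DegenerateInputError("empty cage series")
        return []
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = []
    for prev, curr in zip(series.samples, series.samples[1:]):
        out.append(
            drift_pvalue(
                allele_frequency(prev).p_R,
                allele_frequency(curr).p_R,
                cfg,
                rng,
                cage_id=series.cage_id,
                generation=curr.generation,
            )
        )
    return out
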