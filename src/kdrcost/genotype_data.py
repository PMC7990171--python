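"""Genotype-count data model and I/O for cage allele-competition time series.

A cage experiment tracks a biallelic locus (susceptible allele S, resistance
allele R) in replicate populations sampled at a fixed schedule of generations
(by default F1, F3, F5, F7, F9).  Each sample is a triple of genotype counts
(n_SS, n_RS, n_RR).  This module provides the containers, the frequency
arithmetic, CSV round-tripping, and the reconstruction of integer counts from
rounded published frequencies (used to build fixture tables).

All internal arithmetic is full precision; the 2-decimal display convention
(round half away from zero) is applied only by :func:`round2` at report time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    AmbiguousRoundingError,
    DegenerateInputError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default genotyping schedule: every other cage generation starting at F1.
DEFAULT_GENERATIONS = (1, 3, 5, 7, 9)

REQUIRED_COLUMNS = ("experiment", "cage_id", "generation", "n_SS", "n_RS", "n_RR")


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (the display convention)."""
    return math.copysign(math.floor(abs(x) * 100 + 0.5) / 100, x)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one cage at one sampled generation."""

    cage_id: str
    generation: int
    n_SS: int
    n_RS: int
    n_RR: int

    def __post_init__(self) -> None:
        for name in ("n_SS", "n_RS", "n_RR"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.generation < 1:
            raise ValidationError(f"generation must be >= 1, got {self.generation}")

    @property
    def n(self) -> int:
        return self.n_SS + self.n_RS + self.n_RR

    @property
    def n_R_alleles(self) -> int:
        return 2 * self.n_RR + self.n_RS


@dataclass(frozen=True)
class GenotypeFreqs:
    """Genotype proportions (f_SS, f_RS, f_RR) summing to 1."""

    f_SS: float
    f_RS: float
    f_RR: float

    def __post_init__(self) -> None:
        total = self.f_SS + self.f_RS + self.f_RR
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(f"genotype frequencies must sum to 1, got {total}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_SS, self.f_RS, self.f_RR)


@dataclass(frozen=True)
class AlleleFreq:
    """Allele proportions at the biallelic locus; p_R is the resistance allele."""

    p_S: float
    p_R: float

    def __post_init__(self) -> None:
        if not math.isclose(self.p_S + self.p_R, 1.0, abs_tol=1e-9):
            raise ValidationError(f"allele frequencies must sum to 1, got {self.p_S + self.p_R}")
        if not (-1e-12 <= self.p_R <= 1 + 1e-12):
            raise ValidationError(f"p_R out of [0,1]: {self.p_R}")


@dataclass(frozen=True)
class CageSeries:
    """Ordered genotype samples for one cage across the genotyping schedule."""

    cage_id: str
    samples: tuple[GenotypeCounts, ...]

    def __post_init__(self) -> None:
        gens = [s.generation for s in self.samples]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValidationError(
                f"cage {self.cage_id}: generations must be strictly increasing, got {gens}"
            )

    @property
    def generations(self) -> tuple[int, ...]:
        return tuple(s.generation for s in self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


def genotype_frequencies(c: GenotypeCounts) -> GenotypeFreqs:
    """Observed genotype proportions count / n, full precision."""
    if c.n == 0:
        raise DegenerateInputError(f"cage {c.cage_id} F{c.generation}: sample size is 0")
    return GenotypeFreqs(c.n_SS / c.n, c.n_RS / c.n, c.n_RR / c.n)


def allele_frequency(c: GenotypeCounts) -> AlleleFreq:
    """Allele proportions by gene counting: p_R = (2 n_RR + n_RS) / 2n."""
    if c.n == 0:
        raise DegenerateInputError(f"cage {c.cage_id} F{c.generation}: sample size is 0")
    p_r = c.n_R_alleles / (2 * c.n)
    return AlleleFreq(p_S=1.0 - p_r, p_R=p_r)


def _largest_remainder(freqs: Sequence[float], n: int) -> tuple[int, int, int]:
    """Apportion n among three classes by the largest-remainder method."""
    raw = [f * n for f in freqs]
    base = [math.floor(x) for x in raw]
    short = n - sum(base)
    order = sorted(range(3), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return tuple(base)  # type: ignore[return-value]


def counts_from_frequencies(
    freqs: Sequence[float],
    n: int,
    *,
    allele_freq_R: float | None = None,
    cage_id: str = "",
    generation: int = 1,
) -> GenotypeCounts:
    """Reconstruct the integer genotype triple behind published 2-dp frequencies.

    Enumerates integer triples summing to ``n`` in a window around the
    largest-remainder apportionment of ``freqs`` and keeps those whose
    2-dp rounded genotype frequencies — and, when ``allele_freq_R`` is given,
    2-dp rounded R-allele frequency — all reproduce the published values.

    Raises
    ------
    AmbiguousRoundingError
        If no triple (or more than one) reproduces every published cell.  The
        error carries candidate triples ranked by (number of mismatched cells,
        total absolute rounding discrepancy) so callers can resolve and record
        the choice explicitly.
    """
    if n < 1:
        raise DegenerateInputError("n must be >= 1")
    total = sum(freqs)
    if not (0.98 - 1e-9 <= total <= 1.02 + 1e-9):
        # published rows can sum to 0.99-1.01 from rounding; 1.05 (a known
        # typo pattern) is handled by the caller via the candidate list
        if not (0.9 <= total <= 1.1):
            raise ValidationError(f"frequencies sum to {total}, outside plausible rounding range")

    anchor = _largest_remainder(freqs, n)
    window = 4
    exact: list[tuple[int, int, int]] = []
    scored: list[tuple[float, int, tuple[int, int, int]]] = []
    for a in range(max(0, anchor[0] - window), min(n, anchor[0] + window) + 1):
        for b in range(max(0, anchor[1] - window), min(n - a, anchor[1] + window) + 1):
            c = n - a - b
            if c < 0 or abs(c - anchor[2]) > window:
                continue
            cand = (a, b, c)
            rounded = [round2(x / n) for x in cand]
            mism = sum(abs(r - f) > 1e-9 for r, f in zip(rounded, freqs))
            dist = sum(abs(r - f) for r, f in zip(rounded, freqs))
            if allele_freq_R is not None:
                pr = round2((2 * c + b) / (2 * n))
                if abs(pr - allele_freq_R) > 1e-9:
                    mism += 1
                    dist += abs(pr - allele_freq_R)
            if mism == 0:
                exact.append(cand)
            scored.append((dist, mism, cand))

    if len(exact) == 1:
        a, b, c = exact[0]
        return GenotypeCounts(cage_id=cage_id, generation=generation, n_SS=a, n_RS=b, n_RR=c)

    scored.sort(key=lambda t: (t[1], t[0], t[2]))
    best_key = (scored[0][1], scored[0][0])
    candidates = [t[2] for t in scored if (t[1], t[0]) == best_key]
    if len(exact) > 1:
        candidates = exact
    raise AmbiguousRoundingError(
        f"no unique triple reproduces the published frequencies {tuple(freqs)} at n={n}; "
        f"candidates: {candidates}",
        candidates=candidates,
    )


def read_genotype_table(path: str | Path) -> list[CageSeries]:
    """Read a genotype-count CSV into one :class:`CageSeries` per cage.

    Expected header: ``experiment,cage_id,generation,n_SS,n_RS,n_RR[,n]``.
    Rows are grouped by cage and sorted by generation; when an ``n`` column is
    present each row's counts are validated against it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("genotype table %s is empty", path)
        return []
    if df.empty:
        logger.warning("genotype table %s has no rows", path)
        return []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    out: list[CageSeries] = []
    for (_, cage_id), grp in df.groupby(["experiment", "cage_id"], sort=False):
        grp = grp.sort_values("generation")
        samples = []
        for idx, row in grp.iterrows():
            counts = [int(row[c]) for c in ("n_SS", "n_RS", "n_RR")]
            if any(c < 0 for c in counts):
                raise ValidationError(f"{path} row {idx + 2}: negative genotype count")
            if "n" in df.columns and not pd.isna(row["n"]):
                if sum(counts) != int(row["n"]):
                    raise ValidationError(
                        f"{path} row {idx + 2}: counts sum to {sum(counts)} but n={int(row['n'])}"
                    )
            samples.append(
                GenotypeCounts(
                    cage_id=str(cage_id),
                    generation=int(row["generation"]),
                    n_SS=counts[0],
                    n_RS=counts[1],
                    n_RR=counts[2],
                )
            )
        out.append(CageSeries(cage_id=str(cage_id), samples=tuple(samples)))
    return out


def write_genotype_table(series: Iterable[CageSeries], path: str | Path, experiment: str = "exp") -> None:
    """Write cage series back to the CSV schema read by :func:`read_genotype_table`."""
    rows = []
    for s in series:
        for c in s:
            rows.append(
                {
                    "experiment": experiment,
                    "cage_id": s.cage_id,
                    "generation": c.generation,
                    "n_SS": c.n_SS,
                    "n_RS": c.n_RS,
                    "n_RR": c.n_RR,
                    "n": c.n,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["n"]).to_csv(path, index=False)
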