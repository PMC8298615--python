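"""Hardy-Weinberg genotype expectations for a pooled recessive allele class.

Under random mating, an allele class at frequency ``p`` (here the cumulative
minor allele frequency of all pathogenic alleles of one gene, with q = 1 - p)
yields genotype frequencies p^2 (biallelic: homozygotes plus compound
heterozygotes, since the pathogenic alleles never share a haplotype),
2pq (carriers) and q^2 (non-carriers).

The reporting convention for rare recessive disease is the reciprocal
"1 in N": both N values are computed from the *exact* integer allele counts
as rationals and rounded half-away-from-zero only at the end — never from a
pre-rounded percentage, which corrupts the trailing digits of large N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Optional, Union

__all__ = [
    "NOT_OBSERVED",
    "NotObserved",
    "GenotypeFreqs",
    "HWReport",
    "round_half_away",
    "genotype_frequencies",
    "one_in_homozygote",
    "one_in_carrier",
    "expected_cases",
]

FractionLike = Union[Fraction, float, int]


class NotObserved:
    """Sentinel for cohorts where no pathogenic allele was seen.

    A zero alt count gives no frequency estimate, so "1 in N" is undefined —
    this sentinel is reported instead of any number.
    """

    _instance: Optional["NotObserved"] = None

    def __new__(cls) -> "NotObserved":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "not observed"

    def __bool__(self) -> bool:
        return False


NOT_OBSERVED = NotObserved()


def round_half_away(x: FractionLike) -> int:
    """Nearest integer, ties away from zero, exact for rational input."""
    f = Fraction(x)
    n, d = f.numerator, f.denominator
    if n >= 0:
        return (2 * n + d) // (2 * d)
    return -((-2 * n + d) // (2 * d))


def _as_probability(p: FractionLike, name: str = "p") -> Fraction:
    f = Fraction(p)
    if not 0 <= f <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {float(f)}")
    if f > Fraction(1, 2):
        warnings.warn(f"{name} = {float(f):.4g} > 0.5: not a minor allele", UserWarning, stacklevel=3)
    return f


@dataclass(frozen=True)
class GenotypeFreqs:
    """Hardy-Weinberg genotype frequencies for allele frequency p."""

    p: Fraction
    hom_alt: Fraction  # p^2: biallelic (homozygous or compound heterozygous)
    het: Fraction      # 2pq: carriers
    hom_ref: Fraction  # q^2

    def __post_init__(self) -> None:
        total = self.hom_alt + self.het + self.hom_ref
        if abs(float(total) - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies sum to {float(total)}, not 1")


def genotype_frequencies(p: FractionLike) -> GenotypeFreqs:
    """(p^2, 2pq, q^2) for allele frequency p, exact when p is rational.

    >>> g = genotype_frequencies(Fraction(7, 2730))
    >>> g.hom_alt == Fraction(1, 152100)
    True
    """
    f = _as_probability(p)
    q = 1 - f
    return GenotypeFreqs(f, f * f, 2 * f * q, q * q)


def one_in_homozygote(alt: int, an: int) -> Union[int, NotObserved]:
    """Expected biallelic-genotype frequency as "1 in N": N = round((an/alt)^2).

    Computed from the exact integer ratio. ``alt = 0`` has no defined N and
    returns the NOT_OBSERVED sentinel.
    """
    if alt == 0:
        return NOT_OBSERVED
    p = _as_probability(Fraction(alt, an), "alt/an")
    return round_half_away(1 / (p * p))


def one_in_carrier(alt: int, an: int) -> Union[int, NotObserved]:
    """Expected carrier (heterozygote) frequency as "1 in N": N = round(1/(2pq))."""
    if alt == 0:
        return NOT_OBSERVED
    p = _as_probability(Fraction(alt, an), "alt/an")
    if p == 1:
        raise ValueError("p = 1: carrier frequency 2pq is zero, '1 in N' undefined")
    return round_half_away(1 / (2 * p * (1 - p)))


def expected_cases(p: FractionLike, population_size: int) -> float:
    """Expected number of biallelic (affected) individuals: population_size * p^2.

    No rounding is applied; presentation is the caller's concern.
    """
    if population_size <= 0:
        raise ValueError(f"population_size must be positive, got {population_size}")
    f = Fraction(p)
    if not 0 <= f <= 1:
        raise ValueError(f"p must lie in [0, 1], got {float(f)}")
    return float(population_size * f * f)


@dataclass(frozen=True)
class HWReport:
    """One formatted per-cohort row: pooled counts, percent, 1-in-N expectations."""

    cohort_label: str
    alt: int
    an: int
    percent_text: str
    percent_value: float
    homozygote_one_in: Union[int, NotObserved]
    carrier_one_in: Union[int, NotObserved]
    expected_cases: Optional[float] = None

    def __post_init__(self) -> None:
        hom, car = self.homozygote_one_in, self.carrier_one_in
        if isinstance(hom, int) and isinstance(car, int):
            if 0 < self.alt <= self.an / 2 and hom < car:
                raise ValueError(
                    f"{self.cohort_label}: homozygote 1-in-{hom} below carrier 1-in-{car} "
                    "with p <= 0.5 — inconsistent"
                )
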