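"""Variant registry and per-population allele counting.

A :class:`VariantStore` holds curated pathogenic variants (parsed HGVS, see
:mod:`aprtfreq.nomenclature`) together with their allele counts in
population genomic databases — one :class:`AlleleCount` per
(variant, database, population) observation, mirroring the Alt/AN pairs
such databases publish.

The frequency math lives here as exact rational arithmetic
(:class:`fractions.Fraction`): ``maf`` for a single variant, ``cmaf`` for
the cumulative minor allele frequency of all pathogenic variants pooled
within one cohort (the ``p`` that feeds the Hardy-Weinberg expectations),
and ``percent`` for half-away-from-zero display rounding. Rare pathogenic
alleles of this gene are never reported on the same haplotype, so summing
per-variant frequencies is the correct pooling rule.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP, localcontext
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .nomenclature import (
    Variant,
    classify,
    parse_cdna,
    parse_protein,
    parse_region,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "AlleleCount",
    "CohortFrequency",
    "PercentValue",
    "RegistryValidationError",
    "VariantStore",
    "maf",
    "cmaf",
    "percent",
    "load_registry",
    "save_registry",
    "load_counts_table",
    "export_vcf",
    "fixture_path",
]

REGISTRY_COLUMNS = ["variant_id", "cdna", "protein", "region", "build38_pos", "printed_label"]
COUNTS_COLUMNS = ["variant_id", "database", "population", "alt_count", "allele_number"]

KNOWN_DATABASES = (
    "deCODE",
    "UK Biobank",
    "100,000 Genomes Project",
    "gnomAD",
    "HGVD",
    "KOVA",
)


class RegistryValidationError(ValueError):
    """Schema or content problem in a registry/counts table; lists row numbers."""

    def __init__(self, path, problems: Sequence[str]):
        self.path = str(path)
        self.problems = list(problems)
        detail = "; ".join(self.problems)
        super().__init__(f"{self.path}: {detail}")


@dataclass(frozen=True)
class Cohort:
    """One population sample within one genomic database."""

    database: str
    population: str
    default_allele_number: Optional[int] = None

    def __post_init__(self) -> None:
        if self.default_allele_number is not None and self.default_allele_number <= 0:
            raise ValueError("default_allele_number must be positive")

    @property
    def key(self) -> tuple:
        return (self.database, self.population)

    @property
    def label(self) -> str:
        return f"{self.population} ({self.database})"


@dataclass(frozen=True)
class AlleleCount:
    """Observation of one variant in one cohort: alt count over allele number (2N chromosomes)."""

    variant_id: str
    cohort: Cohort
    alt_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError(f"{self.variant_id}: allele_number must be positive, got {self.allele_number}")
        if not 0 <= self.alt_count <= self.allele_number:
            raise ValueError(
                f"{self.variant_id}: alt_count {self.alt_count} outside 0..{self.allele_number}"
            )

    @property
    def maf(self) -> Fraction:
        return Fraction(self.alt_count, self.allele_number)


@dataclass(frozen=True)
class CohortFrequency:
    """Pooled (cumulative) frequency of pathogenic alleles in one cohort.

    ``p`` is the cumulative minor allele frequency; ``q = 1 - p``. When the
    pooled counts share a single allele number, ``p`` is the exact ratio
    total_alt / allele_number_used; otherwise ``p`` is the sum of per-variant
    frequencies and ``allele_number_used`` records the largest denominator
    as the display convention (``mixed_an`` is then True).
    """

    cohort: Cohort
    variant_ids: tuple
    total_alt: int
    allele_number_used: int
    p: Fraction
    mixed_an: bool = False

    @property
    def q(self) -> Fraction:
        return 1 - self.p


def maf(alt_count: int, allele_number: int) -> Fraction:
    """Minor allele frequency alt/AN as an exact rational.

    >>> float(maf(1299, 107928))  # doctest: +ELLIPSIS
    0.01203...
    """
    if allele_number <= 0:
        raise ValueError(f"allele_number must be positive, got {allele_number}")
    if not 0 <= alt_count <= allele_number:
        raise ValueError(f"alt_count {alt_count} outside 0..{allele_number}")
    return Fraction(alt_count, allele_number)


def cmaf(counts: Sequence[AlleleCount]) -> CohortFrequency:
    """Cumulative MAF of a set of distinct pathogenic variants in one cohort.

    All counts must refer to the same cohort and distinct variants. An empty
    list yields p = 0 for a cohort placeholder labelled "(none)".
    """
    if not counts:
        return CohortFrequency(Cohort("(none)", "(none)"), (), 0, 1, Fraction(0))
    cohorts = {c.cohort.key for c in counts}
    if len(cohorts) > 1:
        raise RegistryValidationError("<cmaf>", [f"mixed cohorts in one pooling: {sorted(cohorts)}"])
    ids = [c.variant_id for c in counts]
    if len(set(ids)) != len(ids):
        raise RegistryValidationError("<cmaf>", [f"duplicate variant_ids in pooling: {ids}"])
    cohort = counts[0].cohort
    ans = {c.allele_number for c in counts}
    total_alt = sum(c.alt_count for c in counts)
    if len(ans) == 1:
        an = ans.pop()
        return CohortFrequency(cohort, tuple(ids), total_alt, an, Fraction(total_alt, an))
    p = sum((c.maf for c in counts), Fraction(0))
    an = max(ans)
    logger.info(
        "mixed-AN pooling for %s: allele numbers %s; p is the sum of frequencies, "
        "display denominator %d", cohort.label, sorted(ans), an,
    )
    return CohortFrequency(cohort, tuple(ids), total_alt, an, p, mixed_an=True)


@dataclass(frozen=True)
class PercentValue:
    """A frequency rendered as a percentage: numeric value plus fixed-decimal text."""

    value: float
    text: str

    def __float__(self) -> float:
        return self.value


def percent(f: Union[Fraction, float, int], decimals: int = 2) -> PercentValue:
    """``f * 100`` rounded half-away-from-zero to ``decimals`` places.

    Rounding is done in exact decimal arithmetic on the rational value, so
    e.g. percent(Fraction(311, 482), 1) is 64.5 with no float-tie surprises.
    """
    frac = Fraction(f)
    if not 0 <= frac <= 1:
        raise ValueError(f"frequency must lie in [0, 1], got {float(frac)}")
    with localcontext() as ctx:
        ctx.prec = 50
        exact = Decimal(frac.numerator) * 100 / Decimal(frac.denominator)
        quantum = Decimal(1).scaleb(-decimals)
        rounded = exact.quantize(quantum, rounding=ROUND_HALF_UP)
    return PercentValue(float(rounded), f"{rounded:f}")


class VariantStore:
    """Variants plus their allele counts, indexed for pooling and reporting."""

    def __init__(self, variants: Iterable[Variant] = (), counts: Iterable[AlleleCount] = ()):
        self.variants: dict[str, Variant] = {}
        self.counts: list[AlleleCount] = []
        for v in variants:
            self.add_variant(v)
        for c in counts:
            self.add_count(c)

    def add_variant(self, v: Variant) -> None:
        if v.variant_id in self.variants:
            raise RegistryValidationError("<store>", [f"duplicate variant_id {v.variant_id!r}"])
        self.variants[v.variant_id] = v

    def add_count(self, c: AlleleCount) -> None:
        key = (c.variant_id, c.cohort.key)
        if any((x.variant_id, x.cohort.key) == key for x in self.counts):
            raise RegistryValidationError("<store>", [f"duplicate count row for {key}"])
        self.counts.append(c)

    def cohorts(self) -> list[Cohort]:
        seen: dict[tuple, Cohort] = {}
        for c in self.counts:
            seen.setdefault(c.cohort.key, c.cohort)
        return list(seen.values())

    def counts_for_cohort(self, cohort: Union[Cohort, tuple, str]) -> list[AlleleCount]:
        """Counts for one cohort; accepts a Cohort, a (database, population) key,
        or a bare population string when unambiguous."""
        if isinstance(cohort, Cohort):
            key = cohort.key
        elif isinstance(cohort, tuple):
            key = cohort
        else:
            keys = {c.cohort.key for c in self.counts if c.cohort.population == cohort}
            if not keys:
                known = sorted({c.cohort.label for c in self.counts})
                raise KeyError(f"unknown cohort {cohort!r}; known cohorts: {known}")
            if len(keys) > 1:
                raise KeyError(f"ambiguous cohort {cohort!r}: {sorted(keys)}")
            key = keys.pop()
        return [c for c in self.counts if c.cohort.key == key]

    def counts_for_variant(self, variant_id: str) -> list[AlleleCount]:
        rows = [c for c in self.counts if c.variant_id == variant_id]
        if not rows and variant_id not in self.variants:
            raise KeyError(f"unknown variant_id {variant_id!r}")
        return rows

    def cohort_cmaf(self, cohort: Union[Cohort, tuple, str]) -> CohortFrequency:
        return cmaf(self.counts_for_cohort(cohort))

    def observed_variant_ids(self) -> set[str]:
        """Variants with at least one nonzero alt count in any database."""
        return {c.variant_id for c in self.counts if c.alt_count > 0}

    def __eq__(self, other) -> bool:
        return (isinstance(other, VariantStore)
                and self.variants == other.variants
                and sorted(self.counts, key=lambda c: (c.variant_id, c.cohort.key))
                == sorted(other.counts, key=lambda c: (c.variant_id, c.cohort.key)))


def _read_tsv(path: Path, required: Sequence[str]) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise RegistryValidationError(path, [f"missing columns: {missing}"])
        return list(reader)


def load_registry(registry_path, counts_path=None) -> VariantStore:
    """Load a variant registry TSV and (optionally) an allele-counts TSV.

    Validation errors are collected with 1-based data row numbers so a bad
    file reports every problem at once.
    """
    registry_path = Path(registry_path)
    store = VariantStore()
    problems: list[str] = []
    for i, row in enumerate(_read_tsv(registry_path, REGISTRY_COLUMNS), start=1):
        try:
            cdna = parse_cdna(row["cdna"])
            protein = parse_protein(row["protein"]) if row.get("protein") else None
            variant = Variant(
                variant_id=row["variant_id"],
                cdna=cdna,
                protein=protein,
                region=parse_region(row["region"]),
                consequence=classify(cdna, protein),
                printed_label=row.get("printed_label") or "",
                build38_pos=row.get("build38_pos") or None,
                genomic_ref=row.get("genomic_ref") or None,
                genomic_alt=row.get("genomic_alt") or None,
            )
            store.add_variant(variant)
        except (ValueError, KeyError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise RegistryValidationError(registry_path, problems)
    if counts_path is not None:
        for c in load_counts_table(counts_path):
            store.add_count(c)
    return store


def load_counts_table(counts_path) -> list[AlleleCount]:
    """Load an allele-counts TSV (variant_id, database, population, alt_count, allele_number)."""
    counts_path = Path(counts_path)
    problems: list[str] = []
    out: list[AlleleCount] = []
    seen: set[tuple] = set()
    for i, row in enumerate(_read_tsv(counts_path, COUNTS_COLUMNS), start=1):
        try:
            cohort = Cohort(row["database"], row["population"])
            key = (row["variant_id"], cohort.key)
            if key in seen:
                raise ValueError(f"duplicate (variant, cohort) row {key}")
            seen.add(key)
            out.append(AlleleCount(row["variant_id"], cohort,
                                   int(row["alt_count"]), int(row["allele_number"])))
        except ValueError as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise RegistryValidationError(counts_path, problems)
    return out


def save_registry(store: VariantStore, registry_path, counts_path=None) -> None:
    """Write the store back to TSV; ``load_registry(save_registry(x)) == x``."""
    registry_path = Path(registry_path)
    with_genomic = any(v.genomic_ref or v.genomic_alt for v in store.variants.values())
    columns = REGISTRY_COLUMNS + (["genomic_ref", "genomic_alt"] if with_genomic else [])
    with open(registry_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for v in store.variants.values():
            row = [
                v.variant_id,
                v.cdna.format(),
                v.protein.format() if v.protein else "",
                v.region.format(),
                v.build38_pos or "",
                v.printed_label,
            ]
            if with_genomic:
                row += [v.genomic_ref or "", v.genomic_alt or ""]
            writer.writerow(row)
    if counts_path is not None:
        with open(counts_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(COUNTS_COLUMNS)
            for c in store.counts:
                writer.writerow([c.variant_id, c.cohort.database, c.cohort.population,
                                 c.alt_count, c.allele_number])


def export_vcf(store: VariantStore, path) -> int:
    """Sites-only VCF v4.2 export of registry variants with explicit genomic alleles.

    Only variants whose registry rows carry a build-38 position AND explicit
    ``genomic_ref``/``genomic_alt`` payloads can be emitted; the gene is on
    the reverse strand and no strand complementing or transcript-to-genome
    arithmetic is attempted here. Variants without those fields are skipped
    with a logged warning. Returns the number of records written.
    """
    path = Path(path)
    written = 0
    records = []
    for v in store.variants.values():
        if v.build38_pos is None or v.genomic_ref is None or v.genomic_alt is None:
            logger.warning("VCF export: skipping %s (no genomic REF/ALT available)", v.variant_id)
            continue
        chrom, pos = v.build38_pos.split(":")
        records.append((int(pos), chrom, v.variant_id, v.genomic_ref, v.genomic_alt))
        written += 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=GRCh38\n")
        fh.write('##INFO=<ID=CDNA,Number=1,Type=String,Description="HGVS cDNA description">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, chrom, vid, ref, alt in sorted(records):
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\tCDNA={vid}\n")
    return written


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture table (e.g. ``table2_decode.tsv``)."""
    return Path(__file__).parent / "fixtures" / name
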