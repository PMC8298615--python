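"""Output tables and summary statistics.

Builds the two table styles a recessive-disease frequency study reports:

* per-cohort rows (pooled allele count, cumulative MAF as a percentage, and
  Hardy-Weinberg "1 in N" homozygote / carrier expectations), and
* per-variant rows (one line per database population with alt/AN and percent).

Machine output is bit-stable TSV/JSON (bare integers, empty-string sentinel
for unobserved cohorts); human output is markdown with thousands separators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .hardy_weinberg import (
    NOT_OBSERVED,
    HWReport,
    NotObserved,
    expected_cases,
    one_in_carrier,
    one_in_homozygote,
)
from .registry import (
    AlleleCount,
    Cohort,
    VariantStore,
    cmaf,
    fixture_path,
    maf,
    percent,
)

__all__ = [
    "SummaryStats",
    "PooledCohortRow",
    "cohort_table",
    "variant_table",
    "summarize",
    "hw_report_row",
    "load_pooled_cohorts",
    "load_case_alleles",
    "known_divergences",
    "write_report_tsv",
    "write_report_md",
    "write_summary_json",
]


@dataclass(frozen=True)
class SummaryStats:
    """Study-level counts: variants found in databases, diagnosed cases, top-k allele share."""

    n_variants: int
    n_in_databases: int
    n_absent: int
    n_cases_total: int
    n_molecular: int
    top_k_allele_share: Fraction

    def __post_init__(self) -> None:
        if self.n_in_databases + self.n_absent != self.n_variants:
            raise ValueError("n_in_databases + n_absent must equal n_variants")
        if not 0 <= self.top_k_allele_share <= 1:
            raise ValueError("top_k_allele_share must lie in [0, 1]")

    @property
    def molecular_share(self) -> Fraction:
        return Fraction(self.n_molecular, self.n_cases_total) if self.n_cases_total else Fraction(0)


@dataclass(frozen=True)
class PooledCohortRow:
    """A pre-pooled cohort count (Alt/AN) plus any published cells kept for comparison."""

    cohort: Cohort
    alt: int
    an: int
    printed_percent: Optional[str] = None
    printed_homozygote_one_in: Optional[int] = None
    printed_carrier_one_in: Optional[int] = None
    flag: str = ""


def hw_report_row(
    label: str,
    alt: int,
    an: int,
    percent_decimals: int = 4,
    population_size: Optional[int] = None,
) -> HWReport:
    """One cohort row from a pooled Alt/AN pair."""
    p = maf(alt, an)
    pct = percent(p, percent_decimals)
    cases = expected_cases(p, population_size) if population_size else None
    return HWReport(
        cohort_label=label,
        alt=alt,
        an=an,
        percent_text=pct.text,
        percent_value=pct.value,
        homozygote_one_in=one_in_homozygote(alt, an),
        carrier_one_in=one_in_carrier(alt, an),
        expected_cases=cases,
    )


def cohort_table(
    store: VariantStore,
    cohorts: Optional[Sequence[Union[Cohort, tuple, str]]] = None,
    percent_decimals: int = 4,
    population_sizes: Optional[Mapping[str, int]] = None,
) -> list[HWReport]:
    """Per-cohort Hardy-Weinberg rows pooled from the store's allele counts.

    Cohorts with a pooled alt count of zero get NOT_OBSERVED sentinels in the
    1-in-N columns. Unknown cohort labels raise KeyError listing known labels.
    """
    population_sizes = population_sizes or {}
    targets = cohorts if cohorts is not None else store.cohorts()
    rows = []
    for cohort in targets:
        counts = store.counts_for_cohort(cohort)  # raises KeyError with known labels
        freq = cmaf(counts)
        label = freq.cohort.label
        rows.append(
            hw_report_row(
                label,
                freq.total_alt,
                freq.allele_number_used,
                percent_decimals,
                population_sizes.get(freq.cohort.population),
            )
        )
    return rows


def variant_table(store: VariantStore, variant_id: str, percent_decimals: int = 4) -> pd.DataFrame:
    """Per-population frequency rows for one variant, in fixture order."""
    counts = store.counts_for_variant(variant_id)
    records = []
    for c in counts:
        pct = percent(c.maf, percent_decimals)
        records.append(
            {
                "variant_id": c.variant_id,
                "database": c.cohort.database,
                "population": c.cohort.population,
                "alt_count": c.alt_count,
                "allele_number": c.allele_number,
                "percent": pct.value,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["variant_id", "database", "population", "alt_count", "allele_number", "percent"],
    )


def load_case_alleles(path=None) -> dict[str, int]:
    """Case-allele tally per variant (disease alleles among genotyped cases)."""
    path = Path(path) if path else fixture_path("case_alleles.tsv")
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["variant_id"], df["case_allele_count"].astype(int)))


def summarize(
    store: VariantStore,
    case_alleles: Mapping[str, int],
    totals: Optional[Mapping[str, int]] = None,
    top_k: int = 3,
) -> SummaryStats:
    """Study-level summary.

    ``totals`` supplies the study-wide counts that cannot be derived from a
    partial registry (total curated variants, total/molecularly diagnosed
    cases, total case alleles); when omitted, the packaged study summary is
    used. Variant presence in databases is computed from the store when the
    registry covers all curated variants, otherwise from the totals.
    """
    if totals is None:
        with open(fixture_path("case_summary.json"), encoding="utf-8") as fh:
            totals = json.load(fh)
    n_variants = int(totals.get("n_variants_total", len(store.variants)))
    if n_variants == len(store.variants):
        n_in_db = len(store.observed_variant_ids())
    else:
        n_in_db = int(totals["n_observed_in_databases"])
    total_alleles = int(totals.get("n_case_alleles_total", sum(case_alleles.values())))
    top = sorted(case_alleles.values(), reverse=True)[:top_k]
    share = Fraction(sum(top), total_alleles) if total_alleles else Fraction(0)
    return SummaryStats(
        n_variants=n_variants,
        n_in_databases=n_in_db,
        n_absent=n_variants - n_in_db,
        n_cases_total=int(totals.get("n_cases_total", 0)),
        n_molecular=int(totals.get("n_molecular", 0)),
        top_k_allele_share=share,
    )


def load_pooled_cohorts(path=None) -> list[PooledCohortRow]:
    """Load a pooled per-cohort count table (Alt/AN plus published cells and flags)."""
    path = Path(path) if path else fixture_path("table3_cohorts.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            PooledCohortRow(
                cohort=Cohort(rec["database"], rec["population"]),
                alt=int(rec["alt_count"]),
                an=int(rec["allele_number"]),
                printed_percent=rec.get("printed_percent") or None,
                printed_homozygote_one_in=int(rec["printed_homozygote_one_in"])
                if rec.get("printed_homozygote_one_in")
                else None,
                printed_carrier_one_in=int(rec["printed_carrier_one_in"])
                if rec.get("printed_carrier_one_in")
                else None,
                flag=rec.get("flag", ""),
            )
        )
    return rows


def known_divergences() -> list[dict]:
    """Published cells that exact recomputation does not reproduce (documented, never asserted)."""
    with open(fixture_path("known_divergences.json"), encoding="utf-8") as fh:
        return json.load(fh)["divergences"]


def _one_in_machine(value) -> str:
    return "" if isinstance(value, NotObserved) else str(value)


def _one_in_human(value) -> str:
    return "not observed" if isinstance(value, NotObserved) else f"1 in {value:,}"


def write_report_tsv(rows: Iterable[HWReport], path) -> None:
    """Machine-readable cohort report: bare integers, empty-string sentinels."""
    df = pd.DataFrame(
        [
            {
                "cohort": r.cohort_label,
                "alt_count": r.alt,
                "allele_number": r.an,
                "percent": r.percent_text,
                "homozygote_one_in": _one_in_machine(r.homozygote_one_in),
                "carrier_one_in": _one_in_machine(r.carrier_one_in),
                "expected_cases": "" if r.expected_cases is None else repr(r.expected_cases),
            }
            for r in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_report_md(rows: Iterable[HWReport], path) -> None:
    """Human-readable cohort report with thousands separators."""
    header = ["Cohort", "Allele count (Alt/AN)", "Allele frequency (%)",
              "Expected homozygote frequency", "Expected carrier frequency"]
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for r in rows:
        lines.append(
            "| "
            + " | ".join(
                [
                    r.cohort_label,
                    f"{r.alt:,}/{r.an:,}",
                    r.percent_text,
                    _one_in_human(r.homozygote_one_in),
                    _one_in_human(r.carrier_one_in),
                ]
            )
            + " |"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_summary_json(stats: SummaryStats, path) -> None:
    payload = {
        "n_variants": stats.n_variants,
        "n_in_databases": stats.n_in_databases,
        "n_absent": stats.n_absent,
        "n_cases_total": stats.n_cases_total,
        "n_molecular": stats.n_molecular,
        "molecular_share_percent": percent(stats.molecular_share, 1).value,
        "top_k_allele_share_percent": percent(stats.top_k_allele_share, 1).value,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
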