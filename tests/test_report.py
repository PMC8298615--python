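"""Cohort/variant output tables, study summary and golden reproduction."""

import json
from fractions import Fraction

import pytest

from aprtfreq.hardy_weinberg import NOT_OBSERVED, NotObserved, one_in_carrier, one_in_homozygote
from aprtfreq.registry import AlleleCount, Cohort, VariantStore, fixture_path, load_registry
from aprtfreq.report import (
    cohort_table,
    hw_report_row,
    known_divergences,
    load_case_alleles,
    load_pooled_cohorts,
    summarize,
    variant_table,
    write_report_md,
    write_report_tsv,
    write_summary_json,
)


def _row(rows, label):
    return next(r for r in rows if r.cohort_label == label)


def test_cohort_table_decode(decode_store):
    rows = cohort_table(decode_store)
    sweden = _row(rows, "Sweden (deCODE)")
    assert (sweden.alt, sweden.an) == (3, 6306)
    assert sweden.percent_value == 0.0476
    assert sweden.homozygote_one_in == 4418404
    assert sweden.carrier_one_in == 1052


def test_cohort_table_unknown_cohort(decode_store):
    with pytest.raises(KeyError, match="known cohorts"):
        cohort_table(decode_store, cohorts=["Atlantis"])


def test_cohort_table_sentinel_for_unobserved():
    store = VariantStore(counts=[AlleleCount("v1", Cohort("simulated", "empty"), 0, 2000)])
    (row,) = cohort_table(store)
    assert row.homozygote_one_in is NOT_OBSERVED
    assert row.carrier_one_in is NOT_OBSERVED
    assert row.percent_value == 0.0


def test_cohort_table_expected_cases(decode_store):
    rows = cohort_table(decode_store, population_sizes={"Ireland": 4_900_000})
    ireland = _row(rows, "Ireland (deCODE)")
    # ~30 expected biallelic subjects in a nation of 4.9 million
    assert ireland.expected_cases == pytest.approx(4_900_000 / 152100, rel=1e-12)
    assert round(ireland.expected_cases) == 32


def test_pooled_cohort_rows_hgvd_kova(pooled_cohorts):
    by_db = {(r.cohort.database, r.cohort.population): r for r in pooled_cohorts}
    hgvd = by_db[("HGVD", "Japan")]
    assert (hgvd.alt, hgvd.an) == (3, 2326)
    assert one_in_homozygote(hgvd.alt, hgvd.an) == 601142
    assert one_in_carrier(hgvd.alt, hgvd.an) == 388
    kova = by_db[("KOVA", "Korea")]
    assert one_in_homozygote(kova.alt, kova.an) == 3602404
    assert one_in_carrier(kova.alt, kova.an) == 950


def test_variant_table_examples(common_variant_store):
    t = variant_table(common_variant_store, "c.407T>C", percent_decimals=2)
    japan = t[(t.database == "HGVD") & (t.population == "Japan")].iloc[0]
    assert (japan.alt_count, japan.allele_number, japan.percent) == (3, 2326, 0.13)

    t2 = variant_table(common_variant_store, "c.194A>T", percent_decimals=1)
    iceland = t2[t2.population == "Iceland"].iloc[0]
    assert (iceland.alt_count, iceland.allele_number, iceland.percent) == (1299, 107928, 1.2)


def test_variant_table_keeps_zero_rows(common_variant_store):
    t = variant_table(common_variant_store, "c.407T>C")
    zero = t[t.alt_count == 0]
    assert len(zero) == 7  # absent from 7 of the 10 sampled populations
    assert (zero.percent == 0).all()


def test_variant_table_unknown_variant(common_variant_store):
    with pytest.raises(KeyError):
        variant_table(common_variant_store, "c.999A>T")


def test_variant_table_order_follows_fixture(common_variant_store):
    t = variant_table(common_variant_store, "c.400+2dup")
    assert t.iloc[0].database == "UK Biobank"
    assert t.iloc[-1].population == "South Asian"


def test_summarize_study_level(decode_store):
    stats = summarize(decode_store, load_case_alleles())
    assert stats.n_variants == 62
    assert stats.n_in_databases == 29
    assert stats.n_absent == 33
    assert (stats.n_molecular, stats.n_cases_total) == (311, 482)
    assert stats.molecular_share == Fraction(311, 482)
    assert stats.top_k_allele_share == Fraction(368, 576)


def test_summarize_counts_presence_from_store_when_registry_complete(decode_store):
    # when the registry covers every curated variant, database presence is
    # derived from the counts themselves: 7 of the 15 fixture variants carry
    # a nonzero alt count in the deCODE table
    stats = summarize(decode_store, load_case_alleles(),
                      totals={"n_variants_total": 15, "n_cases_total": 482,
                              "n_molecular": 311, "n_case_alleles_total": 576})
    assert stats.n_in_databases == 7
    assert stats.n_absent == 8


def test_summarize_empty_case_table(decode_store):
    stats = summarize(decode_store, {}, totals={
        "n_variants_total": 62, "n_observed_in_databases": 29,
        "n_cases_total": 0, "n_molecular": 0, "n_case_alleles_total": 0,
    })
    assert stats.top_k_allele_share == 0
    assert stats.molecular_share == 0


def test_report_writers_round_trip(decode_store, tmp_path):
    rows = cohort_table(decode_store)
    tsv, md, js = tmp_path / "report.tsv", tmp_path / "report.md", tmp_path / "summary.json"
    write_report_tsv(rows, tsv)
    write_report_md(rows, md)
    write_summary_json(summarize(decode_store, load_case_alleles()), js)

    import pandas as pd

    machine = pd.read_csv(tsv, sep="\t")
    assert int(machine.set_index("cohort").loc["Sweden (deCODE)", "homozygote_one_in"]) == 4418404
    human = md.read_text()
    assert "1 in 4,418,404" in human
    summary = json.loads(js.read_text())
    assert summary["molecular_share_percent"] == 64.5
    assert summary["top_k_allele_share_percent"] == 63.9


def test_report_tsv_sentinel_is_empty_string(tmp_path):
    store = VariantStore(counts=[AlleleCount("v1", Cohort("simulated", "empty"), 0, 2000)])
    out = tmp_path / "report.tsv"
    write_report_tsv(cohort_table(store), out)
    line = out.read_text().splitlines()[1]
    fields = line.split("\t")
    assert fields[4] == "" and fields[5] == ""


def test_output_stable_under_input_row_permutation(decode_store, tmp_path):
    a = tmp_path / "a.tsv"
    write_report_tsv(cohort_table(decode_store), a)

    reg = fixture_path("registry.tsv")
    counts = fixture_path("table2_decode.tsv").read_text().splitlines()
    permuted = [counts[0]] + counts[:0:-1]
    pfile = tmp_path / "permuted.tsv"
    pfile.write_text("\n".join(permuted) + "\n")
    store2 = load_registry(reg, pfile)

    labels = [r.cohort_label for r in cohort_table(decode_store)]
    rows2 = {r.cohort_label: r for r in cohort_table(store2)}
    b = tmp_path / "b.tsv"
    write_report_tsv([rows2[label] for label in labels], b)
    assert a.read_bytes() == b.read_bytes()


def test_known_divergences_listed_and_flagged(pooled_cohorts):
    notes = known_divergences()
    cells = " ".join(d["cell"] for d in notes)
    for key in ["Iceland", "Ireland", "UK Biobank", "Latino", "top-3"]:
        assert key in cells
    flagged = {r.cohort.population for r in pooled_cohorts if r.flag}
    assert {"Iceland", "Ireland", "All", "Latino"} <= flagged
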