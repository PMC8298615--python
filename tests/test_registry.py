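"""Allele-count store, MAF/cMAF pooling and exact percent rounding."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from aprtfreq.registry import (
    AlleleCount,
    Cohort,
    RegistryValidationError,
    VariantStore,
    cmaf,
    export_vcf,
    fixture_path,
    load_counts_table,
    load_registry,
    maf,
    percent,
    save_registry,
)


def test_maf_examples():
    assert maf(1299, 107928) == Fraction(1299, 107928)
    assert float(maf(1299, 107928)) == pytest.approx(0.0120358, abs=1e-7)
    assert maf(0, 16760) == 0
    assert float(maf(5, 2730)) == pytest.approx(0.0018315, abs=1e-7)


@pytest.mark.parametrize("alt, an", [(5, 0), (-1, 10), (11, 10)])
def test_maf_domain_errors(alt, an):
    with pytest.raises(ValueError):
        maf(alt, an)


def test_cmaf_iceland(decode_store):
    freq = decode_store.cohort_cmaf("Iceland")
    assert freq.total_alt == 1304
    assert freq.allele_number_used == 107928
    assert freq.p == Fraction(1304, 107928)
    assert freq.p + freq.q == 1
    assert not freq.mixed_an


def test_cmaf_ireland(decode_store):
    freq = decode_store.cohort_cmaf("Ireland")
    assert freq.p == Fraction(7, 2730)
    assert percent(freq.p, 2).value == 0.26


def test_cmaf_empty_list():
    freq = cmaf([])
    assert freq.p == 0
    assert freq.q == 1


def test_cmaf_rejects_mixed_cohorts():
    a = AlleleCount("v1", Cohort("deCODE", "Iceland"), 1, 100)
    b = AlleleCount("v2", Cohort("deCODE", "Denmark"), 1, 100)
    with pytest.raises(RegistryValidationError, match="mixed cohorts"):
        cmaf([a, b])


def test_cmaf_rejects_duplicate_variants():
    c = Cohort("deCODE", "Iceland")
    with pytest.raises(RegistryValidationError, match="duplicate"):
        cmaf([AlleleCount("v1", c, 1, 100), AlleleCount("v1", c, 2, 100)])


def test_cmaf_mixed_allele_numbers_sums_frequencies():
    # unequal denominators: p is the sum of per-variant frequencies and the
    # largest AN is kept as the display denominator
    c = Cohort("gnomAD", "European (Non-Finnish)")
    counts = [
        AlleleCount("c.194A>T", c, 1, 124598),
        AlleleCount("c.400+2dup", c, 27, 128838),
    ]
    freq = cmaf(counts)
    assert freq.mixed_an
    assert freq.allele_number_used == 128838
    assert freq.p == Fraction(1, 124598) + Fraction(27, 128838)


def test_cmaf_additive_over_disjoint_subsets(decode_store):
    counts = decode_store.counts_for_cohort("Denmark")
    whole = cmaf(counts)
    part = cmaf(counts[:2]).p + cmaf(counts[2:]).p
    assert whole.p == part
    assert whole.p >= max(c.maf for c in counts)


def test_cmaf_zero_iff_all_zero():
    c = Cohort("simulated", "x")
    assert cmaf([AlleleCount("a", c, 0, 10), AlleleCount("b", c, 0, 10)]).p == 0
    assert cmaf([AlleleCount("a", c, 0, 10), AlleleCount("b", c, 1, 10)]).p > 0


@pytest.mark.parametrize(
    "num, den, decimals, expected",
    [(7, 2730, 2, 0.26), (1299, 107928, 1, 1.2), (311, 482, 1, 64.5), (0, 1, 3, 0.0)],
)
def test_percent_half_away_rounding(num, den, decimals, expected):
    assert percent(Fraction(num, den), decimals).value == expected


def test_percent_ties_round_away_from_zero():
    assert percent(Fraction(125, 100000), 2).value == 0.13  # 0.125% -> 0.13, not 0.12
    assert percent(Fraction(368, 576), 1).value == 63.9


def test_load_table2_fixture(decode_store):
    assert len(decode_store.counts) == 14
    assert len(decode_store.variants) == 15


def test_load_save_round_trip(decode_store, tmp_path):
    reg, cnt = tmp_path / "registry.tsv", tmp_path / "counts.tsv"
    save_registry(decode_store, reg, cnt)
    reloaded = load_registry(reg, cnt)
    assert reloaded == decode_store
    # byte-stable on a second save
    reg2, cnt2 = tmp_path / "r2.tsv", tmp_path / "c2.tsv"
    save_registry(reloaded, reg2, cnt2)
    assert reg2.read_bytes() == reg.read_bytes()
    assert cnt2.read_bytes() == cnt.read_bytes()


def test_empty_counts_file(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("variant_id\tdatabase\tpopulation\talt_count\tallele_number\n")
    assert load_counts_table(p) == []


def test_counts_validation_reports_row_numbers(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "variant_id\tdatabase\tpopulation\talt_count\tallele_number\n"
        "v1\tdeCODE\tIceland\t5\t0\n"
        "v2\tdeCODE\tIceland\t9\t4\n"
        "v2\tdeCODE\tIceland\t1\t10\n"
    )
    with pytest.raises(RegistryValidationError) as exc:
        load_counts_table(p)
    message = str(exc.value)
    assert "row 1" in message and "row 2" in message


def test_missing_columns(tmp_path):
    p = tmp_path / "cols.tsv"
    p.write_text("variant_id\talt_count\n")
    with pytest.raises(RegistryValidationError, match="missing columns"):
        load_counts_table(p)


def test_unknown_cohort_lists_known_labels(decode_store):
    with pytest.raises(KeyError, match="Iceland"):
        decode_store.counts_for_cohort("Atlantis")


def test_vcf_export_requires_explicit_genomic_alleles(decode_store, tmp_path, caplog):
    # fixture registry has positions but no genomic REF/ALT columns: all skipped
    out = tmp_path / "variants.vcf"
    with caplog.at_level("WARNING"):
        n = export_vcf(decode_store, out)
    assert n == 0
    assert "skipping" in caplog.text
    assert out.read_text().startswith("##fileformat=VCFv4.2")


def test_vcf_export_with_explicit_alleles(tmp_path):
    reg = tmp_path / "registry.tsv"
    reg.write_text(
        "variant_id\tcdna\tprotein\tregion\tbuild38_pos\tprinted_label\tgenomic_ref\tgenomic_alt\n"
        "c.194A>T\tc.194A>T\tp.(Asp65Val)\tExon 3\t16:88810550\tMissense\tT\tA\n"
    )
    store = load_registry(reg)
    out = tmp_path / "variants.vcf"
    assert export_vcf(store, out) == 1
    pysam = pytest.importorskip("pysam")
    records = list(pysam.VariantFile(str(out)))
    assert len(records) == 1
    assert (records[0].chrom, records[0].pos, records[0].ref) == ("16", 88810550, "T")


@given(
    alts=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=6, unique_by=id),
    an=st.integers(min_value=100, max_value=10000),
)
def test_cmaf_matches_sum_of_mafs_property(alts, an):
    c = Cohort("simulated", "prop")
    counts = [AlleleCount(f"v{i}", c, a, an) for i, a in enumerate(alts)]
    freq = cmaf(counts)
    assert freq.p == sum(Fraction(a, an) for a in alts)
    assert freq.p >= max(Fraction(a, an) for a in alts)
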