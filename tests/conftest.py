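import pytest

from aprtfreq import fixture_path, load_counts_table, load_registry
from aprtfreq.registry import VariantStore
from aprtfreq.report import load_pooled_cohorts


@pytest.fixture(scope="session")
def decode_store() -> VariantStore:
    """Registry plus the 14-row deCODE allele-count table."""
    return load_registry(fixture_path("registry.tsv"), fixture_path("table2_decode.tsv"))


@pytest.fixture(scope="session")
def common_variant_store() -> VariantStore:
    """Registry plus the per-population counts of the three most common variants."""
    return load_registry(fixture_path("registry.tsv"), fixture_path("table1_counts.tsv"))


@pytest.fixture(scope="session")
def pooled_cohorts():
    """Pre-pooled per-cohort Alt/AN rows with published cells and flags."""
    return load_pooled_cohorts()


@pytest.fixture(scope="session")
def registry_only() -> VariantStore:
    return load_registry(fixture_path("registry.tsv"))
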