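# Methods

## Problem and model

APRT deficiency is autosomal recessive: an individual is affected when both
chromosomes carry a pathogenic *APRT* allele — the same allele (homozygote)
or two different ones (compound heterozygote). Every pathogenic allele of
this gene is individually rare and none are reported on the same haplotype,
so the per-chromosome probability of carrying *some* pathogenic allele is
the sum of the per-variant minor allele frequencies, the cumulative MAF

p = Σᵢ altᵢ / ANᵢ,

and under Hardy-Weinberg equilibrium the genotype classes have frequencies
p² (biallelic = affected, pooling homozygotes and compound heterozygotes),
2p(1−p) (carriers) and (1−p)². Expected case counts are N·p² for a
population of size N. The model assumes random mating; consanguinity or
population substructure (F > 0) inflates the biallelic class beyond p² and
is deliberately not modelled — estimates for populations with frequent
consanguineous unions are therefore lower bounds.

## Exact arithmetic and rounding

All frequency math uses exact rationals (`fractions.Fraction`); floats
appear only at presentation boundaries. Two conventions matter:

* **"1 in N"** values are `round((AN/alt)²)` and `round(1/(2pq))` on the
  exact ratio, rounding half away from zero. Rounding is applied once, at
  the end; deriving N from an already-rounded percentage changes the result
  for large cohorts (1304/107,928 → 1 in 6850 exactly; 1 in 6841 via the
  two-decimal percent). This choice reproduces every internally consistent
  published per-cohort cell in the packaged fixtures.
* **Percentages** are rounded half away from zero at a caller-chosen number
  of decimals, computed in exact decimal arithmetic (so 311/482 → 64.5 and
  368/576 → 63.9 without float-tie artefacts).

A cohort whose pooled alternate count is zero yields a `NOT_OBSERVED`
sentinel, never a number, and machine-readable output renders it as an
empty field (not 0 or inf).

### Mixed denominators

When pooled variants within one cohort have unequal allele numbers (typical
for exome databases where coverage differs per site), p is the sum of
per-variant frequencies and the largest AN is kept as the display
denominator, with a logged notice. When all variants share one AN, p is
exactly Σalt/AN and the two definitions coincide.

## Nomenclature

The HGVS parser covers the constructs occurring in this gene's published
variant spectrum: substitutions (with signed intronic offsets), single and
range duplications/deletions, insertions and delins, on transcript
NM_000485.2 (543-nt CDS, 180 residues + stop; five exons). Protein
descriptions cover missense, nonsense, frameshift (`fs*N` and `fs*?`),
single-residue in-frame deletion, start loss (`Met1?`) and stop loss
(`*181Xaaext*?`). Parsing normalises internal whitespace (sources print
both `c.400+2dup` and `c.400 + 2dup`) and formatting reproduces the
normalised string byte-for-byte, which is the registry validation
round-trip. Positions beyond the CDS raise a warning, not an error.

Classification is total and deterministic: a variant at the canonical
splice dinucleotide (intronic offset |1–2|) is `splice_region` regardless
of its annotated protein effect; otherwise the protein tag decides;
in-frame del/dup without a frameshift falls to `inframe_indel`; everything
unresolvable is `other`. Registries sometimes print looser labels (a
start-loss labelled "Nonsense", a splice-donor duplication labelled
"Indel"); the printed label is preserved verbatim (`printed_label`) for
table reproduction while all logic uses the systematic class.

Genomic coordinates are stored as opaque `16:<pos>` build-38 strings. The
gene lies on the reverse strand, so no transcript-to-genome arithmetic or
strand complementing is attempted; VCF export emits only variants whose
registry rows carry explicit plus-strand `genomic_ref`/`genomic_alt`
columns and skips the rest with a warning.

## Fixture data and known divergences

The packaged fixture tables encode the published per-variant and per-cohort
allele counts for the curated pathogenic-variant set: a 15-variant registry,
the 14-row deCODE count table (five populations), the per-population counts
of the three globally most common variants, and the pooled per-cohort table
across six databases. Six published cells are contradicted by exact
recomputation from their own printed integer counts (a pre-rounded
homozygote cell for Iceland; an Irish row mixing pooled counts with
founder-variant-only derived cells; a UK Biobank denominator off by an
order of magnitude; an internally inconsistent Latino row; a truncated
percentage; a transposed-digit denominator). These are stored verbatim with
a `flag` column, enumerated in `fixtures/known_divergences.json`, and
excluded from golden tests — the tests assert that they are *documented and
divergent*, not that either value is right.

Per-variant case-allele tallies (223/80/65) are reconstructed from the
reported homozygote and compound-heterozygote case counts per country,
constrained to the published top-3 total of 368 of 576 disease alleles;
only the 368/576 ratio is asserted anywhere. Study-level totals that a
partial registry cannot yield (62 curated variants, 29 observed in
databases, 482 cases, 311 molecular diagnoses) are inputs, shipped in
`case_summary.json`.

## Synthetic cohorts

The simulator draws, for each diploid individual, two chromosomes
independently from the categorical distribution {reference: 1−Σpᵢ,
variantᵢ: pᵢ} — Hardy-Weinberg sampling with at most one pathogenic allele
per chromosome, mirroring the no-shared-haplotype observation. It emits
(a) an allele-count table in the registry schema, so simulated cohorts flow
through the identical pooling/reporting code as real database counts, and
(b) realized genotype tallies (per-variant homozygotes, compound
heterozygotes, carriers). Conservation holds exactly: total alt alleles =
2·(biallelic) + carriers; AN = 2·individuals.

What it emulates: finite-sample binomial noise in database allele counts,
founder-effect frequency contrasts, multi-allele compound heterozygosity.
What it does not: linkage/phasing, relatedness, consanguinity, sequencing
or variant-calling error, and per-site coverage differences (simulated
cohorts have a single AN). Passing recovery tests therefore validate the
estimator under the model's own assumptions, not robustness to those
real-data complications.

Randomness is a single numpy PCG64 stream (`numpy.random.default_rng`)
seeded from the scenario; replicate streams are spawned from one
`SeedSequence`, so results are reproducible across platforms byte-for-byte.

Presets: `iceland_founder` (one allele at p = 0.012 in 50,000 diploids —
the sample size and founder frequency of the largest sequenced founder
population — plus a comparison population of 15,000 with the same allele
100× rarer), `ireland` (three alleles at 5, 1, 1 copies per 2730
chromosomes, n = 1365), `null` (no pathogenic alleles).

### Recovery check

`recovery_check` runs replicate simulations (default 200) and verifies
(a) the mean realized biallelic fraction lies within 3 Monte-Carlo SE of
p², and (b) each replicate's pipeline-estimated cMAF lies within 3 binomial
SE (√(p(1−p)/2n)) of truth. Because (b) performs one 3σ test per replicate,
about 0.27 % of replicates are expected outside the band by chance
(~0.5 of 200); the pass criterion allows up to the binomial mean + 3 SD of
that exceedance count (3 of 200) rather than demanding zero, which would
fail a correct implementation on ~40 % of seeds. This is a multiplicity
correction, not a loosened per-replicate band.

## Design choices

* The registry records `c.521_523del (p.(Phe174del))` and
  `c.522_524del (p.(Ser175del))` as distinct alleles; raw strings are never
  merged on the suspicion that two descriptions denote one allele.
* `c.407T>C` (codon 136) is placed in exon 5, consistent with its cDNA
  position lying beyond the intron-4 donor site (c.400+2).
* Sub-populations (e.g. gnomAD "South European" under non-Finnish European)
  are independent population labels; no hierarchy arithmetic is performed,
  since pooled rows are published at each level separately.
* Variants absent from a database are stored as alt = 0 rows rather than
  dropped, so presence/absence statistics remain computable and zero rows
  survive round-trips.
* p > 0.5 is mathematically allowed but triggers a "not a minor allele"
  warning; p = 1 makes the carrier "1 in N" undefined (2pq = 0) and raises.

## Problem sizes

Default test and acceptance runs use the fixture tables as-is (≤ 39 count
rows), 200 simulation replicates of the 65,000-diploid founder scenario,
a 200,000-diploid single draw for the compound-heterozygote closed-form
check, and exhaustive 1-in-N oracle enumeration for pool sizes up to 20
chromosomes. The full suite completes in a few seconds; the acceptance
script in about one.

## Limitations

Estimates inherit every bias of the underlying databases (ancestry
composition, relatedness, variant-calling differences). No confidence
intervals are produced, matching the reporting convention of the published
per-cohort tables. The HGVS parser intentionally covers only this gene's
variant constructs and validates positions, not reference sequence content.
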