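# aprtfreq

Estimating the population frequency of **APRT deficiency** — a rare,
autosomal-recessive disorder of purine metabolism in which loss of adenine
phosphoribosyltransferase causes 2,8-dihydroxyadenine kidney stones and
progressive chronic kidney disease — from the frequency of its pathogenic
alleles in large population genomic databases.

The package is for medical geneticists and population-genetics analysts who
want to turn curated pathogenic-variant lists plus published allele counts
(deCODE, UK Biobank, the 100,000 Genomes Project, gnomAD, HGVD, KOVA, …)
into genetic-prevalence estimates, and to validate that machinery against
simulated cohorts with known truth.

## The model

For one gene and one population, let variant *i* have minor allele frequency
*p<sub>i</sub>* = alt<sub>i</sub>/AN (alternate allele count over allele
number, i.e. chromosomes genotyped). Because the rare pathogenic alleles of
*APRT* are never reported on the same haplotype, the frequency of carrying
*any* pathogenic allele on a chromosome is the **cumulative minor allele
frequency**

&nbsp;&nbsp;&nbsp;&nbsp;p = cMAF = Σ<sub>i</sub> p<sub>i</sub>,&nbsp;&nbsp; q = 1 − p.

Under Hardy-Weinberg equilibrium (random mating) genotype frequencies are
p² + 2pq + q² = 1, where

* **p²** — biallelic individuals (true homozygotes *and* compound
  heterozygotes): the expected affected fraction;
* **2pq** — carriers (one pathogenic allele; clinically unaffected);
* expected case count in a population of size N is N·p².

Both "1 in N" reciprocals are computed from the exact integer counts as
rationals and rounded half-away-from-zero only at the end; computing them
from a pre-rounded percentage corrupts large N (e.g. 1304/107,928 gives
1 in 6850 exactly, but 6841 via the rounded 1.21 %).

The package has six parts: `nomenclature` (an HGVS c./p. parser covering
this gene's published variant spectrum, with byte-for-byte round-trip),
`registry` (typed variant/allele-count store, TSV IO, exact cMAF pooling),
`hardy_weinberg` (the genotype math above), `report` (per-cohort and
per-variant tables, study summary), `synthetic_data` (a forward simulator
drawing diploid cohorts under the model, used as ground truth), and a thin
`cli`.

## Worked example

Pooling the packaged deCODE allele-count table (seven pathogenic variants
across five populations) and deriving the Hardy-Weinberg expectations:

```python
from aprtfreq import cohort_table, fixture_path, load_registry

store = load_registry(fixture_path("registry.tsv"),
                      fixture_path("table2_decode.tsv"))
for r in cohort_table(store, population_sizes={"Ireland": 4_900_000}):
    print(r.cohort_label, f"{r.alt}/{r.an}", r.percent_text + "%",
          f"hom 1 in {r.homozygote_one_in}", f"carrier 1 in {r.carrier_one_in}")
```

prints

```
Iceland (deCODE) 1304/107928 1.2082% hom 1 in 6850 carrier 1 in 42
Denmark (deCODE) 12/17662 0.0679% hom 1 in 2166293 carrier 1 in 736
Sweden (deCODE) 3/6306 0.0476% hom 1 in 4418404 carrier 1 in 1052
Ireland (deCODE) 7/2730 0.2564% hom 1 in 152100 carrier 1 in 196
Norway (deCODE) 3/5840 0.0514% hom 1 in 3789511 carrier 1 in 974
```

Reading: in Iceland the founder missense allele pushes the pooled frequency
to 1.2 %, so one person in ~6850 is expected to be biallelic (affected) and
one in 42 is a carrier. In Ireland, 7 pathogenic chromosomes among 2730
give an expected affected frequency of 1 in 152,100 — about 32 expected
cases in a nation of 4.9 million (`expected_cases(7/2730, 4_900_000)`),
although none has ever been reported there. The Scandinavian cohorts sit
near cMAF 0.05 %, i.e. roughly five expected cases per 20 million people.

The same stages are scriptable from the shell (`aprtfreq parse-registry`,
`cmaf`, `hw`, `report`, `simulate`); see `examples/` for narrative scripts
covering parsing, pooling, reporting and simulation.

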