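"""Derive expected homozygote / carrier frequencies and expected case counts.

For each cohort the pooled allele frequency p gives, under Hardy-Weinberg
equilibrium, a biallelic (affected) genotype frequency of p^2 and a carrier
frequency of 2p(1-p), reported in the field's "1 in N" convention. N is
computed from the exact integer counts, never from a pre-rounded percent.
"""

import json

from aprtfreq import cohort_table, expected_cases, fixture_path, load_registry

with open(fixture_path("config.json")) as fh:
    config = json.load(fh)

store = load_registry(fixture_path("registry.tsv"), fixture_path("table2_decode.tsv"))
rows = cohort_table(store, population_sizes=config["population_sizes"])

print("cohort                 Alt/AN        %        homozygote      carrier   exp. cases")
for r in rows:
    cases = f"{r.expected_cases:8.1f}" if r.expected_cases is not None else "        "
    print(f"{r.cohort_label:22s} {r.alt:>5}/{r.an:<8} {r.percent_text:>7}  "
          f"1 in {r.homozygote_one_in:>10,}  1 in {r.carrier_one_in:>5,} {cases}")

# A combined Scandinavian-scale population at cMAF 0.05%:
print(f"\n20 million people at cMAF 0.05%: "
      f"{expected_cases(0.0005, 20_000_000):.0f} expected biallelic cases")

# Ireland's 1-in-152,100 biallelic expectation implies ~30 undiagnosed
# subjects nationwide, although no case has ever been reported there.
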