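{
  "rounding_mode": "half_away",
  "percent_decimals": 4,
  "population_sizes": {
    "Iceland": 364134,
    "Ireland": 4900000,
    "Scandinavia": 20000000,
    "Japan": 126500000,
    "East Asia": 1700000000,
    "Latin America": 642000000
  }
}
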