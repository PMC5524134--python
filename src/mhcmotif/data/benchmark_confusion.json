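{
  "description": "Published position-level anchor confusion matrix (predicted x actual) for the 18-allele expert benchmark; 162 positions = 18 alleles x 9.",
  "tp": 32,
  "fp": 4,
  "fn": 7,
  "tn": 119
}
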