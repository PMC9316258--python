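{
  "comment": "Background amino-acid frequencies (percent) matching the average composition of well-curated protein databases; used as the base distribution of the synthetic two-class sequence generator so that k-mer features have realistic sparsity.",
  "frequencies_percent": {
    "A": 8.25, "C": 1.37, "D": 5.45, "E": 6.75, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66,
    "M": 2.42, "N": 4.06, "P": 4.70, "Q": 3.93, "R": 5.53,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92
  }
}
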