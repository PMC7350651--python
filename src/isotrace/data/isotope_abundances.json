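{
  "version": "ciaaw-2021",
  "source": "IUPAC/CIAAW representative terrestrial isotopic abundances (2021 compilation). Entries are [integer mass shift above the monoisotopic peak, mole fraction].",
  "elements": {
    "H": [[0, 0.999885], [1, 0.000115]],
    "C": [[0, 0.9893], [1, 0.0107]],
    "N": [[0, 0.99636], [1, 0.00364]],
    "O": [[0, 0.99757], [1, 0.00038], [2, 0.00205]],
    "F": [[0, 1.0]],
    "Na": [[0, 1.0]],
    "Si": [[0, 0.92223], [1, 0.04685], [2, 0.03092]],
    "P": [[0, 1.0]],
    "S": [[0, 0.9499], [1, 0.0075], [2, 0.0425], [4, 0.0001]],
    "Cl": [[0, 0.7576], [2, 0.2424]],
    "K": [[0, 0.932581], [1, 0.000117], [2, 0.067302]],
    "Br": [[0, 0.5069], [2, 0.4931]]
  }
}
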