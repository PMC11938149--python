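{
  "comment": "Bondi-style van der Waals radii in Angstrom, keyed by element symbol",
  "default": 1.8,
  "radii": {
    "H": 1.2,
    "D": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.8,
    "S": 1.8,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.9
  }
}
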