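{
  "version": 1,
  "comment": "van der Waals radii per element (Angstrom) and residue-level centroid interaction radii per amino acid.",
  "element": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80},
  "centroid": {
    "GLY": 1.8, "ALA": 2.0, "SER": 2.2, "CYS": 2.3, "THR": 2.4,
    "PRO": 2.4, "VAL": 2.5, "ASP": 2.5, "ASN": 2.5, "ILE": 2.7,
    "LEU": 2.7, "GLU": 2.7, "GLN": 2.7, "MET": 2.8, "HIS": 2.8,
    "LYS": 2.9, "PHE": 2.9, "ARG": 3.0, "TYR": 3.0, "TRP": 3.2
  }
}
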