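{
  "_comment": "Total residue van der Waals volumes (A^3), standard published set; sidechain volume is taken as total minus the glycine value.",
  "GLY": 48.0, "ALA": 67.0, "SER": 73.0, "CYS": 86.0, "PRO": 90.0,
  "ASP": 91.0, "THR": 93.0, "ASN": 96.0, "VAL": 105.0, "GLU": 109.0,
  "GLN": 114.0, "HIS": 118.0, "MET": 124.0, "ILE": 124.0, "LEU": 124.0,
  "LYS": 135.0, "PHE": 135.0, "TYR": 141.0, "ARG": 148.0, "TRP": 163.0
}
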